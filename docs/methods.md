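# Methods

## Joint deconvolution model

Each tissue sample is modeled independently. With G proteins, M genes and K
cell types, the bulk vectors satisfy

    E[y⁽¹⁾] = X⁽¹⁾ diag(p) s⁽¹⁾,   E[y⁽²⁾] = X⁽²⁾ diag(p) s⁽²⁾,

where p ≥ 0 are tissue cell-count fractions shared by both molecular
sources and s⁽ʲ⁾ ≥ 0 are modality-specific cell size factors. The reported
composition is the molecule-level fraction θₖ⁽ʲ⁾ ∝ pₖsₖ⁽ʲ⁾, normalized to
the simplex only at output time — p itself is never renormalized during
optimization.

**Optimization.** The summed squared-error loss over both modalities is
minimized by projected gradient descent over the full parameter set
η = {X⁽¹⁾, X⁽²⁾, p, s⁽¹⁾, s⁽²⁾}: η ← [η − Δ∇l(η)]₊. The analytic gradient
blocks are

    ∇X⁽ʲ⁾ = −2 r⁽ʲ⁾ (p∘s⁽ʲ⁾)ᵀ,  ∇s⁽ʲ⁾ = −2 (X⁽ʲ⁾ᵀr⁽ʲ⁾)∘p,
    ∇p = −2 Σⱼ (X⁽ʲ⁾ᵀr⁽ʲ⁾)∘s⁽ʲ⁾,      r⁽ʲ⁾ = y⁽ʲ⁾ − X⁽ʲ⁾diag(p)s⁽ʲ⁾,

verified in the test suite against central finite differences on random
instances. A step that would increase the loss is rejected and the step
size halved (up to `max_halvings=30`, the halved step persists), so the
loss trace is non-increasing by construction. Iteration stops when the
maximum absolute parameter change falls below `tol` or at `max_iter`.

**Defaults and their rationale.**

* `step Δ = 1e-3`. The estimated fractions are insensitive to moderate
  step-size changes because the halving guard adapts the effective step to
  the local curvature; Δ only sets the upper envelope. It should be scaled
  with the data if inputs are far from O(1).
* `tol ϵ = 1e-5` (absolute, on the parameter scale), `max_iter = 1000`.
  On noiseless data the tolerance fires almost immediately at an optimum.
  On noisy data the parameter drift per iteration rarely falls below ϵ and
  runs end at the iteration cap; this is intentional. The model has more
  parameters than observations ((G+M)K + 3K vs G+M per sample) and θ is not
  identified by the loss alone — rescaling X columns by c and s by 1/c
  leaves the fit unchanged but moves θ. Identification comes from starting
  at the signature matrix with unit size factors; the iteration budget
  bounds how far the fit can drift from that anchor and acts as implicit
  regularization (in the recovery benchmark, accuracy at 300 iterations is
  marginally better than at 1000, so the benchmark uses 300).
* Initial proportions: user-supplied, else non-negative least squares of
  the marker-gene bulk on the signature columns, renormalized to the
  simplex. NNLS-then-normalize equals the exact simplex-direction optimum
  with free scale (verified against a grid oracle in the tests). A ν-SVR
  deconvolution initializer is not re-implemented; initial proportions are
  an input.
* Rescaling: `log` (log2(x+1)) or `minmax` (per feature) can be applied
  consistently to bulk and signature before fitting. The CLI defaults to
  `log`, matching common practice for expression intensities; the library
  default is no rescaling so the model algebra is exact on the raw scale.
  MinMax is per feature across samples, preserving the between-sample
  ordering the deconvolution relies on.

**Degenerate cases.** A sample whose fitted p∘s is identically zero is
flagged failed (uninformative), never silently set uniform. Non-finite
losses raise with the iteration index. Per-sample failures do not affect
other samples; samples are fit independently and results are invariant to
fitting order.

## Signature protein selection (AJ-RF)

Blocks Y⁽ʲ⁾ (features × samples; the whole proteome, and the transcriptome
restricted to marker genes) are row-centered, reduced to per-block initial
ranks r_j by SVD, and the stacked sample-score bases are decomposed again:
squared singular values of the stacked matrix lie in [0, J] and measure how
many blocks share each direction. A component is declared joint when its
squared singular value exceeds both

* a **Wedin perturbation bound**: per block, sin²Θ ≤ (max(‖EᵀU‖, ‖EV‖)/σ_min)²
  estimated over `n_resample=100` random orthonormal direction sets, using
  the 95th percentile; threshold J − Σⱼ sin²Θⱼ;
* a **random-direction null**: the 95th percentile of the largest squared
  stacked singular value when each block's score basis is replaced by a
  random orthonormal basis of the same rank.

The retained right singular vectors are the common normalized scores (CNS,
orthonormal by construction). Per block, C = Y_c P (projection onto the
joint score space), I = rank-(r_j − r) truncated SVD of Y_c − C, and
E = Y − C − I, so C + I + E reconstructs the input exactly (removed row
means live in E). Joint rank 0 is a valid outcome meaning no shared space
is distinguishable from noise; selection then refuses to project and says
so. Note that when modality-specific size-factor variation dominates, the
two blocks' leading subspaces genuinely differ and a rank of 0 at high
initial ranks is the statistically correct answer — smaller initial ranks
focus the comparison on the dominant, composition-driven directions.

Proteins are ranked by d_g = ‖y_g· − ỹ_g·‖₂ where Ỹ = V V ᵀ Y_c + row
means and V holds the loadings of the SVD of the proteome's common matrix;
the n smallest distances are selected, ties broken by input order. The
joint rank always comes from the Wedin/null procedure, never from the
assumed number of cell types. Default initial ranks follow a scree rule
(components explaining ≥ 5% of centered block variance).

## Cell-type-specific pQTL test

For a protein y, pre-estimated fractions θ (samples × K) and a SNP with
genotype groups g ∈ {0,1,2}, the full model is

    E[yᵢ] = Σₖ θᵢₖ βₖ + Σₖ Σ_{a∈{1,2}} θᵢₖ γₖₐ 1[gᵢ = a]

with no global intercept: since θ rows sum to one, the intercept direction
lies in the span of the θ columns, which also makes every F statistic
invariant to constant shifts of y (asserted in the tests). H0: γₖ· = 0 is
tested per cell type by the nested F-test
F = ((RSS₀−RSS₁)/df₁)/(RSS₁/df₂), df₁ = observed groups − 1,
df₂ = n − rank(full design). Genotype is categorical by default (additive
dosage is an option with df₁ = 1); missing dosages drop the sample
(complete case, no imputation); covariates may enter as additive columns.
Designs are fit by pseudo-inverse least squares, so collinearity degrades
to a flagged warning rather than an error; constant y yields F = 0, p = 1.
Cis pairing keeps (gene, SNP) pairs on the same chromosome with distance
from the SNP to the gene interval ≤ 1 Mb (0 inside the gene); BED input is
converted to 1-based inclusive coordinates. Benjamini–Hochberg adjustment
is applied per cell type across all tested pairs by default (pooled scope
is available); under simulated nulls the test is calibrated (type-I error
at the nominal level, uniform p-values), as the acceptance checks verify.

## Synthetic-data generator

The generator emulates exactly the structure the model assumes, which is
what makes the validation informative about implementation correctness:

* cell counts p ~ Dirichlet(2·1_K): moderate compositional variation with
  occasional small fractions, typical of tissue cohorts;
* size factors lognormal(0, 0.4) per cell type and sample: cell types
  differ several-fold in per-cell molecular yield, and yields vary across
  samples; scenario A draws s⁽¹⁾, s⁽²⁾ independently (cross-modality
  per-cell-type correlation of θ ≈ 0.75, driven only by shared p), while
  scenario B multiplies one shared draw by a lognormal perturbation of sd
  (1 − coupling)·0.4 with coupling = 0.5 (correlation ≈ 0.93 — high but
  distinct, so there is still protein-specific signal to recover);
* individualized panels: base panel × elementwise lognormal(0, 0.2);
* marker structure: 30% of genes are markers boosted 8-fold in one cell
  type; the protein base panel is the RNA panel of the coding gene times a
  lognormal(0, 0.3) translation-efficiency factor;
* bulk noise: additive Gaussian on the log2(y+1) scale (sd 0.05),
  back-transformed and clamped at zero;
* pseudo signatures: multiplicative lognormal corruption of the true RNA
  base panel, sd 0.1 ("small") or 0.5 ("large"); marker genes are ranked
  by coefficient of variation across cell types;
* genotypes: dosages ~ Binomial(2, maf) (Hardy–Weinberg by construction);
  planted effects add β·dosage to chosen panel rows of one cell type
  before mixing, giving the QTL screen a known causal cell type.

What the generator does **not** emulate: count-based mean–variance
relationships, batch and platform effects, missing proteins, correlated
noise across features, or misspecified marker genes. Passing the recovery
benchmarks therefore demonstrates that the algorithms do what they claim
under their own model assumptions — not that real tissue compositions will
be recovered with the same accuracy.

## Validation design and problem sizes

The validation suite uses desk-scale problem sizes chosen to make the
statistical checks sharp while staying quick to run: recovery benchmark
n = 50 samples, K = 4, G = M = 300 features with the top 50% of genes by
signature CV as markers, 20 replicates per scenario, 300 PGD iterations;
planted-selection cohorts with 50 signal proteins among 500 over 20 seeds;
2000 Monte-Carlo null tests (n = 200, K = 3) for QTL calibration. All
stochastic checks are seed-controlled and deterministic.

## Known limitations

* Per-sample overparameterization means purified panels X are useful as a
  by-product but are noisier than the fractions; they are emitted raw,
  without post-processing.
* The Wedin bound implementation is a documented resampling variant
  (95th-percentile direction sampling); other AJIVE implementations may
  select slightly different joint ranks on borderline data.
* The two-block decomposition is the tested configuration; more blocks are
  accepted but not validated beyond the algebraic identities.
* BH adjustment controls FDR per screen; no permutation-based empirical
  FDR or conditional fine-mapping is provided.
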