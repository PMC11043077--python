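"""Data model and I/O for bulk expression matrices, signatures, genotypes and
gene annotations.

Bulk expression is stored features-by-samples, matching the layout of most
published deconvolution references: each column is one tissue sample, each row
one protein or gene. All containers validate their invariants on construction
(unique identifiers, finite values, non-negativity on raw/minmax scales) so
that downstream numerical code can assume clean input.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODALITIES = ("protein", "rna")
SCALES = ("raw", "log", "minmax")


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({x for x in ids if x in seen or seen.add(x)})  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {what}: {dups[:5]}{'...' if len(dups) > 5 else ''}")
    return ids


@dataclass
class BulkMatrix:
    """A bulk expression matrix (features x samples) for one molecular modality.

    Parameters
    ----------
    values : ndarray, shape (n_features, n_samples)
        Expression values. Must be finite; non-negative unless ``scale='log'``.
    feature_ids, sample_ids : sequences of unique strings
    modality : {'protein', 'rna'}
    scale : {'raw', 'log', 'minmax'}
        Bookkeeping for which rescaling has been applied.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    modality: str
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional (features x samples)")
        self.feature_ids = _check_unique(self.feature_ids, "feature_ids")
        self.sample_ids = _check_unique(self.sample_ids, "sample_ids")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.scale in ("raw", "minmax") and np.any(self.values < 0):
            raise ValueError(f"negative values not allowed on scale={self.scale!r}")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, modality: str, scale: str = "raw") -> "BulkMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns), modality, scale)

    def subset_features(self, feature_ids: Sequence[str]) -> "BulkMatrix":
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [idx[f] for f in feature_ids]
        return replace(self, values=self.values[rows, :], feature_ids=list(feature_ids))

    def subset_samples(self, sample_ids: Sequence[str]) -> "BulkMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return replace(self, values=self.values[:, cols], sample_ids=list(sample_ids))

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index_label="feature_id")


@dataclass
class SignatureMatrix:
    """Reference expression of signature features across K pure cell types."""

    values: np.ndarray
    feature_ids: list[str]
    cell_types: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional (features x cell types)")
        self.feature_ids = _check_unique(self.feature_ids, "feature_ids")
        self.cell_types = _check_unique(self.cell_types, "cell_types")
        if len(self.cell_types) < 1:
            raise ValueError("at least one cell type required")
        if self.values.shape != (len(self.feature_ids), len(self.cell_types)):
            raise ValueError("shape inconsistent with feature/cell-type labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if np.any(self.values < 0):
            raise ValueError("signature values must be non-negative")

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_types)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.cell_types)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SignatureMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def subset_features(self, feature_ids: Sequence[str]) -> "SignatureMatrix":
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [idx[f] for f in feature_ids]
        return SignatureMatrix(self.values[rows, :], list(feature_ids), list(self.cell_types))

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index_label="feature_id")


@dataclass
class PairedBulk:
    """Sample-matched protein and RNA bulk matrices plus a protein->gene map.

    ``protein_to_gene`` may be partial; proteins whose mapping target is not
    present among the RNA features are recorded in ``unmapped_proteins``.
    """

    protein: BulkMatrix
    rna: BulkMatrix
    protein_to_gene: dict[str, str] = field(default_factory=dict)
    unmapped_proteins: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.protein.modality != "protein" or self.rna.modality != "rna":
            raise ValueError("PairedBulk expects (protein, rna) modalities")
        if self.protein.sample_ids != self.rna.sample_ids:
            raise ValueError(
                "sample ids differ between modalities; use align_modalities() first"
            )
        rna_feats = set(self.rna.feature_ids)
        self.unmapped_proteins = [
            p for p, g in self.protein_to_gene.items() if g not in rna_feats
        ]

    @property
    def sample_ids(self) -> list[str]:
        return self.protein.sample_ids

    @property
    def n_samples(self) -> int:
        return self.protein.n_samples


@dataclass
class GenotypeTable:
    """Biallelic genotype dosages (SNPs x samples), 0/1/2 with NaN = missing."""

    dosages: np.ndarray
    snp_ids: list[str]
    sample_ids: list[str]
    snp_positions: list[tuple[str, int]]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.snp_ids = _check_unique(self.snp_ids, "snp_ids")
        self.sample_ids = _check_unique(self.sample_ids, "sample_ids")
        if self.dosages.shape != (len(self.snp_ids), len(self.sample_ids)):
            raise ValueError("dosage shape inconsistent with snp/sample ids")
        if len(self.snp_positions) != len(self.snp_ids):
            raise ValueError("snp_positions length must match snp_ids")
        observed = self.dosages[~np.isnan(self.dosages)]
        if not np.all(np.isin(observed, (0.0, 1.0, 2.0))):
            bad = np.unique(observed[~np.isin(observed, (0.0, 1.0, 2.0))])
            raise ValueError(f"dosages must be 0/1/2 or missing; found {bad[:5]}")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.snp_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class GeneAnnotation:
    """Genomic interval of a gene, 1-based inclusive coordinates."""

    gene_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty table")
    return df


def _coerce_numeric(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & ~df.isna()
    # pd.to_numeric maps the literal string "nan"/"NA" to NaN silently in some
    # paths; treat any NaN in the result as non-numeric since expression
    # tables must be fully observed.
    bad = bad | out.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at "
            f"row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    return out


def read_expression_table(path: str | Path, modality: str) -> BulkMatrix:
    """Read a delimited expression table (first column feature ids, header row
    sample ids) into a :class:`BulkMatrix` with ``scale='raw'``.

    Row and column order are preserved from the file. Duplicated identifiers,
    non-numeric cells (with the offending row/column named) and empty tables
    raise ``ValueError``.
    """
    df = _read_table(path)
    _check_unique(df.index, f"feature ids in {path}")
    _check_unique(df.columns, f"sample ids in {path}")
    df = _coerce_numeric(df, path)
    return BulkMatrix.from_frame(df, modality=modality, scale="raw")


def read_signature_table(path: str | Path) -> SignatureMatrix:
    """Read a delimited signature matrix (features x cell types)."""
    df = _read_table(path)
    df = _coerce_numeric(df, path)
    return SignatureMatrix.from_frame(df)


def read_mapping_table(path: str | Path) -> dict[str, str]:
    """Read a two-column protein->gene mapping table (no header required if
    exactly two columns; a header line is detected and skipped)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: mapping table needs two columns")
    first = df.iloc[0]
    if str(first[0]).lower() in ("protein", "protein_id") or str(first[1]).lower() in (
        "gene",
        "gene_id",
    ):
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_dosage_table(path: str | Path, positions: Mapping[str, tuple[str, int]] | None = None) -> GenotypeTable:
    """Read a TSV dosage matrix (SNPs x samples, entries 0/1/2 or NA).

    SNP coordinates come either from optional leading ``chrom``/``pos``
    columns in the table itself or from the ``positions`` mapping
    (snp_id -> (chromosome, 1-based position)); SNPs without either get
    ("", 0) and never enter cis windows.
    """
    df = _read_table(path)
    cols = {c.lower(): c for c in df.columns}
    chrom_col = next((cols[c] for c in ("chrom", "chromosome", "chr") if c in cols), None)
    pos_col = next((cols[c] for c in ("pos", "position") if c in cols), None)
    table_pos: dict[str, tuple[str, int]] = {}
    if chrom_col and pos_col:
        for sid, chrom, pos in zip(df.index, df[chrom_col], df[pos_col]):
            table_pos[sid] = (str(chrom), int(float(pos)))
        df = df.drop(columns=[chrom_col, pos_col])
    dos = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    snp_ids = list(df.index)
    pos_list = []
    for s in snp_ids:
        if positions and s in positions:
            pos_list.append(tuple(positions[s]))
        else:
            pos_list.append(table_pos.get(s, ("", 0)))
    return GenotypeTable(dos, snp_ids, list(df.columns), pos_list)  # type: ignore[arg-type]


def read_vcf(path: str | Path) -> GenotypeTable:
    """Read a biallelic VCF into dosages of the alternate allele.

    Multi-allelic records are skipped with a warning. Missing genotypes become
    NaN and are handled complete-case downstream.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    snp_ids, positions, rows = [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        sid = var.ID if var.ID else f"{var.CHROM}:{var.POS}"
        snp_ids.append(sid)
        positions.append((str(var.CHROM), int(var.POS)))
        gt = np.asarray(var.gt_types, dtype=float)  # 0,1,2; 3 = unknown
        gt[gt == 3] = np.nan
        rows.append(gt)
    if n_multi:
        logger.warning("skipped %d multi-allelic records in %s", n_multi, path)
    if not rows:
        raise ValueError(f"{path}: no usable biallelic records")
    return GenotypeTable(np.vstack(rows), snp_ids, samples, positions)


def read_bed(path: str | Path) -> list[GeneAnnotation]:
    """Read a BED-like TSV (chrom, start, end, id) of gene intervals.

    BED uses 0-based half-open coordinates; these are converted to 1-based
    inclusive internally (start+1, end).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise ValueError(f"{path}: BED needs >= 4 columns (chrom, start, end, id)")
    out = []
    for _, row in df.iterrows():
        out.append(
            GeneAnnotation(
                gene_id=str(row[3]),
                chromosome=str(row[0]),
                start=int(row[1]) + 1,
                end=int(row[2]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def rescale(bulk: BulkMatrix, method: str, log_offset: float = 1.0) -> BulkMatrix:
    """Rescale a bulk matrix.

    ``log``: elementwise log2(x + log_offset) (values must be >= 0).
    ``minmax``: per feature across samples, x -> (x - min) / (max - min);
    constant features map to 0. Output lies in [0, 1].
    """
    if method == "log":
        if np.any(bulk.values < 0):
            raise ValueError("log rescaling requires non-negative input")
        vals = np.log2(bulk.values + log_offset)
        return replace(bulk, values=vals, scale="log")
    if method == "minmax":
        lo = bulk.values.min(axis=1, keepdims=True)
        hi = bulk.values.max(axis=1, keepdims=True)
        span = hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(span > 0, (bulk.values - lo) / np.where(span > 0, span, 1.0), 0.0)
        return replace(bulk, values=vals, scale="minmax")
    raise ValueError(f"unknown rescale method {method!r} (expected 'log' or 'minmax')")


def align_modalities(
    protein: BulkMatrix,
    rna: BulkMatrix,
    protein_to_gene: Mapping[str, str] | None = None,
) -> PairedBulk:
    """Restrict both modalities to their shared samples, in the protein
    matrix's sample order, and package them as a :class:`PairedBulk`.

    Raises ``ValueError`` when no sample is shared. Proteins whose mapping
    target is absent from the RNA features are counted and logged.
    """
    shared = [s for s in protein.sample_ids if s in set(rna.sample_ids)]
    if not shared:
        raise ValueError("no shared samples between protein and RNA matrices")
    mapping = dict(protein_to_gene) if protein_to_gene else {}
    paired = PairedBulk(
        protein=protein.subset_samples(shared),
        rna=rna.subset_samples(shared),
        protein_to_gene=mapping,
    )
    dropped = (protein.n_samples - len(shared), rna.n_samples - len(shared))
    if any(dropped):
        logger.info("align_modalities: dropped %d protein / %d RNA samples", *dropped)
    if paired.unmapped_proteins:
        logger.info(
            "align_modalities: %d proteins map to genes absent from the RNA matrix",
            len(paired.unmapped_proteins),
        )
    return paired
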