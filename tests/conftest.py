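import numpy as np
import pytest

from omixdeconv import (
    BulkMatrix,
    NoiseSpec,
    PairedBulk,
    ParamSet,
    SignatureMatrix,
    make_truth,
    synthesize_bulk,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_paramset(rng, G=3, M=4, K=2, scale=1.0):
    """Random strictly-positive parameter set for oracle comparisons."""
    return ParamSet(
        X1=rng.uniform(0.1, scale, size=(G, K)),
        X2=rng.uniform(0.1, scale, size=(M, K)),
        p=rng.uniform(0.1, 1.0, size=K),
        s1=rng.uniform(0.5, 1.5, size=K),
        s2=rng.uniform(0.5, 1.5, size=K),
    )


def exact_bulk(param: ParamSet):
    """Noiseless bulk vectors implied by a parameter set."""
    y1 = param.X1 @ (param.p * param.s1)
    y2 = param.X2 @ (param.p * param.s2)
    return y1, y2


@pytest.fixture
def tiny_truth():
    """Small noiseless-capable cohort shared across tests."""
    return make_truth(n=6, K=3, G=30, M=30, seed=7)


@pytest.fixture
def tiny_noiseless_paired(tiny_truth):
    return synthesize_bulk(tiny_truth, NoiseSpec(bulk_sd=0.0), seed=1)


@pytest.fixture
def small_paired(rng):
    """Hand-sized paired cohort with explicit ids, for alignment tests."""
    protein = BulkMatrix(
        rng.uniform(0, 5, size=(4, 3)), [f"p{i}" for i in range(4)], ["a", "b", "c"], "protein"
    )
    bulk_rna = BulkMatrix(
        rng.uniform(0, 5, size=(5, 3)), [f"g{i}" for i in range(5)], ["a", "b", "c"], "rna"
    )
    mapping = {f"p{i}": f"g{i}" for i in range(4)}
    return PairedBulk(protein=protein, rna=bulk_rna, protein_to_gene=mapping)


@pytest.fixture
def identity_signature():
    return SignatureMatrix(np.eye(2), ["f1", "f2"], ["ct0", "ct1"])
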