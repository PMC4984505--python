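import numpy as np
import pytest

from matriflow.core import Alignment, GenotypeMatrix
from matriflow.simulate import SimConfig, make_fixtures, simulate_structured


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """Deterministic miniature dataset written once per session."""
    outdir = tmp_path_factory.mktemp("fixtures")
    return make_fixtures(outdir, seed=12345)


@pytest.fixture(scope="session")
def small_sim():
    """Small structured dataset shared across tests (1 cohort x 3 demes)."""
    cfg = SimConfig(
        seed=7,
        cohorts=("2010",),
        sample_sizes={"2010": (20, 14, 12)},
        n_loci=10,
        length_means=(66.59,),
        cohort_kn_factor=(1.0,),
    )
    return simulate_structured(cfg)


@pytest.fixture(scope="session")
def study_sim():
    """Three-cohort dataset at reduced per-deme sizes."""
    cfg = SimConfig(
        seed=11,
        sample_sizes={
            "2010": (24, 12, 10),
            "2011": (20, 12, 10),
            "2012": (20, 10, 10),
        },
        n_loci=12,
    )
    return simulate_structured(cfg)


@pytest.fixture
def toy_alignment():
    seqs = ["AAAAAAAAAA", "AAAAAAAAAG", "AAAAAAAAAG", "CAAAAAAAAA"]
    return Alignment(
        ids=tuple(f"i{k}" for k in range(4)),
        cohorts=("2010", "2010", "2011", "2011"),
        seqs=tuple(seqs),
    )


def make_genotypes(rows, demes, loci=None):
    """Helper: rows = list of per-individual [(a, b), ...] genotypes."""
    arr = np.array(rows, dtype=int)
    n, L, _ = arr.shape
    return GenotypeMatrix(
        ids=[f"i{k}" for k in range(n)],
        demes=list(demes),
        loci=loci or [f"L{j}" for j in range(L)],
        genotypes=arr,
    )
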