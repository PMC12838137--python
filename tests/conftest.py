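import warnings

import numpy as np
import pytest

from envgp.enviromics import build_erms
from envgp.genomics import build_grms, deduplicate, filter_markers, rogers_distance
from envgp.simulate import SimConfig, simulate_study

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_study():
    """A small line+hybrid study with duplicates, shared across tests."""
    cfg = SimConfig(
        n_lines=80,
        n_hybrids=40,
        n_markers=300,
        n_chromosomes=4,
        n_sites=3,
        n_years=2,
        duplicate_count=4,
        sparsity=0.9,
        variance_shares={
            "env": 0.20, "additive": 0.30, "dominance": 0.05,
            "epistatic": 0.10, "gxe": 0.10, "error": 0.25,
        },
        seed=9,
    )
    markers, catalog, weather, ev, pheno, truth = simulate_study(cfg)
    filtered = filter_markers(markers)
    dist = rogers_distance(filtered)
    dedup = deduplicate(dist)
    grm_a, grm_d, grm_aa = build_grms(filtered)
    erm_l, erm_nl, yrm, srm = build_erms(ev)
    return {
        "cfg": cfg,
        "markers": markers,
        "filtered": filtered,
        "catalog": catalog,
        "weather": weather,
        "ev": ev,
        "pheno": pheno,
        "truth": truth,
        "dist": dist,
        "dedup": dedup,
        "kernels": {
            "GRM_a": grm_a, "GRM_d": grm_d, "GRM_aa": grm_aa,
            "ERM_l": erm_l, "ERM_nl": erm_nl, "YRM": yrm, "SRM": srm,
        },
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
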