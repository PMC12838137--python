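"""Study-condition benchmark runs used by the acceptance checks.

These functions wire the synthetic-data generator to the model stack at
the study conditions (variance shares with G-by-E at 25% of the genetic
variance, quadrant cross-validation with a third of genotypes and
environments held out as new) and return summary statistics computed
from scratch.
"""

from __future__ import annotations

import numpy as np

from .enviromics import build_erms
from .genomics import build_grms
from .pipeline import run_quadrant_cv
from .simulate import SimConfig, simulate_study

__all__ = ["STUDY_SHARES", "study_kernels", "m1_null_prediction_ability"]

#: phenotype variance decomposition used for the benchmark simulations:
#: genetic = additive + dominance + epistatic + G-by-E = 0.60 of total,
#: with the G-by-E interaction at 25% of the genetic variance
STUDY_SHARES = {
    "env": 0.15,
    "additive": 0.30,
    "dominance": 0.05,
    "epistatic": 0.10,
    "gxe": 0.15,
    "error": 0.25,
}


def study_kernels(markers, ev):
    grm_a, grm_d, grm_aa = build_grms(markers)
    erm_l, erm_nl, yrm, srm = build_erms(ev)
    return {
        "GRM_a": grm_a, "GRM_d": grm_d, "GRM_aa": grm_aa,
        "ERM_l": erm_l, "ERM_nl": erm_nl, "YRM": yrm, "SRM": srm,
    }


def m1_null_prediction_ability(
    seed: int = 1,
    n_genotypes: int = 500,
    n_sites: int = 5,
    n_years: int = 4,
    runs: int = 20,
    n_markers: int = 600,
    nIter: int = 1500,
    burnIn: int = 300,
) -> dict:
    """Mean prediction ability of the baseline model M_1 for new genotypes.

    Simulates a multi-environment trial (``n_genotypes`` x
    ``n_sites * n_years`` environments) with additive, dominance,
    epistatic, environment and G-by-E components, builds the quadrant
    cross-validation plan (33% new genotypes and environments, 80% of
    quadrant 1 as training) and fits M_1 -- identity genotype and
    environment kernels -- on every run.  Because the identity kernel
    carries no information about unseen genotypes, the per-environment
    prediction ability in cv3 and cv4 is structurally zero.

    Returns mean per-environment Pearson correlations per quadrant cell
    plus the combined cv3/cv4 mean.
    """
    cfg = SimConfig(
        n_lines=n_genotypes,
        n_markers=n_markers,
        n_sites=n_sites,
        n_years=n_years,
        variance_shares=dict(STUDY_SHARES),
        sparsity=1.0,
        seed=seed,
    )
    markers, catalog, weather, ev, pheno, truth = simulate_study(cfg)
    results = run_quadrant_cv(
        pheno, {}, ["M_1"], runs=runs, min_genotypes_per_env=50,
        seed=seed, mcmc={"nIter": nIter, "burnIn": burnIn},
    )
    res = results["M_1"]
    out = {cell: res.mean_r(cell) for cell in ("cv1", "cv2", "cv3", "cv4")}
    out["cv3_cv4_mean"] = float(np.mean([out["cv3"], out["cv4"]]))
    out["n_cells"] = len(pheno)
    out["runs"] = runs
    return out
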