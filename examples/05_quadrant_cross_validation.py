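"""Benchmark models under the four quadrant cross-validation geometries.

cv1 predicts known genotypes in known environments (sparse testing),
cv2 known genotypes in new environments, cv3 new genotypes in known
environments, cv4 new genotypes in new environments.  The baseline M_1
(identity kernels) collapses to zero for new genotypes; genomic kernels
(M_2) recover cv3/cv4, and the G-by-E kernel (M_6) adds on top when
interaction variance is present.
"""

from envgp import SimConfig, compare_models, simulate_study
from envgp.benchmarks import study_kernels
from envgp.pipeline import run_quadrant_cv

cfg = SimConfig(n_lines=200, n_markers=400, n_sites=4, n_years=3,
                variance_shares={"env": 0.15, "additive": 0.28,
                                 "dominance": 0.04, "epistatic": 0.08,
                                 "gxe": 0.20, "error": 0.25},
                seed=7)
markers, catalog, weather, ev, pheno, truth = simulate_study(cfg)
kernels = study_kernels(markers, ev)

results = run_quadrant_cv(pheno, kernels, ["M_1", "M_2", "M_6"], runs=5,
                          min_genotypes_per_env=50, seed=7,
                          mcmc={"nIter": 1500, "burnIn": 300})

print("mean prediction ability (Pearson r) per cell:")
print(f"{'model':6s} {'cv1':>6s} {'cv2':>6s} {'cv3':>6s} {'cv4':>6s}")
for model, res in results.items():
    row = " ".join(f"{res.mean_r(c):6.3f}" for c in ("cv1", "cv2", "cv3", "cv4"))
    print(f"{model:6s} {row}")

print()
cmp = compare_models([results["M_2"], results["M_6"]], "M_2", cell="cv3")
print("M_6 vs M_2 in cv3 (new genotypes, known environments):")
print(cmp[["model", "pct_difference", "t", "p", "significant"]].round(4)
      .to_string(index=False))
# A positive, significant percent difference reproduces the study's
# structural finding: modeling G-by-E pays off exactly where genotypes
# must be predicted into environments with data from their relatives.
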