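"""Cluster environments by G-by-E patterns and rank the weather drivers.

A diverse core set of lines is selected from the Rogers distance matrix,
its performance predicted in every environment with M_6, the G-by-E
pattern (the residual after removing genotype and environment main
effects) extracted, environments K-means-clustered on the first two
principal coordinates, and a gradient-boosted classifier used to score
which environment variables explain the clustering.
"""

import warnings

warnings.filterwarnings("ignore")

from envgp import (
    SimConfig,
    cluster_gxe,
    ev_importance,
    extract_gxe_patterns,
    filter_markers,
    rogers_distance,
    select_core_set,
    simulate_study,
)
from envgp.benchmarks import study_kernels
from envgp.pipeline import predict_full_matrix

cfg = SimConfig(n_lines=120, n_markers=400, n_sites=6, n_years=4,
                variance_shares={"env": 0.15, "additive": 0.25,
                                 "dominance": 0.05, "epistatic": 0.05,
                                 "gxe": 0.30, "error": 0.20},
                sparsity=0.7, seed=13)
markers, catalog, weather, ev, pheno, truth = simulate_study(cfg)
kernels = study_kernels(markers, ev)

core = select_core_set(rogers_distance(filter_markers(markers)), n=60)
print(f"core set: {len(core)} genetically diverse lines")

pred = predict_full_matrix(pheno, kernels, core, ev.environments,
                           model="M_6", seed=1,
                           mcmc={"nIter": 1500, "burnIn": 300})
patterns = extract_gxe_patterns(pred, seed=1)
print(f"G x E pattern matrix: {patterns.values.shape[0]} genotypes x "
      f"{patterns.values.shape[1]} environments (row/col means are zero)")

clusters = cluster_gxe(patterns, k="auto", min_size=3, seed=1)
print(f"K-means chose k={clusters.k} clusters "
      f"(mean silhouette {clusters.silhouette:.2f}); sizes: "
      f"{clusters.sizes().to_dict()}")

imp = ev_importance(ev, clusters, n_estimators=300)
print(f"cluster membership predicted from EVs with accuracy {imp.accuracy:.0%}")
print("top weather variables by mean scaled gain:")
print(imp.per_variable.head(5).round(3).to_string())
# High-gain variables are the weather signals whose between-environment
# differences line up with the G-by-E response groups.
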