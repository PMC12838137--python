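"""Generate a synthetic multi-environment wheat trial and inspect it.

The generator emulates the structure of a large breeding dataset: inbred
lines plus hybrids from an incomplete factorial, injected genomic
duplicates, daily weather per site-year, and grain-yield phenotypes
composed of environment, additive, dominance, epistatic and G-by-E
effects with configured variance shares.
"""

import numpy as np

from envgp import SimConfig, simulate_study

cfg = SimConfig(
    n_lines=120,
    n_hybrids=60,
    n_markers=400,
    n_sites=5,
    n_years=3,
    duplicate_count=3,
    sparsity=0.8,
    seed=42,
)
markers, catalog, weather, ev, pheno, truth = simulate_study(cfg)

print(f"genotypes: {markers.n_genotypes} "
      f"({len(catalog.lines)} lines, {len(catalog.hybrids)} hybrids)")
print(f"markers:   {markers.n_markers} on "
      f"{markers.marker_map['chrom'].nunique()} chromosomes")
print(f"environments: {len(ev.environments)} site-years, "
      f"{ev.values.shape[1]} environment variables each")
print(f"phenotype records: {len(pheno)} "
      f"({cfg.sparsity:.0%} of the genotype x environment grid)")
print(f"phenotypic mean {pheno['value'].mean():.1f} Q/ha, "
      f"variance {np.var(pheno['value']):.1f} (configured {cfg.total_variance})")
print("configured variance shares:", truth.variance_shares)
# Each component is drawn from its kernel scaled so the shares are
# shares of total phenotypic variance; with few environments the
# realized env/G-by-E contribution fluctuates around its target.
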