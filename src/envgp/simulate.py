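"""Synthetic multi-environment trial generator.

Emulates the data structure of a large winter-wheat breeding resource:
inbred elite lines plus an optional genetically divergent subpopulation
(a stand-in for gene-bank accessions), single-cross hybrids from
incomplete factorial mating designs, injected genomic duplicates, daily
weather for each site-by-year environment (27 variables over the
1 October - 31 August season) and grain-yield phenotypes composed of
environment, additive, dominance, additive-epistatic and G-by-E effects
plus residual noise, with configurable variance shares.

Effects are drawn from kernel-structured normals (Cholesky with 1e-8
diagonal jitter) using the same kernels the prediction models assume, so
parameter-recovery tests are well posed.  Kernels are scaled to unit mean
diagonal before drawing so the configured shares are shares of total
phenotypic variance.  Ground truth is retained in a :class:`TruthRecord`.

One global seed fans out to per-operation child seeds by fixed offsets:
population +1, environments +2, phenotypes +3, growth parameters +4.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enviromics import EVMatrix, build_erms, monthly_evs
from .genomics import GenotypeCatalog, MarkerMatrix, build_grms

__all__ = [
    "SimConfig",
    "TruthRecord",
    "WEATHER_VARIABLES",
    "simulate_population",
    "simulate_environments",
    "simulate_phenotypes",
    "simulate_gs_parameters",
]

#: 27 weather variables (name -> (mean, SD) on natural scale).  Names follow
#: the sensor_stat_unit idiom (e.g. at_maC = maximum air temperature in
#: Celsius); they are treated as opaque labels everywhere downstream.
WEATHER_VARIABLES: dict[str, tuple[float, float]] = {
    "at_avC": (9.0, 1.2), "at_maC": (14.0, 1.5), "at_miC": (4.0, 1.3),
    "at_5_avC": (8.5, 1.2), "at_5_miC": (2.5, 1.4), "st_avC": (9.5, 1.0),
    "dp_avC": (5.0, 1.1), "pr_smM": (55.0, 12.0), "pr_maM": (14.0, 4.0),
    "rh_avP": (78.0, 4.0), "rh_maP": (95.0, 2.0), "rh_miP": (55.0, 6.0),
    "ws_2_avK": (8.0, 1.5), "ws_2_mxK": (30.0, 5.0), "ws_10_avK": (11.0, 2.0),
    "sr_avW": (120.0, 18.0), "sr_smW": (3600.0, 500.0), "lwr_avW": (310.0, 12.0),
    "lwr_miW": (250.0, 15.0), "sd_smH": (130.0, 30.0), "et_smM": (45.0, 9.0),
    "vp_avH": (9.5, 1.0), "cc_avP": (60.0, 8.0), "fd_ct": (4.0, 2.5),
    "hd_ct": (1.5, 1.2), "sn_smM": (3.0, 2.0), "lw_avH": (7.0, 1.8),
}

#: canonical phenotype variance-share terms
SHARE_TERMS = ("env", "additive", "dominance", "epistatic", "gxe", "error")


@dataclass
class SimConfig:
    """Configuration of the synthetic study."""

    n_lines: int = 200
    n_hybrids: int = 0
    n_markers: int = 500
    n_chromosomes: int = 5
    n_sites: int = 4
    n_years: int = 3
    n_series: int = 3
    factorial_density: float = 0.5
    duplicate_count: int = 0
    n_divergent: int = 0
    divergence: float = 0.0
    variance_shares: dict = field(
        default_factory=lambda: {
            "env": 0.20, "additive": 0.25, "dominance": 0.05,
            "epistatic": 0.10, "gxe": 0.15, "error": 0.25,
        }
    )
    sparsity: float = 1.0
    mean_yield: float = 80.0
    total_variance: float = 100.0
    chrom_length_bp: int = 2_000_000
    site_sd: float = 0.6
    year_sd: float = 0.6
    site_year_sd: float = 0.35
    day_sd: float = 1.0
    first_year: int = 2018
    seed: int = 1

    def __post_init__(self):
        for name in ("n_lines", "n_markers", "n_chromosomes", "n_sites",
                     "n_years", "n_series"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 < self.sparsity <= 1.0):
            raise ValueError("sparsity must lie in (0, 1]")
        if not (0.0 < self.factorial_density <= 1.0):
            raise ValueError("factorial_density must lie in (0, 1]")
        if self.n_hybrids < 0 or self.duplicate_count < 0 or self.n_divergent < 0:
            raise ValueError("counts must be non-negative")
        self.validate_shares()

    def validate_shares(self) -> None:
        unknown = set(self.variance_shares) - set(SHARE_TERMS)
        if unknown:
            raise ValueError(f"unknown variance-share terms: {sorted(unknown)}")
        for required in ("additive", "error"):
            if required not in self.variance_shares:
                raise ValueError(f"variance_shares missing required term {required!r}")
        total = sum(self.variance_shares.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"variance shares sum to {total}, expected 1.0")


@dataclass
class TruthRecord:
    """Ground truth kept for recovery tests."""

    variance_shares: dict
    true_effects: dict
    seed: int

    def __post_init__(self):
        if abs(sum(self.variance_shares.values()) - 1.0) > 1e-9:
            raise ValueError("variance shares must sum to 1")

    def to_json(self, path) -> None:
        payload = {
            "variance_shares": self.variance_shares,
            "seed": self.seed,
            "true_effects": {
                k: (v.tolist() if isinstance(v, np.ndarray)
                    else v.to_dict() if isinstance(v, (pd.Series, pd.DataFrame))
                    else v)
                for k, v in self.true_effects.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------
def simulate_population(cfg: SimConfig) -> tuple[MarkerMatrix, GenotypeCatalog]:
    """Generate line and hybrid genotypes with map, series and duplicates."""
    rng = np.random.default_rng(cfg.seed + 1)
    p = rng.uniform(0.15, 0.85, size=cfg.n_markers)

    n_elite = cfg.n_lines - cfg.n_divergent
    if n_elite < 1:
        raise ValueError("n_divergent must leave at least one elite line")
    elite = (rng.random((n_elite, cfg.n_markers)) < p).astype(float) * 2.0

    shift = cfg.divergence * rng.choice([-1.0, 1.0], size=cfg.n_markers)
    p_div = np.clip(p + shift, 0.02, 0.98)
    divergent = (rng.random((cfg.n_divergent, cfg.n_markers)) < p_div).astype(float) * 2.0
    codes = np.vstack([elite, divergent]) if cfg.n_divergent else elite

    # keep every marker polymorphic: flip one random genotype at fixed loci
    for j in np.where(codes.std(axis=0) == 0)[0]:
        i = rng.integers(codes.shape[0])
        codes[i, j] = 2.0 - codes[i, j]

    line_ids = [f"L{i + 1:04d}" for i in range(cfg.n_lines)]
    # series: elite lines in blocks Exp_1..Exp_k; divergent subpopulation
    # gets the last series (the gene-bank stand-in)
    series = np.empty(cfg.n_lines, dtype=object)
    if cfg.n_divergent:
        elite_series = max(cfg.n_series - 1, 1)
        series[n_elite:] = f"Exp_{cfg.n_series}"
    else:
        elite_series = cfg.n_series
    blocks = np.array_split(np.arange(n_elite), elite_series)
    for b, idx in enumerate(blocks):
        series[idx] = f"Exp_{b + 1}"

    rows = [codes]
    ids = list(line_ids)
    cat_rows = [
        {"genotype_id": gid, "material_type": "line", "female_parent": None,
         "male_parent": None, "series": ser}
        for gid, ser in zip(line_ids, series)
    ]

    # injected exact duplicates under new identifiers
    if cfg.duplicate_count:
        dup_src = rng.choice(cfg.n_lines, size=cfg.duplicate_count, replace=False)
        for k, src in enumerate(dup_src):
            gid = f"D{k + 1:03d}"
            rows.append(codes[src][None, :])
            ids.append(gid)
            cat_rows.append(
                {"genotype_id": gid, "material_type": "line", "female_parent": None,
                 "male_parent": None, "series": series[src]}
            )

    # hybrids from an incomplete factorial among elite lines
    if cfg.n_hybrids:
        n_par = int(np.ceil(np.sqrt(cfg.n_hybrids / cfg.factorial_density)))
        n_par = min(n_par, n_elite // 2)
        females = np.arange(n_par)
        males = np.arange(n_par, 2 * n_par)
        n_possible = int(round(len(females) * len(males) * cfg.factorial_density))
        if n_possible < cfg.n_hybrids:
            raise ValueError(
                f"factorial density {cfg.factorial_density} over "
                f"{len(females)}x{len(males)} parents yields only "
                f"{n_possible} crosses < n_hybrids={cfg.n_hybrids}"
            )
        lattice = [(f, m) for f in females for m in males]
        pick = rng.choice(len(lattice), size=cfg.n_hybrids, replace=False)
        for k, sel in enumerate(pick):
            f, mparent = lattice[sel]
            gid = f"H{k + 1:04d}"
            rows.append(((codes[f] + codes[mparent]) / 2.0)[None, :])
            ids.append(gid)
            cat_rows.append(
                {"genotype_id": gid, "material_type": "hybrid",
                 "female_parent": line_ids[f], "male_parent": line_ids[mparent],
                 "series": series[f]}
            )

    all_codes = pd.DataFrame(np.vstack(rows), index=ids,
                             columns=[f"M{j + 1:05d}" for j in range(cfg.n_markers)])
    per_chrom = np.array_split(np.arange(cfg.n_markers), cfg.n_chromosomes)
    chrom = np.empty(cfg.n_markers, dtype=object)
    pos = np.empty(cfg.n_markers, dtype=int)
    for c, idx in enumerate(per_chrom):
        chrom[idx] = f"chr{c + 1}"
        step = cfg.chrom_length_bp // (len(idx) + 1)
        pos[idx] = (np.arange(len(idx)) + 1) * max(step, 1)
    mmap = pd.DataFrame({"chrom": chrom, "pos": pos}, index=all_codes.columns)
    return MarkerMatrix(all_codes, mmap), GenotypeCatalog(pd.DataFrame(cat_rows))


# ---------------------------------------------------------------------------
# environments
# ---------------------------------------------------------------------------
def _season_dates(harvest_year: int) -> pd.DatetimeIndex:
    """335 daily dates from 1 Oct (sowing year) to 31 Aug, Feb 29 dropped."""
    start = pd.Timestamp(year=harvest_year - 1, month=10, day=1)
    end = pd.Timestamp(year=harvest_year, month=8, day=31)
    days = pd.date_range(start, end, freq="D")
    return days[~((days.month == 2) & (days.day == 29))]


def simulate_environments(cfg: SimConfig) -> pd.DataFrame:
    """Daily weather per site-year with site/year/site-by-year structure.

    Each variable is its natural-scale mean plus site, year and
    site-by-year effects (SDs are the configured multiples of the
    variable's own SD) plus day-level noise.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    sites = [f"S{s + 1}" for s in range(cfg.n_sites)]
    years = [cfg.first_year + t for t in range(cfg.n_years)]
    var_names = list(WEATHER_VARIABLES)
    sds = np.array([WEATHER_VARIABLES[v][1] for v in var_names])
    means = np.array([WEATHER_VARIABLES[v][0] for v in var_names])

    site_eff = rng.normal(0.0, 1.0, (cfg.n_sites, len(var_names))) * sds * cfg.site_sd
    year_eff = rng.normal(0.0, 1.0, (cfg.n_years, len(var_names))) * sds * cfg.year_sd
    sy_eff = (
        rng.normal(0.0, 1.0, (cfg.n_sites, cfg.n_years, len(var_names)))
        * sds * cfg.site_year_sd
    )

    frames = []
    for si, site in enumerate(sites):
        for yi, year in enumerate(years):
            dates = _season_dates(year)
            base = means + site_eff[si] + year_eff[yi] + sy_eff[si, yi]
            noise = rng.normal(0.0, 1.0, (len(dates), len(var_names))) * sds * cfg.day_sd
            vals = base + noise
            df = pd.DataFrame(vals, columns=var_names)
            df.insert(0, "date", dates)
            df.insert(0, "year", year)
            df.insert(0, "site", site)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------
def _chol_draw(K: np.ndarray, rng: np.random.Generator, jitter: float = 1e-8):
    """One draw from N(0, K) scaled so its expected empirical variance is 1.

    For u ~ N(0, K) the expected sample variance of u is
    ``mean(diag K) - mean(K)`` (correlation moves variance into the mean),
    so the kernel is normalized by that centered scale before drawing.
    """
    scale = np.diag(K).mean() - K.mean()
    if scale <= 0:
        raise ValueError("degenerate kernel: no centered variance to draw from")
    L = np.linalg.cholesky(K / scale + jitter * np.eye(K.shape[0]))
    return L @ rng.standard_normal(K.shape[0])


def simulate_phenotypes(
    markers: MarkerMatrix,
    ev: EVMatrix,
    cfg: SimConfig,
    catalog: GenotypeCatalog | None = None,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Phenotypes y = mu + u_E + u_a + u_d + u_aa + u_GE + e.

    Environment effects are drawn from the non-linear environment kernel,
    genotype effects from the additive/dominance/epistatic genomic
    kernels, and G-by-E effects from the Kronecker product of the
    non-linear environment kernel with the additive genomic kernel (the
    covariance the reaction-norm models assume).  Observed cells are
    subsampled to ``cfg.sparsity``.
    """
    cfg.validate_shares()
    rng = np.random.default_rng(cfg.seed + 3)
    shares = {t: cfg.variance_shares.get(t, 0.0) for t in SHARE_TERMS}
    sig = {t: cfg.total_variance * s for t, s in shares.items()}

    genotypes = markers.genotype_ids
    environments = ev.environments
    n_g, n_e = len(genotypes), len(environments)

    grm_a, grm_d, grm_aa = build_grms(markers)
    if sig["env"] or sig["gxe"]:
        if n_e < 2:
            raise ValueError("env/gxe variance requires at least two environments")
        _, erm_nl, _, _ = build_erms(ev)
    else:
        erm_nl = None

    def _component(K, target, size):
        """Kernel-structured draw rescaled to its exact target variance.

        Strongly correlated kernels (notably the environment kernel) have
        few effective degrees of freedom, so a raw draw's realized
        variance can be far from its expectation; rescaling keeps the
        configured shares exact while preserving the kernel direction.
        """
        if not target:
            return np.zeros(size)
        u = _chol_draw(K, rng)
        v = u.var()
        return u * np.sqrt(target / v) if v > 0 else u

    u_a = _component(grm_a.values, sig["additive"], n_g)
    u_d = _component(grm_d.values, sig["dominance"], n_g)
    u_aa = _component(grm_aa.values, sig["epistatic"], n_g)
    u_env = _component(erm_nl.values if erm_nl is not None else None,
                       sig["env"], n_e)

    if sig["gxe"]:
        Kg, Ke = grm_a.values, erm_nl.values
        Lg = np.linalg.cholesky(Kg + 1e-8 * np.eye(n_g))
        Le = np.linalg.cholesky(Ke + 1e-8 * np.eye(n_e))
        u_ge = Lg @ rng.standard_normal((n_g, n_e)) @ Le.T
        u_ge *= np.sqrt(sig["gxe"] / u_ge.var())
    else:
        u_ge = np.zeros((n_g, n_e))

    noise = rng.normal(0.0, np.sqrt(sig["error"]), (n_g, n_e))
    Y = (
        cfg.mean_yield
        + u_env[None, :]
        + (u_a + u_d + u_aa)[:, None]
        + u_ge
        + noise
    )

    series_of = catalog.series_of() if catalog is not None else {}
    long = pd.DataFrame(
        {
            "genotype": np.repeat(genotypes, n_e),
            "environment": np.tile(environments, n_g),
            "series": [series_of.get(g, "Exp_1") for g in np.repeat(genotypes, n_e)],
            "value": Y.ravel(),
        }
    )
    n_obs = int(round(cfg.sparsity * len(long)))
    if n_obs < len(long):
        keep = rng.choice(len(long), size=n_obs, replace=False)
        long = long.iloc[np.sort(keep)].reset_index(drop=True)

    truth = TruthRecord(
        variance_shares={t: s for t, s in shares.items()},
        true_effects={
            "u_a": pd.Series(u_a, index=genotypes),
            "u_d": pd.Series(u_d, index=genotypes),
            "u_aa": pd.Series(u_aa, index=genotypes),
            "env": pd.Series(u_env, index=environments),
            "gxe": pd.DataFrame(u_ge, index=genotypes, columns=environments),
        },
        seed=cfg.seed,
    )
    return long, truth


# ---------------------------------------------------------------------------
# crop-growth-parameter stand-in
# ---------------------------------------------------------------------------
def simulate_gs_parameters(
    catalog: GenotypeCatalog,
    sites: list,
    k: int = 5,
    heritable_fraction: float = 0.15,
    grm=None,
    seed: int = 1,
) -> pd.DataFrame:
    """Genotype-by-site growth parameters with a configurable genetic part.

    Each of the ``k`` parameters decomposes into a genotype component
    (fraction ``heritable_fraction`` of the unit within-site variance,
    drawn from ``grm`` when given, otherwise iid), a site component, a
    genotype-by-site interaction and noise.  Crop-growth-model outputs in
    the study this emulates are mostly weakly heritable, hence the low
    default.
    """
    if not sites:
        raise ValueError("sites must be non-empty")
    if not (0.0 <= heritable_fraction <= 1.0):
        raise ValueError("heritable_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed + 4)
    genotypes = list(catalog.table["genotype_id"])
    n_g, n_s = len(genotypes), len(sites)
    rows = {"genotype_id": np.repeat(genotypes, n_s), "site": np.tile(sites, n_g)}
    h = heritable_fraction
    resid = 1.0 - h
    for pnum in range(k):
        if grm is not None:
            g = _chol_draw(grm.values if hasattr(grm, "values") else grm, rng)
        else:
            g = rng.standard_normal(n_g)
        g = g * np.sqrt(h)
        s_eff = rng.normal(0.0, np.sqrt(resid) * 0.5, n_s)
        inter = rng.normal(0.0, np.sqrt(resid * 0.4), (n_g, n_s))
        noise = rng.normal(0.0, np.sqrt(resid * 0.6), (n_g, n_s))
        vals = g[:, None] + s_eff[None, :] + inter + noise
        rows[f"param_{pnum + 1}"] = vals.ravel()
    return pd.DataFrame(rows)


def simulate_study(cfg: SimConfig):
    """Convenience wrapper: population, weather, EVs and phenotypes."""
    markers, catalog = simulate_population(cfg)
    weather = simulate_environments(cfg)
    ev = monthly_evs(weather)
    pheno, truth = simulate_phenotypes(markers, ev, cfg, catalog)
    return markers, catalog, weather, ev, pheno, truth
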