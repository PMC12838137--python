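"""Multi-kernel Bayesian linear mixed models for genomic prediction.

The model family extends GBLUP stepwise: phenotypic records (genotype
means within environments) are modeled as an intercept plus optional
fixed factors plus a stack of random terms, each with a labeled
covariance kernel --

* identity kernels (uncorrelated genotype/environment main effects),
* genomic kernels GRM_a / GRM_d / GRM_aa,
* environmental kernels ERM_l / ERM_nl and the year/site kernels YRM/SRM,
* Hadamard-product reaction-norm kernels for G-by-E and G-by-year terms,
  expanded on phenotype rows so unbalanced data are handled exactly.

Fitting is by Gibbs sampling with scaled-inverse-chi-square variance
priors (df0 = 5, prior mode splitting the phenotypic variance equally
among terms).  Each correlated term is sampled as one blocked draw in a
whitened eigenbasis in which its conditional precision is diagonal, so a
full sweep costs two matrix-vector products per term.  Identity-kernel
terms use conditionally independent per-level updates, which also
support heterogeneous per-environment residual variances (used by the
heritability model).  A closed-form Henderson mixed-model-equation
solver (`blup_oracle`) provides the deterministic reference when
variance components are fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, eigh, solve_triangular
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .genomics import DuplicateMap
from .kernels import Kernel

__all__ = [
    "RandomTerm",
    "ModelSpec",
    "FitResult",
    "MODEL_NAMES",
    "build_model",
    "build_gs_kernel",
    "fit_gibbs",
    "blup_oracle",
    "predict",
    "estimate_blues",
    "variance_decomposition_h2",
    "genomic_repeatability",
]

EIG_TOL = 1e-10
DF0 = 5.0

MODEL_NAMES = (
    "M_1", "M_2", "M_3", "M_4", "M_5", "M_6", "M_7", "M_8",
    "GBLUP_D", "E_GBLUP_D", "GxE_pattern",
)


# ---------------------------------------------------------------------------
# specification
# ---------------------------------------------------------------------------
@dataclass
class RandomTerm:
    """One random term of a model.

    ``columns`` name the data column(s) carrying the term's level id.
    A single column with ``kernel=None`` is an iid (identity-kernel)
    term; with a kernel it is a correlated-level term.  Multiple columns
    with ``parts`` (one kernel per column) define a Hadamard
    reaction-norm term whose row covariance is the element-wise product
    of the per-column kernel expansions.
    """

    name: str
    columns: tuple
    kernel: Kernel | None = None
    parts: tuple | None = None

    def __post_init__(self):
        if isinstance(self.columns, str):
            self.columns = (self.columns,)
        else:
            self.columns = tuple(self.columns)
        if self.parts is not None:
            self.parts = tuple(self.parts)
            if len(self.parts) != len(self.columns):
                raise ValueError(f"term {self.name}: one kernel per column required")

    @property
    def is_hadamard(self) -> bool:
        return self.parts is not None


@dataclass
class ModelSpec:
    """Declarative model: response, fixed factors, random terms, residual."""

    name: str
    data: pd.DataFrame
    terms: list
    response: str = "value"
    fixed_factors: list = field(default_factory=list)
    fixed_covariates: list = field(default_factory=list)
    residual_col: str | None = None  # column defining residual variance groups

    def __post_init__(self):
        cols = set(self.data.columns)
        need = {self.response, *self.fixed_factors, *self.fixed_covariates}
        for t in self.terms:
            need.update(t.columns)
        if self.residual_col:
            need.add(self.residual_col)
        missing = need - cols
        if missing:
            raise ValueError(f"model {self.name}: data lacks columns {sorted(missing)}")
        for t in self.terms:
            kernels = t.parts if t.is_hadamard else ((t.kernel,) if t.kernel else ())
            for col, k in zip(t.columns, kernels or ()):
                if k is None:
                    continue
                levels = set(self.data[col].dropna().unique())
                absent = levels - set(k.labels)
                if absent:
                    raise ValueError(
                        f"term {t.name}: kernel lacks levels {sorted(map(str, absent))[:5]}"
                    )


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------
class _IIDTerm:
    """Identity-kernel term: conditionally independent level updates."""

    def __init__(self, term: RandomTerm, rows: pd.DataFrame):
        self.name = term.name
        self.column = term.columns[0]
        vals = rows[self.column]
        observed = pd.unique(vals.dropna())
        self.levels = list(observed)
        lut = {lv: i for i, lv in enumerate(self.levels)}
        self.codes = np.array([lut.get(v, -1) for v in vals], dtype=int)
        self.mask = self.codes >= 0
        self.m = len(self.levels)
        self.df = self.m
        self.u = np.zeros(self.m)
        self.acc = np.zeros(self.m)
        # centered variance scale: empirical variance contributed per unit
        # sigma2 (1 - sum n_l^2 / n^2 for an identity-kernel term)
        counts = np.bincount(self.codes[self.mask], minlength=self.m).astype(float)
        n_obs = max(self.mask.sum(), 1)
        self.var_scale = 1.0 - (counts**2).sum() / n_obs**2

    def update(self, r, w, sig2_t, rng):
        cm = self.codes[self.mask]
        r[self.mask] += self.u[cm]
        wm = w[self.mask]
        num = np.bincount(cm, weights=wm * r[self.mask], minlength=self.m)
        prec = np.bincount(cm, weights=wm, minlength=self.m) + 1.0 / sig2_t
        self.u = num / prec + rng.standard_normal(self.m) / np.sqrt(prec)
        r[self.mask] -= self.u[cm]

    def ssq(self) -> float:
        return float(self.u @ self.u)

    def accumulate(self):
        self.acc += self.u

    def finalize(self, n_samples):
        self.u_mean = self.acc / n_samples
        self.lut = {lv: i for i, lv in enumerate(self.levels)}

    def contribution(self) -> np.ndarray:
        out = np.zeros(len(self.codes))
        out[self.mask] = self.u_mean[self.codes[self.mask]]
        return out

    def effects(self) -> pd.Series:
        return pd.Series(self.u_mean, index=self.levels, name=self.name)

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        vals = rows[self.column]
        return np.array([self.u_mean[self.lut[v]] if v in self.lut else 0.0 for v in vals])


class _CorrTerm:
    """Correlated term sampled as a blocked draw in a whitened eigenbasis.

    With level kernel K (restricted to training-observed levels),
    incidence B and u = K^{1/2} Q q, the conditional precision of q is
    diagonal: Phi/sigma2_e + I/sigma2_t where Phi are the eigenvalues of
    K^{1/2} B'B K^{1/2}.  Hadamard terms are the special case B = I with
    K the row-expanded product kernel.
    """

    def __init__(self, term: RandomTerm, rows: pd.DataFrame):
        self.name = term.name
        self.term = term
        n = len(rows)
        if term.is_hadamard:
            C = np.ones((n, n))
            self.row_levels = []
            for col, k in zip(term.columns, term.parts):
                labs = list(rows[col])
                C *= k.loc(labs)
                self.row_levels.append(labs)
            d, V = eigh(C)
            keep = d > EIG_TOL * max(d.max(), 1e-300)
            d, V = d[keep], V[:, keep]
            self.T = V * np.sqrt(d)
            self.phi = d
            self._alpha_basis = (V, d)  # alpha = V (q / sqrt(d))
            self.var_scale = float(np.diag(C).mean() - C.mean())
        else:
            col = term.columns[0]
            vals = rows[col]
            self.levels = list(pd.unique(vals.dropna()))
            lut = {lv: i for i, lv in enumerate(self.levels)}
            codes = np.array([lut[v] for v in vals], dtype=int)
            m = len(self.levels)
            K = term.kernel.loc(self.levels)
            dk, Vk = eigh(K)
            dk = np.clip(dk, 0.0, None)
            Ksqrt = (Vk * np.sqrt(dk)) @ Vk.T
            counts = np.bincount(codes, minlength=m).astype(float)
            M = Ksqrt * counts @ Ksqrt  # Ksqrt diag(counts) Ksqrt
            phi, Q = eigh(M)
            keep = phi > EIG_TOL * max(phi.max(), 1e-300)
            phi, Q = phi[keep], Q[:, keep]
            U_lvl = Ksqrt @ Q  # level effects u = U_lvl q
            self.T = U_lvl[codes, :]
            self.phi = phi
            self._lvl_basis = U_lvl
            self._k_eig = (Vk, dk)
            self.codes = codes
            # centered variance scale of the row-expanded covariance
            n_rows = len(codes)
            d_bar = float(np.diag(K)[codes].mean())
            c_bar = float(counts @ K @ counts) / n_rows**2
            self.var_scale = d_bar - c_bar
        self.m = self.T.shape[1]
        self.df = self.m
        self.q = np.zeros(self.m)
        self.acc = np.zeros(self.m)

    def update(self, r, w, sig2_t, rng):
        sig2_e = 1.0 / w[0]  # homogeneous residual enforced upstream
        t = self.T.T @ r + self.phi * self.q
        prec = self.phi / sig2_e + 1.0 / sig2_t
        q_new = (t / sig2_e) / prec + rng.standard_normal(self.m) / np.sqrt(prec)
        r += self.T @ (self.q - q_new)
        self.q = q_new

    def ssq(self) -> float:
        return float(self.q @ self.q)

    def accumulate(self):
        self.acc += self.q

    def finalize(self, n_samples):
        self.q_mean = self.acc / n_samples
        if self.term.is_hadamard:
            V, d = self._alpha_basis
            self.alpha = V @ (self.q_mean / np.sqrt(d))
        else:
            self.u_lvl = self._lvl_basis @ self.q_mean
            Vk, dk = self._k_eig
            keep = dk > EIG_TOL * max(dk.max(), 1e-300)
            self.alpha = Vk[:, keep] @ ((Vk[:, keep].T @ self.u_lvl) / dk[keep])
            self.lut = {lv: i for i, lv in enumerate(self.levels)}

    def contribution(self) -> np.ndarray:
        return self.T @ self.q_mean

    def effects(self) -> pd.Series | None:
        if self.term.is_hadamard:
            return None
        return pd.Series(self.u_lvl, index=self.levels, name=self.name)

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        if self.term.is_hadamard:
            cross = np.ones((len(rows), len(self.alpha)))
            for col, k, labs in zip(self.term.columns, self.term.parts, self.row_levels):
                cross *= k.loc(list(rows[col]), labs)
            return cross @ self.alpha
        k_cross = self.term.kernel.loc(list(rows[self.term.columns[0]]), self.levels)
        return k_cross @ self.alpha


def _make_sampler(term: RandomTerm, rows: pd.DataFrame):
    if term.kernel is None and not term.is_hadamard:
        return _IIDTerm(term, rows)
    return _CorrTerm(term, rows)


# ---------------------------------------------------------------------------
# design helpers
# ---------------------------------------------------------------------------
def _design_fixed(
    data: pd.DataFrame,
    fixed_factors: list,
    categories: dict | None = None,
    fixed_covariates: list | None = None,
):
    n = len(data)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    cats = {}
    for f in fixed_factors:
        if categories is None:
            levels = list(pd.unique(data[f].dropna()))
        else:
            levels = categories[f]
        cats[f] = levels
        for lv in levels[1:]:  # first level is the reference
            cols.append((data[f] == lv).to_numpy(dtype=float))
            names.append(f"{f}[{lv}]")
    for c in fixed_covariates or []:
        cols.append(data[c].to_numpy(dtype=float))
        names.append(c)
    return np.column_stack(cols), names, cats


def _ess(x: np.ndarray) -> float:
    """Effective sample size via the initial-positive-sequence estimator."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * np.var(x))
    s = 0.0
    for lag in range(1, n // 2):
        pair = acf[lag] + acf[lag + 1] if lag + 1 < n else acf[lag]
        if pair < 0:
            break
        s += pair
    return float(n / (1.0 + 2.0 * s))


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------
@dataclass
class FitResult:
    """Posterior summaries of a Gibbs fit."""

    spec_name: str
    mu: float
    beta: pd.Series
    variance_components: pd.DataFrame  # sigma2, sd, explained, ess per term
    effects: dict  # term -> Series of posterior-mean level effects (or None)
    fitted: np.ndarray
    settings: dict
    samplers: list = field(repr=False, default_factory=list)
    fixed_categories: dict = field(repr=False, default_factory=dict)
    fixed_factors: list = field(repr=False, default_factory=list)
    fixed_covariates: list = field(repr=False, default_factory=list)
    var_chains: pd.DataFrame | None = field(repr=False, default=None)

    def shares(self) -> pd.Series:
        expl = self.variance_components["explained"]
        return expl / expl.sum()

    def to_dict(self) -> dict:
        return {
            "model": self.spec_name,
            "mu": self.mu,
            "beta": self.beta.to_dict(),
            "variance_components": self.variance_components.to_dict(),
            "settings": self.settings,
        }


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------
def fit_gibbs(
    spec: ModelSpec,
    nIter: int = 3000,
    burnIn: int = 500,
    thin: int = 5,
    seed: int = 1,
    fix_variances: dict | None = None,
    min_group_size: int = 10,
    log_every: int | None = None,
) -> FitResult:
    """Fit a model spec by Gibbs sampling.

    ``fix_variances`` maps term names (and optionally ``"residual"``) to
    values that are held fixed rather than sampled.  Residual variances
    are per-group when ``spec.residual_col`` is set; groups smaller than
    ``min_group_size`` share a pooled variance.
    """
    if nIter <= burnIn:
        raise ValueError("nIter must exceed burnIn")
    y = spec.data[spec.response].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("non-finite response values")
    n = len(y)
    rng = np.random.default_rng(seed)
    fix_variances = fix_variances or {}

    X, xnames, cats = _design_fixed(
        spec.data, spec.fixed_factors, fixed_covariates=spec.fixed_covariates
    )
    samplers = [_make_sampler(t, spec.data) for t in spec.terms]

    # residual grouping
    if spec.residual_col:
        gvals = spec.data[spec.residual_col]
        counts = gvals.value_counts()
        big = [g for g in counts.index if counts[g] >= min_group_size]
        glut = {g: i + 1 for i, g in enumerate(big)}  # group 0 pools the rest
        groups = np.array([glut.get(g, 0) for g in gvals], dtype=int)
        if not (groups == 0).any():
            groups -= 1  # no pooled group needed
            glut = {g: i for i, g in enumerate(big)}
        n_groups = groups.max() + 1
        group_labels = [None] * n_groups
        for g, i in glut.items():
            group_labels[i] = g
        if group_labels[0] is None:
            group_labels[0] = "(pooled)"
    else:
        groups = np.zeros(n, dtype=int)
        n_groups = 1
        group_labels = ["residual"]
    if n_groups > 1 and any(isinstance(s, _CorrTerm) for s in samplers):
        raise NotImplementedError(
            "heterogeneous residual variances are only supported with "
            "identity-kernel terms"
        )
    group_n = np.bincount(groups, minlength=n_groups).astype(float)

    var_y = float(np.var(y))
    vt = max(var_y, 1e-8) / (len(samplers) + 1)
    S0 = vt * (DF0 + 2.0) / DF0  # prior mode = vt
    floor = 1e-10 * max(var_y, 1e-8)

    sig2 = {s.name: fix_variances.get(s.name, vt) for s in samplers}
    fixed_terms = {name for name in fix_variances if name != "residual"}
    sig2_e = np.full(n_groups, fix_variances.get("residual", vt), dtype=float)
    res_fixed = "residual" in fix_variances

    beta = np.zeros(X.shape[1])
    beta[0] = y.mean()
    r = y - X @ beta
    XtX_template = None

    n_samples = 0
    beta_acc = np.zeros_like(beta)
    var_chain: dict[str, list] = {s.name: [] for s in samplers}
    for gl in group_labels:
        var_chain[f"residual[{gl}]"] = []

    for it in range(nIter):
        w = 1.0 / sig2_e[groups]
        # fixed effects (flat prior)
        r += X @ beta
        Xw = X * w[:, None]
        A = X.T @ Xw
        rhs = Xw.T @ r
        L = np.linalg.cholesky(A)
        mean = cho_solve((L, True), rhs)
        z = solve_triangular(L.T, rng.standard_normal(len(beta)), lower=False)
        beta = mean + z
        r -= X @ beta
        # random terms
        for s in samplers:
            s.update(r, w, sig2[s.name], rng)
        # term variances
        for s in samplers:
            if s.name in fixed_terms:
                continue
            sc = (DF0 * S0 + s.ssq()) / rng.chisquare(DF0 + s.df)
            sig2[s.name] = max(sc, floor)
        # residual variance(s)
        if not res_fixed:
            sse = np.bincount(groups, weights=r * r, minlength=n_groups)
            for g in range(n_groups):
                sig2_e[g] = max(
                    (DF0 * S0 + sse[g]) / rng.chisquare(DF0 + group_n[g]), floor
                )
        if log_every and (it + 1) % log_every == 0:
            trace = ", ".join(f"{k}={v:.3g}" for k, v in sig2.items())
            print(f"[gibbs {spec.name}] iter {it + 1}: {trace}, "
                  f"sig2_e={sig2_e.mean():.3g}")
        # accumulate
        if it >= burnIn and (it - burnIn) % thin == 0:
            n_samples += 1
            beta_acc += beta
            for s in samplers:
                s.accumulate()
                var_chain[s.name].append(sig2[s.name])
            for g, gl in enumerate(group_labels):
                var_chain[f"residual[{gl}]"].append(sig2_e[g])

    beta_mean = beta_acc / n_samples
    for s in samplers:
        s.finalize(n_samples)

    rows = []
    for s in samplers:
        chain = np.array(var_chain[s.name])
        rows.append(
            {
                "term": s.name,
                "sigma2": chain.mean(),
                "sd": chain.std(ddof=1) if len(chain) > 1 else 0.0,
                "explained": chain.mean() * s.var_scale,
                "ess": _ess(chain),
            }
        )
    for g, gl in enumerate(group_labels):
        chain = np.array(var_chain[f"residual[{gl}]"])
        rows.append(
            {
                "term": f"residual[{gl}]" if n_groups > 1 else "residual",
                "sigma2": chain.mean(),
                "sd": chain.std(ddof=1) if len(chain) > 1 else 0.0,
                "explained": chain.mean(),
                "ess": _ess(chain),
            }
        )
    vc = pd.DataFrame(rows).set_index("term")

    fitted = X @ beta_mean
    for s in samplers:
        fitted = fitted + s.contribution()

    return FitResult(
        spec_name=spec.name,
        mu=float(beta_mean[0]),
        beta=pd.Series(beta_mean, index=xnames),
        variance_components=vc,
        effects={s.name: s.effects() for s in samplers},
        fitted=fitted,
        settings={"nIter": nIter, "burnIn": burnIn, "thin": thin, "seed": seed},
        samplers=samplers,
        fixed_categories=cats,
        fixed_factors=list(spec.fixed_factors),
        fixed_covariates=list(spec.fixed_covariates),
        var_chains=pd.DataFrame(var_chain),
    )


def predict(fit: FitResult, spec: ModelSpec, new_rows: pd.DataFrame) -> np.ndarray:
    """Posterior-mean prediction for new design rows.

    Each term contributes its kernel cross-covariance projection of the
    trained effects; identity-kernel terms contribute exactly zero for
    unseen levels.  Fixed-factor levels unseen in training fall back to
    the reference level.
    """
    X, _, _ = _design_fixed(
        new_rows, fit.fixed_factors, fit.fixed_categories, fit.fixed_covariates
    )
    out = X @ fit.beta.to_numpy()
    for s in fit.samplers:
        out = out + s.predict(new_rows)
    return out


# ---------------------------------------------------------------------------
# closed-form oracle (Henderson MME via the marginal covariance)
# ---------------------------------------------------------------------------
def _row_cov(term: RandomTerm, rows: pd.DataFrame) -> np.ndarray:
    if term.is_hadamard:
        C = np.ones((len(rows), len(rows)))
        for col, k in zip(term.columns, term.parts):
            C *= k.loc(list(rows[col]))
        return C
    vals = list(rows[term.columns[0]])
    if term.kernel is None:
        arr = pd.factorize(pd.Series(vals))[0]
        return (arr[:, None] == arr[None, :]).astype(float)
    return term.kernel.loc(vals)


def blup_oracle(
    spec: ModelSpec,
    variances: dict,
    residual_variance: float | dict = 1.0,
) -> dict:
    """Exact GLS/BLUP solution with all variance components supplied.

    Returns fixed-effect estimates, per-term row contributions and level
    effects, and fitted values.  Raises on singular systems with a rank
    report.
    """
    data = spec.data
    y = data[spec.response].to_numpy(dtype=float)
    n = len(y)
    X, xnames, _ = _design_fixed(
        data, spec.fixed_factors, fixed_covariates=spec.fixed_covariates
    )
    covs = {}
    V = np.zeros((n, n))
    for t in spec.terms:
        if t.name not in variances:
            raise ValueError(f"variance for term {t.name!r} not supplied")
        covs[t.name] = _row_cov(t, data)
        V += variances[t.name] * covs[t.name]
    if isinstance(residual_variance, dict):
        rv = data[spec.residual_col].map(residual_variance).to_numpy(dtype=float)
        V[np.diag_indices(n)] += rv
    else:
        V[np.diag_indices(n)] += residual_variance
    try:
        cf = cho_factor(V)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular marginal covariance (rank {np.linalg.matrix_rank(V)} of {n})"
        ) from exc
    Vinv_y = cho_solve(cf, y)
    Vinv_X = cho_solve(cf, X)
    XtVX = X.T @ Vinv_X
    if np.linalg.matrix_rank(XtVX) < XtVX.shape[0]:
        raise np.linalg.LinAlgError(
            f"fixed-effect design rank {np.linalg.matrix_rank(XtVX)} "
            f"< {XtVX.shape[0]}"
        )
    beta = np.linalg.solve(XtVX, X.T @ Vinv_y)
    resid_proj = cho_solve(cf, y - X @ beta)
    contributions = {}
    level_effects = {}
    for t in spec.terms:
        contributions[t.name] = variances[t.name] * covs[t.name] @ resid_proj
        if not t.is_hadamard:
            col = t.columns[0]
            levels = list(pd.unique(data[col].dropna()))
            if t.kernel is None:
                Kzt = (np.array([[lv == v for v in data[col]] for lv in levels])
                       .astype(float))
            else:
                Kzt = t.kernel.loc(levels, list(data[col]))
            level_effects[t.name] = pd.Series(
                variances[t.name] * Kzt @ resid_proj, index=levels, name=t.name
            )
    fitted = X @ beta + sum(contributions.values())
    return {
        "beta": pd.Series(beta, index=xnames),
        "contributions": contributions,
        "effects": level_effects,
        "fitted": fitted,
    }


# ---------------------------------------------------------------------------
# BLUEs across environments (genotype fixed, environment random)
# ---------------------------------------------------------------------------
def estimate_blues(
    pheno: pd.DataFrame,
    dedup: DuplicateMap | None = None,
    nIter: int = 2000,
    burnIn: int = 400,
    seed: int = 1,
) -> pd.DataFrame:
    """Across-environment BLUEs of genotype performance.

    Duplicates are collapsed to canonical ids before fitting and the
    estimates are copied back to every member id.  Variance components of
    the all-random companion model are estimated by Gibbs sampling; the
    genotype-fixed solution is then obtained from one exact generalized
    least squares solve.  Requires the genotype-environment incidence
    graph to be connected after deduplication.
    """
    df = pheno.copy()
    if dedup is not None:
        df["genotype"] = [dedup.canonical(g) for g in df["genotype"]]

    genos = list(pd.unique(df["genotype"]))
    envs = list(pd.unique(df["environment"]))
    gi = df["genotype"].map({g: i for i, g in enumerate(genos)}).to_numpy()
    ei = df["environment"].map({e: i for i, e in enumerate(envs)}).to_numpy()

    adj = csr_matrix(
        (np.ones(len(df)), (gi, ei + len(genos))),
        shape=(len(genos) + len(envs), len(genos) + len(envs)),
    )
    n_comp, labels = connected_components(adj + adj.T, directed=False)
    used = np.unique(np.concatenate([labels[: len(genos)][np.unique(gi)],
                                     labels[len(genos):][np.unique(ei)]]))
    if len(used) > 1:
        comps = [
            [genos[i] for i in range(len(genos)) if labels[i] == c]
            for c in used
        ]
        raise ValueError(
            f"genotype-environment incidence graph has {len(used)} components: "
            + "; ".join(str(c[:5]) for c in comps)
        )

    spec = ModelSpec(
        name="BLUE_vc",
        data=df,
        terms=[RandomTerm("G", ("genotype",)), RandomTerm("E", ("environment",))],
    )
    vc = fit_gibbs(spec, nIter=nIter, burnIn=burnIn, seed=seed)
    sig2_e = float(vc.variance_components.loc["residual", "sigma2"])
    sig2_env = float(vc.variance_components.loc["E", "sigma2"])

    # exact genotype-fixed GLS given the environment variance ratio
    G = csr_matrix((np.ones(len(df)), (np.arange(len(df)), gi)),
                   shape=(len(df), len(genos)))
    Z = csr_matrix((np.ones(len(df)), (np.arange(len(df)), ei)),
                   shape=(len(df), len(envs)))
    lam = sig2_e / max(sig2_env, 1e-12)
    GtG = (G.T @ G).toarray()
    GtZ = (G.T @ Z).toarray()
    ZtZ = (Z.T @ Z).toarray() + lam * np.eye(len(envs))
    y = df["value"].to_numpy(dtype=float)
    lhs = np.block([[GtG, GtZ], [GtZ.T, ZtZ]])
    rhs = np.concatenate([G.T @ y, Z.T @ y])
    sol = np.linalg.lstsq(lhs, rhs, rcond=None)[0]
    blues = pd.Series(sol[: len(genos)], index=genos, name="blue")

    rows = [{"genotype": g, "blue": blues[g], "canonical": g} for g in genos]
    if dedup is not None:
        for member, canon in dedup.mapping.items():
            if canon in blues.index:
                rows.append({"genotype": member, "blue": blues[canon],
                             "canonical": canon})
    out = pd.DataFrame(rows).drop_duplicates("genotype").set_index("genotype")
    return out


# ---------------------------------------------------------------------------
# broad-sense heritability decomposition
# ---------------------------------------------------------------------------
def variance_decomposition_h2(
    pheno: pd.DataFrame,
    catalog,
    nIter: int = 3000,
    burnIn: int = 500,
    seed: int = 1,
) -> dict:
    """Variance decomposition with line/hybrid genetics and per-environment
    residuals, plus entry-mean broad-sense heritabilities.

    Hybrid genetic variance is split into female/male general combining
    ability and specific combining ability; all terms except material
    type and series are random.  H2 on an entry-mean basis uses the
    harmonic-mean number of environments per genotype and the mean of the
    per-environment residual variances.
    """
    cat = catalog.table.set_index("genotype_id")
    df = pheno.copy()
    df["type"] = df["genotype"].map(cat["material_type"])
    if df["type"].isna().any():
        missing = df.loc[df["type"].isna(), "genotype"].unique()
        raise ValueError(f"genotypes absent from catalog: {list(missing)[:5]}")
    is_line = df["type"] == "line"
    df["line"] = df["genotype"].where(is_line)
    df["gca_f"] = df["genotype"].map(cat["female_parent"])
    df["gca_m"] = df["genotype"].map(cat["male_parent"])
    df["sca"] = df["genotype"].where(~is_line)
    hyb_missing = (~is_line) & (df["gca_f"].isna() | df["gca_m"].isna())
    if hyb_missing.any():
        raise ValueError(
            f"hybrids lacking parent ids: "
            f"{list(df.loc[hyb_missing, 'genotype'].unique())[:5]}"
        )
    for col in ("line", "gca_f", "gca_m", "sca"):
        df[f"env_{col}"] = (df["environment"].astype(str) + ":" + df[col].astype(str)
                            ).where(df[col].notna())

    terms = [RandomTerm("Env", ("environment",)), RandomTerm("Line", ("line",))]
    has_hybrids = (~is_line).any()
    if has_hybrids:
        terms += [
            RandomTerm("GCA_F", ("gca_f",)),
            RandomTerm("GCA_M", ("gca_m",)),
            RandomTerm("SCA", ("sca",)),
        ]
    terms.append(RandomTerm("Env:Line", ("env_line",)))
    if has_hybrids:
        terms += [
            RandomTerm("Env:GCA_F", ("env_gca_f",)),
            RandomTerm("Env:GCA_M", ("env_gca_m",)),
            RandomTerm("Env:SCA", ("env_sca",)),
        ]
    fixed = ["type"] if has_hybrids else []
    if df["series"].nunique() > 1:
        fixed.append("series")
    spec = ModelSpec(
        name="H2", data=df, terms=terms, fixed_factors=fixed,
        residual_col="environment",
    )
    fit = fit_gibbs(spec, nIter=nIter, burnIn=burnIn, seed=seed)
    vc = fit.variance_components
    sig = vc["sigma2"]
    res_terms = [t for t in vc.index if t.startswith("residual")]
    sig_e = float(sig[res_terms].mean())

    def _harmonic_envs(sub):
        k = sub.groupby("genotype")["environment"].nunique()
        return len(k) / (1.0 / k).sum()

    out = {"variance_components": vc, "fit": fit}
    lines = df[is_line]
    if len(lines):
        ne = _harmonic_envs(lines)
        vl = float(sig["Line"])
        vle = float(sig["Env:Line"])
        out["H2_line"] = vl / (vl + vle / ne + sig_e / ne)
    if has_hybrids:
        hy = df[~is_line]
        ne = _harmonic_envs(hy)
        vg = float(sig["GCA_F"] + sig["GCA_M"] + sig["SCA"])
        vge = float(sig["Env:GCA_F"] + sig["Env:GCA_M"] + sig["Env:SCA"])
        out["H2_hybrid"] = vg / (vg + vge / ne + sig_e / ne)
    return out


def genomic_repeatability(
    pheno: pd.DataFrame,
    grm_a: Kernel,
    min_genotypes: int = 30,
    nIter: int = 2000,
    burnIn: int = 400,
    seed: int = 1,
) -> pd.Series:
    """Per-environment GBLUP variance ratio sigma2_a / (sigma2_a + sigma2_e).

    Environments with fewer than ``min_genotypes`` genotypes are skipped
    with a warning.  The additive variance enters on the explained scale
    (scaled by the mean diagonal of the realized additive kernel) so the
    ratio is a fraction of phenotypic variance.
    """
    out = {}
    for env, sub in pheno.groupby("environment"):
        if sub["genotype"].nunique() < min_genotypes:
            warnings.warn(f"environment {env!r}: fewer than {min_genotypes} "
                          "genotypes, skipped")
            continue
        spec = ModelSpec(
            name="repeatability",
            data=sub.reset_index(drop=True),
            terms=[RandomTerm("G_a", ("genotype",), kernel=grm_a)],
        )
        fit = fit_gibbs(spec, nIter=nIter, burnIn=burnIn, seed=seed)
        va = float(fit.variance_components.loc["G_a", "explained"])
        ve = float(fit.variance_components.loc["residual", "sigma2"])
        out[env] = va / (va + ve)
    return pd.Series(out, name="genomic_repeatability")


# ---------------------------------------------------------------------------
# model builder
# ---------------------------------------------------------------------------
def build_gs_kernel(gs_params: pd.DataFrame) -> Kernel:
    """Linear kernel over genotype-by-site levels from growth parameters.

    Parameter columns are standardized; the kernel is mean-diagonal
    normalized.  Levels are labeled ``genotype::site``.
    """
    pcols = [c for c in gs_params.columns if c not in ("genotype_id", "site")]
    if not pcols:
        raise ValueError("growth-parameter table has no parameter columns")
    labels = [f"{g}::{s}" for g, s in zip(gs_params["genotype_id"], gs_params["site"])]
    X = gs_params[pcols].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    K = X @ X.T
    return Kernel(labels, K / np.diag(K).mean(), "GS").jittered()


def build_model(
    name: str,
    pheno: pd.DataFrame,
    kernels: dict | None = None,
    env_meta: pd.DataFrame | None = None,
    gs_params: pd.DataFrame | None = None,
    gs_mode: str = "kernel",
) -> ModelSpec:
    """Construct the term stack of a named model.

    ``kernels`` maps kind names (GRM_a, GRM_d, GRM_aa, ERM_l, ERM_nl,
    YRM, SRM) to :class:`Kernel` objects; only the kernels the named
    model requires must be present.  ``env_meta`` (environment -> site,
    year) is required for M_7/M_8; ``gs_params`` for M_8.
    """
    kernels = kernels or {}

    def need(*kinds):
        for kind in kinds:
            if kind not in kernels:
                raise ValueError(f"model {name} requires kernel {kind!r}")
        return [kernels[k] for k in kinds]

    data = pheno.copy().reset_index(drop=True)
    g = ("genotype",)
    e = ("environment",)

    if name == "M_1" or name == "GxE_pattern":
        terms = [RandomTerm("E_I", e), RandomTerm("G_I", g)]
    elif name == "M_2":
        ka, kd, kaa = need("GRM_a", "GRM_d", "GRM_aa")
        terms = [
            RandomTerm("E_I", e),
            RandomTerm("G_a", g, kernel=ka),
            RandomTerm("G_d", g, kernel=kd),
            RandomTerm("G_aa", g, kernel=kaa),
        ]
    elif name in ("M_3", "M_4"):
        ka, kd, kaa, kl = need("GRM_a", "GRM_d", "GRM_aa", "ERM_l")
        terms = [
            RandomTerm("E_l", e, kernel=kl),
            RandomTerm("G_a", g, kernel=ka),
            RandomTerm("G_d", g, kernel=kd),
            RandomTerm("G_aa", g, kernel=kaa),
        ]
        if name == "M_4":
            terms.append(
                RandomTerm("GE_1", ("environment", "genotype"), parts=(kl, ka))
            )
    elif name in ("M_5", "M_6"):
        ka, kd, kaa, knl = need("GRM_a", "GRM_d", "GRM_aa", "ERM_nl")
        terms = [
            RandomTerm("E_nl", e, kernel=knl),
            RandomTerm("G_a", g, kernel=ka),
            RandomTerm("G_d", g, kernel=kd),
            RandomTerm("G_aa", g, kernel=kaa),
        ]
        if name == "M_6":
            terms.append(
                RandomTerm("GE_2", ("environment", "genotype"), parts=(knl, ka))
            )
    elif name in ("M_7", "M_8"):
        ka, kd, kl, kyr, ksr = need("GRM_a", "GRM_d", "ERM_l", "YRM", "SRM")
        if env_meta is None:
            raise ValueError(f"model {name} requires env_meta (site/year per environment)")
        meta = env_meta.copy()
        data["site"] = data["environment"].map(meta["site"])
        data["year"] = data["environment"].map(meta["year"])
        if data["site"].isna().any():
            raise ValueError("env_meta does not cover all environments")
        data["gs"] = data["genotype"].astype(str) + "::" + data["site"].astype(str)
        terms = [
            RandomTerm("S", ("site",), kernel=ksr),
            RandomTerm("Y", ("year",), kernel=kyr),
            RandomTerm("G_a", g, kernel=ka),
            RandomTerm("G_d", g, kernel=kd),
            RandomTerm("GY_a", ("year", "genotype"), parts=(kyr, ka)),
            RandomTerm("GE_1", ("environment", "genotype"), parts=(kl, ka)),
        ]
        if name == "M_7":
            terms.append(RandomTerm("GS_I", ("gs",)))
        else:
            if gs_params is None:
                raise ValueError("model M_8 requires the genotype-by-site "
                                 "parameter table (gs_params)")
            if gs_mode == "kernel":
                terms.append(RandomTerm("GS", ("gs",), kernel=build_gs_kernel(gs_params)))
            elif gs_mode == "covariate":
                pcols = [c for c in gs_params.columns
                         if c not in ("genotype_id", "site")]
                gp = gs_params.copy()
                gp["gs"] = gp["genotype_id"].astype(str) + "::" + gp["site"].astype(str)
                lut = gp.set_index("gs")[pcols]
                std = (lut - lut.mean()) / lut.std(ddof=0).replace(0.0, 1.0)
                covariates = []
                for c in pcols:
                    data[f"gs_{c}"] = data["gs"].map(std[c]).fillna(0.0)
                    covariates.append(f"gs_{c}")
                terms.append(RandomTerm("GS_I", ("gs",)))
                spec = ModelSpec(name=name, data=data, terms=terms,
                                 fixed_covariates=covariates)
                return spec
            else:
                raise ValueError("gs_mode must be 'kernel' or 'covariate'")
    elif name == "GBLUP_D":
        ka, kd = need("GRM_a", "GRM_d")
        terms = [RandomTerm("G_a", g, kernel=ka), RandomTerm("G_d", g, kernel=kd)]
    elif name == "E_GBLUP_D":
        ka, kd, kaa = need("GRM_a", "GRM_d", "GRM_aa")
        terms = [
            RandomTerm("G_a", g, kernel=ka),
            RandomTerm("G_d", g, kernel=kd),
            RandomTerm("G_aa", g, kernel=kaa),
        ]
    else:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")

    return ModelSpec(name=name, data=data, terms=terms)
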