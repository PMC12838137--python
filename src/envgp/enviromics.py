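"""Environment variables and environmental relationship kernels.

Daily weather records for each environment (a site-by-harvest-year
combination, season 1 October to 31 August) are aggregated to monthly
means of 27 weather variables, giving 297 environment variables (EVs)
per environment.  From the column-standardized EV matrix the package
builds

* ``ERM_l``  -- linear environment kernel ``EV EV' / mean(diag(EV EV'))``;
* ``ERM_nl`` -- exponential (Gaussian-family) kernel
  ``exp(-dist(EV)/theta)`` mean-diagonal normalized, ``dist`` Euclidean;
* ``YRM``/``SRM`` -- year and site kernels from EV rows averaged across
  sites (resp. years), normalized like ``ERM_l``.

``theta="auto"`` uses the median off-diagonal Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from ._trees import Dendrogram, average_linkage_tree
from .kernels import DistanceMatrix, Kernel

__all__ = [
    "SEASON_MONTHS",
    "EVMatrix",
    "monthly_evs",
    "build_erms",
    "cluster_environments",
]

#: growing-season months in order: October of the sowing year through
#: August of the harvest year (11 months; September is outside the season)
SEASON_MONTHS = [10, 11, 12, 1, 2, 3, 4, 5, 6, 7, 8]
MONTH_NAMES = {
    10: "Oct", 11: "Nov", 12: "Dec", 1: "Jan", 2: "Feb", 3: "Mar",
    4: "Apr", 5: "May", 6: "Jun", 7: "Jul", 8: "Aug",
}
_META_COLS = ("site", "year", "date")


@dataclass
class EVMatrix:
    """Environment-by-EV matrix (variables x months, variable-major).

    ``values`` holds natural-scale monthly means indexed by environment id
    (``site_year``); ``env_meta`` maps environments to site and harvest
    year.  ``scaled()`` returns the per-column z-scored view used by all
    kernel constructions.
    """

    values: pd.DataFrame
    env_meta: pd.DataFrame  # index env id; columns site, year

    def __post_init__(self):
        if not self.values.index.equals(self.env_meta.index):
            self.env_meta = self.env_meta.reindex(self.values.index)
            if self.env_meta.isna().any().any():
                raise ValueError("env_meta does not cover all environments")

    @property
    def environments(self) -> list:
        return list(self.values.index)

    @property
    def n_variables(self) -> int:
        return self.values.shape[1] // len(SEASON_MONTHS)

    def scaled(self) -> pd.DataFrame:
        """Column z-scores across environments (constant columns -> 0)."""
        mu = self.values.mean(axis=0)
        sd = self.values.std(axis=0, ddof=1)
        sd = sd.where(sd > 0, 1.0)
        return (self.values - mu) / sd

    def to_csv(self, path) -> None:
        out = self.env_meta.join(self.values)
        out.to_csv(path, index_label="environment")

    @classmethod
    def from_csv(cls, path) -> "EVMatrix":
        df = pd.read_csv(path, index_col="environment")
        meta = df[["site", "year"]]
        return cls(df.drop(columns=["site", "year"]), meta)


def monthly_evs(weather: pd.DataFrame) -> EVMatrix:
    """Monthly means of every weather variable per environment.

    ``weather`` needs columns ``site``, ``year`` (harvest year), ``date``
    (ISO-8601 or datetime) and one column per weather variable.  Every
    environment must cover all 11 season months; a missing month raises an
    error naming the environment and month.
    """
    w = weather.copy()
    w["date"] = pd.to_datetime(w["date"])
    if w.duplicated(subset=["site", "year", "date"]).any():
        raise ValueError("duplicate site x date rows in weather table")
    var_cols = [c for c in w.columns if c not in _META_COLS]
    if not var_cols:
        raise ValueError("no weather variable columns found")
    w["env"] = w["site"].astype(str) + "_" + w["year"].astype(str)
    w["month"] = w["date"].dt.month

    agg = w.groupby(["env", "month"])[var_cols].mean()
    rows, meta = {}, {}
    for env, sub in w.groupby("env"):
        present = set(agg.loc[env].index)
        for mo in SEASON_MONTHS:
            if mo not in present:
                raise ValueError(f"environment {env!r} lacks month {MONTH_NAMES[mo]}")
        vals = []
        for var in var_cols:
            for mo in SEASON_MONTHS:
                vals.append(agg.loc[(env, mo), var])
        rows[env] = vals
        meta[env] = (sub["site"].iloc[0], sub["year"].iloc[0])
    cols = [f"{var}_{MONTH_NAMES[mo]}" for var in var_cols for mo in SEASON_MONTHS]
    values = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    env_meta = pd.DataFrame.from_dict(meta, orient="index", columns=["site", "year"])
    return EVMatrix(values.sort_index(), env_meta.sort_index())


def _linear_kernel(x: np.ndarray, labels, kind: str) -> Kernel:
    k = x @ x.T
    md = np.diag(k).mean()
    if md <= 0:
        raise ValueError("degenerate EV matrix: zero mean diagonal")
    return Kernel(labels, k / md, kind).jittered()


def build_erms(
    ev: EVMatrix, theta: float | str = "auto"
) -> tuple[Kernel, Kernel, Kernel, Kernel]:
    """Linear/non-linear environment kernels plus year and site kernels."""
    if ev.values.shape[0] < 2:
        raise ValueError("need at least two environments")
    X = ev.scaled()
    labels = list(X.index)
    erm_l = _linear_kernel(X.to_numpy(), labels, "ERM_l")

    dist = squareform(pdist(X.to_numpy(), metric="euclidean"))
    if theta == "auto":
        off = dist[np.triu_indices_from(dist, k=1)]
        theta_val = float(np.median(off))
        if theta_val <= 0:
            theta_val = 1.0  # identical environments: any positive scale
    else:
        theta_val = float(theta)
        if theta_val <= 0:
            raise ValueError("theta must be positive")
    nl = np.exp(-dist / theta_val)
    erm_nl = Kernel(labels, nl / np.diag(nl).mean(), "ERM_nl").jittered()

    year_means = X.groupby(ev.env_meta["year"]).mean()
    site_means = X.groupby(ev.env_meta["site"]).mean()
    yrm = _linear_kernel(year_means.to_numpy(), list(year_means.index), "YRM")
    srm = _linear_kernel(site_means.to_numpy(), list(site_means.index), "SRM")
    return erm_l, erm_nl, yrm, srm


def cluster_environments(x) -> Dendrogram:
    """Average-linkage hierarchical clustering of environments.

    Accepts an :class:`EVMatrix` (Euclidean distances of the scaled EVs),
    a :class:`Kernel` (distance taken as ``1 - K`` with the diagonal
    zeroed) or a :class:`DistanceMatrix`.  The cophenetic matrix is kept
    on the returned tree for later comparison.
    """
    if isinstance(x, EVMatrix):
        labels = x.environments
        d = squareform(pdist(x.scaled().to_numpy(), metric="euclidean"))
    elif isinstance(x, Kernel):
        labels = x.labels
        d = np.clip(1.0 - x.values, 0.0, None)
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2.0
    elif isinstance(x, DistanceMatrix):
        labels, d = x.labels, x.values
    else:
        raise TypeError("expected EVMatrix, Kernel or DistanceMatrix")
    if len(labels) < 3:
        raise ValueError("need at least three environments to cluster")
    return average_linkage_tree(d, labels)
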