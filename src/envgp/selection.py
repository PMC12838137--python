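"""Reference-set curation and enviromically adapted selection gain.

A reference set is curated from across-environment BLUEs (a top fraction
plus a random fraction of the remainder).  For every environment the
"enviromically adapted" genotypes are the top fraction of the reference
set by predicted environment-specific yield.  Their selection gain over
the environment mean of the reference set is contrasted with the gain of
a fixed set of overall top performers; the difference (the "boost") is
converted to equivalent years of breeding progress with a genetic-gain
rate in Q per hectare per year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SelectionReport",
    "curate_reference_set",
    "enviromically_adapted",
    "selection_gain",
    "cluster_overlap",
]


def _top_ids(scores: pd.Series, n: int) -> list:
    """Deterministic top-n: sort by value descending, ties by id."""
    df = pd.DataFrame({"v": scores})
    df["id"] = df.index.astype(str)
    df = df.sort_values(["v", "id"], ascending=[False, True])
    return list(df.index[:n])


def curate_reference_set(
    blues: pd.Series,
    top_frac: float = 0.07,
    random_frac: float = 0.03,
    seed: int = 1,
) -> pd.DataFrame:
    """Top fraction plus a random fraction of the remaining genotypes.

    Returns a frame indexed by genotype with a ``subset`` column
    ('top' or 'random'); the two subsets are disjoint by construction.
    """
    if top_frac + random_frac >= 1.0 + 1e-12:
        raise ValueError("fractions must sum to < 1")
    n = len(blues)
    n_top = math.ceil(top_frac * n)
    n_rand = math.ceil(random_frac * n) if random_frac > 0 else 0
    if n_top + n_rand > n:
        n_rand = n - n_top
    if n_top < 1:
        raise ValueError("top_frac too small for the number of genotypes")
    top = _top_ids(blues, n_top)
    remainder = [g for g in blues.index if g not in set(top)]
    if n_rand > len(remainder):
        raise ValueError("not enough genotypes for the random subset")
    rng = np.random.default_rng(seed)
    rand = (
        list(np.array(remainder, dtype=object)[
            np.sort(rng.choice(len(remainder), size=n_rand, replace=False))
        ])
        if n_rand
        else []
    )
    return pd.DataFrame(
        {"subset": ["top"] * len(top) + ["random"] * len(rand)},
        index=pd.Index(top + rand, name="genotype"),
    )


def enviromically_adapted(
    predictions: pd.DataFrame, top_frac: float = 0.10
) -> dict:
    """Per-environment top fraction of genotypes by predicted yield.

    ``predictions`` is a complete genotype-by-environment matrix over the
    reference set.  Set sizes use ceiling rounding; ties break by
    genotype id.
    """
    if predictions.isna().any().any():
        raise ValueError("prediction matrix must be complete")
    n = math.ceil(top_frac * predictions.shape[0])
    return {
        env: _top_ids(predictions[env], n) for env in predictions.columns
    }


@dataclass
class SelectionReport:
    """Per-environment selection gains and their summary."""

    per_environment: pd.DataFrame
    rate: float

    @property
    def mean_gain_adapted(self) -> float:
        return float(self.per_environment["gain_adapted"].mean())

    @property
    def mean_gain_overall(self) -> float:
        return float(self.per_environment["gain_overall"].mean())

    @property
    def mean_boost(self) -> float:
        return float(self.per_environment["boost"].mean())

    @property
    def max_boost(self) -> float:
        return float(self.per_environment["boost"].max())

    def to_csv(self, path) -> None:
        self.per_environment.to_csv(path)


def selection_gain(
    predictions: pd.DataFrame,
    reference_ids,
    adapted_sets: dict,
    blues: pd.Series | None = None,
    overall_top_n: int = 50,
    rate: float = 0.32,
    rank_overall_by: str = "blue",
) -> SelectionReport:
    """Selection gain of adapted versus overall-top genotypes.

    Per environment, the gain of a set is its mean predicted yield minus
    the reference-set mean.  The overall set is the ``overall_top_n``
    genotypes ranked by across-environment BLUE (or by mean prediction
    with ``rank_overall_by="pred_mean"``).  ``boost`` is the adapted gain
    minus the overall gain; dividing by ``rate`` (Q/ha per year) converts
    it to equivalent years of breeding progress.
    """
    reference_ids = list(reference_ids)
    if overall_top_n > len(reference_ids):
        raise ValueError("overall_top_n exceeds the reference set size")
    pred = predictions.loc[reference_ids]
    if rank_overall_by == "blue":
        if blues is None:
            raise ValueError("ranking by BLUE requires the blues series")
        overall = _top_ids(blues.loc[reference_ids], overall_top_n)
    elif rank_overall_by == "pred_mean":
        overall = _top_ids(pred.mean(axis=1), overall_top_n)
    else:
        raise ValueError("rank_overall_by must be 'blue' or 'pred_mean'")

    rows = []
    for env in pred.columns:
        ref_mean = float(pred[env].mean())
        adapted_mean = float(pred.loc[adapted_sets[env], env].mean())
        overall_mean = float(pred.loc[overall, env].mean())
        gain_a = adapted_mean - ref_mean
        gain_o = overall_mean - ref_mean
        boost = gain_a - gain_o
        rows.append(
            {
                "environment": env,
                "reference_mean": ref_mean,
                "adapted_mean": adapted_mean,
                "overall_mean": overall_mean,
                "gain_adapted": gain_a,
                "gain_overall": gain_o,
                "boost": boost,
                "breeding_progress_years": boost / rate,
            }
        )
    return SelectionReport(pd.DataFrame(rows).set_index("environment"), rate)


def cluster_overlap(adapted_sets: dict, clusters) -> pd.DataFrame:
    """Mean pairwise adapted-set intersection within versus between clusters.

    Returns one row per cluster (within-cluster mean intersection size,
    NaN for singletons) plus an ``overall`` row with the grand within and
    between means.
    """
    assign = clusters.assignment if hasattr(clusters, "assignment") else clusters
    envs = [e for e in adapted_sets if e in assign.index]
    if not envs:
        raise ValueError("adapted sets and cluster assignment share no environments")
    sets = {e: set(adapted_sets[e]) for e in envs}
    within_by_cluster: dict = {}
    within_all, between_all = [], []
    for i, e1 in enumerate(envs):
        for e2 in envs[i + 1:]:
            inter = len(sets[e1] & sets[e2])
            if assign[e1] == assign[e2]:
                within_all.append(inter)
                within_by_cluster.setdefault(assign[e1], []).append(inter)
            else:
                between_all.append(inter)
    rows = []
    for c in sorted(assign.unique()):
        vals = within_by_cluster.get(c)
        rows.append(
            {
                "cluster": c,
                "n_environments": int((assign == c).sum()),
                "within_mean": float(np.mean(vals)) if vals else np.nan,
            }
        )
    rows.append(
        {
            "cluster": "overall",
            "n_environments": len(envs),
            "within_mean": float(np.mean(within_all)) if within_all else np.nan,
            "between_mean": float(np.mean(between_all)) if between_all else np.nan,
        }
    )
    return pd.DataFrame(rows)
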