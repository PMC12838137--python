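"""Cross-validation geometries and prediction-ability scoring.

Five validation designs are provided:

* five-fold CV over genotypes (duplicates collapsed to one canonical
  genotype, results stacked within a run before correlating);
* scenario-based validation holding out whole experimental series, with
  the training set stacking 1..6 series;
* the quadrant design: a fraction of genotypes and environments is
  declared "new", partitioning observed cells into quadrants -- cv1
  predicts known genotypes in known environments (sparse testing), cv2
  known genotypes in new environments, cv3 new genotypes in known
  environments, cv4 new genotypes in new environments;
* leave-one-environment-out with a minimum-connectivity requirement.

Prediction ability is the Pearson correlation between predicted and
observed values, computed per test-set environment and averaged.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genomics import DuplicateMap

__all__ = [
    "CVPlan",
    "CVResult",
    "fivefold_plan",
    "scenario_plan",
    "quadrant_plan",
    "loo_plan",
    "prediction_ability",
    "compare_models",
]

log = logging.getLogger("envgp.validation")


@dataclass
class CVPlan:
    """Train/test index sets for one validation geometry."""

    scheme: str
    runs: list  # one dict per run: {"run": id, "train": ..., "tests": {...}}
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.runs)


@dataclass
class CVResult:
    """Per-(run, cell, environment) prediction abilities for one model."""

    model: str
    records: pd.DataFrame  # run, cell, environment, r, rmse, n

    def per_run(self, cell: str | None = None) -> pd.Series:
        df = self.records
        if cell is not None:
            df = df[df["cell"] == cell]
        return df.groupby("run")["r"].mean()

    def mean_r(self, cell: str | None = None) -> float:
        return float(self.per_run(cell).mean())


# ---------------------------------------------------------------------------
# plans
# ---------------------------------------------------------------------------
def fivefold_plan(
    genotypes,
    dedup: DuplicateMap | None = None,
    runs: int = 10,
    n_folds: int = 5,
    seed: int = 1,
) -> CVPlan:
    """Random five-fold partitions of canonical genotypes, repeated.

    Genomic duplicates are treated as a single genotype so members of a
    duplicate group always share a fold.  Ten runs of five folds give the
    study's 50 model evaluations; within a run, fold predictions are
    stacked before correlating.
    """
    canon = sorted({dedup.canonical(g) if dedup else g for g in genotypes}, key=str)
    if len(canon) < n_folds:
        raise ValueError(f"need at least {n_folds} canonical genotypes")
    rng = np.random.default_rng(seed)
    plan_runs = []
    for r in range(runs):
        perm = rng.permutation(len(canon))
        folds = np.array_split(perm, n_folds)
        fold_sets = []
        for f in folds:
            test = [canon[i] for i in f]
            train = [canon[i] for i in perm if i not in set(f)]
            fold_sets.append({"train": train, "test": test})
        plan_runs.append({"run": r, "folds": fold_sets})
    return CVPlan("fivefold", plan_runs, seed, {"n_folds": n_folds})


def scenario_plan(
    series_map: dict,
    scenario: int,
    seed: int = 1,
    max_splits: int = 50,
) -> CVPlan:
    """Series-holdout splits with a training stack of ``scenario`` series.

    Every (train-subset, test-series) combination is a split; when the
    enumeration exceeds ``max_splits`` a seeded subsample is used.
    Genotypes keep their natural series distribution.
    """
    series = sorted(set(series_map.values()), key=str)
    if scenario < 1 or scenario >= len(series):
        raise ValueError(
            f"scenario must lie in 1..{len(series) - 1} for {len(series)} series"
        )
    splits = []
    for test_s in series:
        rest = [s for s in series if s != test_s]
        for combo in itertools.combinations(rest, scenario):
            splits.append({"train_series": list(combo), "test_series": test_s})
    if len(splits) > max_splits:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(splits), size=max_splits, replace=False)
        splits = [splits[i] for i in sorted(keep)]
    runs = []
    for i, sp in enumerate(splits):
        train = [g for g, s in series_map.items() if s in set(sp["train_series"])]
        test = [g for g, s in series_map.items()
                if s == sp["test_series"] and g not in set(train)]
        runs.append({"run": i, "train": train, "tests": {"holdout": test}, **sp})
    return CVPlan("scenario", runs, seed, {"scenario": scenario})


def quadrant_plan(
    pheno: pd.DataFrame,
    min_genotypes_per_env: int = 50,
    frac: float = 0.33,
    test_frac_q1: float = 0.20,
    runs: int = 50,
    seed: int = 1,
) -> CVPlan:
    """The four-quadrant cross-validation design (cv1..cv4).

    Environments with more than ``min_genotypes_per_env`` genotypes are
    retained.  Per run, ``round(frac * n)`` genotypes and environments
    are declared new; observed cells split into quadrants by the known /
    new status of their genotype and environment.  Training is a random
    ``1 - test_frac_q1`` share of quadrant 1; cv1 tests on the held-out
    share and cv2..cv4 on the full quadrants 2..4.  Indices refer to rows
    of the filtered phenotype table stored in ``meta["data"]``.
    """
    env_counts = pheno.groupby("environment")["genotype"].nunique()
    keep_envs = set(env_counts[env_counts > min_genotypes_per_env].index)
    data = pheno[pheno["environment"].isin(keep_envs)].reset_index(drop=True)
    genos = sorted(data["genotype"].unique(), key=str)
    envs = sorted(data["environment"].unique(), key=str)
    if len(genos) < 3 or len(envs) < 2:
        raise ValueError("too few genotypes/environments after filtering")
    n_new_g = int(round(frac * len(genos)))
    n_new_e = int(round(frac * len(envs)))
    if n_new_g < 1 or n_new_e < 1:
        raise ValueError("frac too small: no new genotypes or environments")
    rng = np.random.default_rng(seed)
    plan_runs = []
    g_arr = data["genotype"].to_numpy()
    e_arr = data["environment"].to_numpy()
    for r in range(runs):
        new_g = set(rng.choice(genos, size=n_new_g, replace=False))
        new_e = set(rng.choice(envs, size=n_new_e, replace=False))
        g_new = np.isin(g_arr, list(new_g))
        e_new = np.isin(e_arr, list(new_e))
        q1 = np.where(~g_new & ~e_new)[0]
        q2 = np.where(~g_new & e_new)[0]
        q3 = np.where(g_new & ~e_new)[0]
        q4 = np.where(g_new & e_new)[0]
        if min(len(q1), len(q2), len(q3), len(q4)) == 0:
            raise ValueError(f"run {r}: an empty quadrant; adjust frac or data")
        n_test1 = max(int(round(test_frac_q1 * len(q1))), 1)
        test1 = rng.choice(q1, size=n_test1, replace=False)
        train = np.setdiff1d(q1, test1)
        plan_runs.append(
            {
                "run": r,
                "train": train,
                "tests": {"cv1": np.sort(test1), "cv2": q2, "cv3": q3, "cv4": q4},
                "new_genotypes": new_g,
                "new_environments": new_e,
            }
        )
    return CVPlan("quadrant", plan_runs, seed, {"data": data, "frac": frac})


def loo_plan(pheno: pd.DataFrame, min_train_points: int = 3) -> CVPlan:
    """Leave-one-environment-out runs with a connectivity requirement.

    A genotype enters an environment's test set only if it has at least
    ``min_train_points`` records in the other environments; environments
    with no eligible test genotype are reported in ``meta["ineligible"]``.
    """
    envs = sorted(pheno["environment"].unique(), key=str)
    if len(envs) < 2:
        raise ValueError("need at least two environments")
    counts = pheno.groupby("genotype")["environment"].count()
    runs, ineligible = [], []
    data = pheno.reset_index(drop=True)
    for env in envs:
        in_env = data["environment"] == env
        test_ok = [
            i for i in np.where(in_env)[0]
            if counts[data.at[i, "genotype"]] - 1 >= min_train_points
        ]
        if not test_ok:
            ineligible.append(env)
            continue
        runs.append(
            {
                "run": env,
                "train": np.where(~in_env)[0],
                "tests": {env: np.array(test_ok)},
            }
        )
    if not runs:
        raise ValueError("no environment satisfies the LoO connectivity rule")
    return CVPlan("loo", runs, None, {"data": data, "ineligible": ineligible})


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------
def prediction_ability(
    pred,
    obs,
    environments=None,
    grouping: str = "per-environment",
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Pearson r and RMSE between predictions and observations.

    With ``grouping="per-environment"`` one row per environment is
    returned (groups with fewer than ``min_pairs`` pairs or degenerate
    variance are skipped and logged); ``"stacked"`` gives a single row.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("pred and obs must be aligned")
    if grouping == "stacked" or environments is None:
        groups = {"all": np.arange(len(pred))}
    else:
        env = np.asarray(environments)
        groups = {e: np.where(env == e)[0] for e in pd.unique(env)}
    rows = []
    for name, idx in groups.items():
        if len(idx) < min_pairs:
            log.info("group %r skipped: only %d pairs", name, len(idx))
            continue
        p, o = pred[idx], obs[idx]
        if np.std(o) == 0:
            log.info("group %r skipped: degenerate observations", name)
            continue
        if np.std(p) == 0:
            # constant predictions carry no ranking information: by the
            # study's reporting convention this counts as ability 0
            log.info("group %r: constant predictions, recording r = 0", name)
            r = 0.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = float(np.corrcoef(p, o)[0, 1])
        rows.append(
            {
                "environment": name,
                "r": r,
                "rmse": float(np.sqrt(np.mean((p - o) ** 2))),
                "n": len(idx),
            }
        )
    return pd.DataFrame(rows, columns=["environment", "r", "rmse", "n"])


def compare_models(results: list[CVResult], baseline: str, cell: str | None = None) -> pd.DataFrame:
    """Pairwise run-matched comparison of models against a baseline.

    Reports the mean percent difference of per-run mean prediction
    ability, the paired t statistic, the two-sided p value and a
    significance flag at 0.05.
    """
    by_label = {res.model: res.per_run(cell) for res in results}
    if baseline not in by_label:
        raise ValueError(f"baseline {baseline!r} not among results")
    base = by_label[baseline]
    rows = []
    for label, series in by_label.items():
        if label == baseline:
            continue
        joined = pd.concat([base, series], axis=1, keys=["base", "model"]).dropna()
        if len(joined) != len(base) or len(joined) != len(series):
            raise ValueError(f"runs of {label!r} are not paired with the baseline")
        diff = joined["model"] - joined["base"]
        pct = 100.0 * (joined["model"].mean() - joined["base"].mean()) / abs(
            joined["base"].mean()
        )
        if np.allclose(diff, diff.iloc[0]):
            # constant difference: t-test degenerate; report closed-form
            t = np.inf if diff.iloc[0] != 0 else 0.0
            p = 0.0 if diff.iloc[0] != 0 else 1.0
        else:
            t, p = stats.ttest_rel(joined["model"], joined["base"])
        rows.append(
            {
                "model": label,
                "baseline": baseline,
                "pct_difference": float(pct),
                "t": float(t),
                "p": float(p),
                "significant": bool(p < 0.05),
            }
        )
    return pd.DataFrame(rows)
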