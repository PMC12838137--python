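"""Core-set selection, G-by-E pattern extraction, environment clustering
and environment-variable importance.

The G-by-E pattern of a genotype panel is what remains of its predicted
performance after genotype and environment main effects are removed: a
genotype-by-environment residual matrix.  Environments are clustered on
the first two principal coordinates of the Euclidean distances between
the pattern columns (K-means), and a gradient-boosted classifier maps
environment variables onto the clusters to rank the variables by gain
importance.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import accuracy_score, silhouette_score
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split

from ._trees import Dendrogram
from .enviromics import EVMatrix, MONTH_NAMES, SEASON_MONTHS
from .genomics import DistanceMatrix
from .mixedmodel import ModelSpec, RandomTerm, fit_gibbs

__all__ = [
    "GxEPatternMatrix",
    "ClusterAssignment",
    "select_core_set",
    "extract_gxe_patterns",
    "cluster_gxe",
    "cophenetic_correlation",
    "ev_importance",
    "ImportanceResult",
]


# ---------------------------------------------------------------------------
# core set
# ---------------------------------------------------------------------------
def select_core_set(d: DistanceMatrix, n: int = 500) -> list:
    """Greedy diversity-maximizing subset of genotypes.

    Starts from the most distant pair and repeatedly adds the genotype
    whose distance to its nearest already-selected entry is largest
    (maximizing the mean entry-to-nearest-entry distance of the growing
    set).  Deterministic: ties break by label.
    """
    if n < 2:
        raise ValueError("core set size must be at least 2")
    if n > d.n:
        raise ValueError(f"core set size {n} exceeds {d.n} genotypes")
    vals = d.values
    order = np.argsort([str(lab) for lab in d.labels])  # tie-break order
    rank = np.empty(d.n, dtype=int)
    rank[order] = np.arange(d.n)

    iu = np.unravel_index(np.argmax(vals), vals.shape)
    selected = [iu[0], iu[1]]
    in_set = np.zeros(d.n, dtype=bool)
    in_set[selected] = True
    nearest = np.minimum(vals[:, selected[0]], vals[:, selected[1]])
    while len(selected) < n:
        cand = np.where(~in_set)[0]
        scores = nearest[cand]
        best = cand[np.lexsort((rank[cand], -scores))][0]
        selected.append(best)
        in_set[best] = True
        nearest = np.minimum(nearest, vals[:, best])
    return [d.labels[i] for i in selected]


# ---------------------------------------------------------------------------
# G x E patterns
# ---------------------------------------------------------------------------
@dataclass
class GxEPatternMatrix:
    """Genotype-by-environment interaction residual matrix."""

    values: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        sd = self.values.to_numpy().std()
        # absolute floor keeps the check meaningful for all-zero patterns
        tol = 1e-6 * sd + 1e-9
        if np.abs(self.values.mean(axis=0)).max() > tol:
            raise ValueError("pattern column means are not zero")
        if np.abs(self.values.mean(axis=1)).max() > tol:
            raise ValueError("pattern row means are not zero")

    @property
    def environments(self) -> list:
        return list(self.values.columns)


def extract_gxe_patterns(
    predictions: pd.DataFrame,
    nIter: int = 1500,
    burnIn: int = 300,
    seed: int = 1,
) -> GxEPatternMatrix:
    """Residual G-by-E patterns from a complete prediction matrix.

    Fits ``yhat = mu + genotype + environment + e`` with independent
    normal random effects and takes the residuals, which are then
    orthogonalized exactly against the genotype and environment indicator
    spaces (random-effect shrinkage would otherwise leave a trace of the
    main effects in the residual).  The result is invariant to adding a
    constant to all predictions.
    """
    if predictions.isna().any().any():
        raise ValueError("prediction matrix has gaps: predict them first "
                         "(e.g. with model M_6)")
    long = predictions.stack().rename("value").reset_index()
    long.columns = ["genotype", "environment", "value"]
    spec = ModelSpec(
        name="GxE_pattern",
        data=long,
        terms=[RandomTerm("G_I", ("genotype",)), RandomTerm("E_I", ("environment",))],
    )
    fit = fit_gibbs(spec, nIter=nIter, burnIn=burnIn, seed=seed)
    resid = long["value"].to_numpy() - fit.fitted
    mat = pd.DataFrame(
        resid.reshape(predictions.shape),
        index=predictions.index,
        columns=predictions.columns,
    )
    # exact removal of any remaining main-effect structure
    mat = mat.sub(mat.mean(axis=1), axis=0)
    mat = mat.sub(mat.mean(axis=0), axis=1)
    mat = mat.sub(mat.to_numpy().mean())
    digest = hashlib.sha256(
        np.ascontiguousarray(predictions.to_numpy()).tobytes()
    ).hexdigest()[:12]
    return GxEPatternMatrix(
        mat, {"model": "GxE_pattern", "training_hash": digest,
              "mcmc": fit.settings}
    )


# ---------------------------------------------------------------------------
# environment clustering on patterns
# ---------------------------------------------------------------------------
@dataclass
class ClusterAssignment:
    """K-means clustering of environments on G-by-E pattern coordinates."""

    assignment: pd.Series  # environment -> cluster id
    k: int
    sse: float
    silhouette: float
    coords: pd.DataFrame
    scan: pd.DataFrame | None = None  # k, sse, silhouette over the scan

    def sizes(self) -> pd.Series:
        return self.assignment.value_counts().sort_index()


def cluster_gxe(
    patterns: GxEPatternMatrix,
    k: int | str = "auto",
    min_size: int = 3,
    n_init: int = 50,
    seed: int = 1,
) -> ClusterAssignment:
    """Cluster environments by their G-by-E pattern columns.

    Euclidean distances between environment columns feed a classical
    principal-coordinate analysis; K-means (k-means++ with ``n_init``
    restarts) runs on the first two coordinates.  ``k="auto"`` scans
    2..n/min_size and picks the best mean silhouette subject to every
    cluster holding at least ``min_size`` environments; the SSE elbow
    curve is reported alongside.
    """
    from .genomics import pcoa

    envs = patterns.environments
    if len(envs) < 2 * min_size:
        raise ValueError(f"need at least {2 * min_size} environments")
    X = patterns.values.to_numpy().T  # environments x genotypes
    d = DistanceMatrix(envs, squareform(pdist(X, metric="euclidean")))
    coords, _ = pcoa(d, k=2)
    C = coords.to_numpy()

    def run_kmeans(kk):
        km = KMeans(n_clusters=kk, init="k-means++", n_init=n_init,
                    random_state=seed)
        lab = km.fit_predict(C)
        sil = silhouette_score(C, lab) if kk > 1 else np.nan
        return lab, float(km.inertia_), float(sil)

    if k == "auto":
        k_max = len(envs) // min_size
        if k_max < 2:
            raise ValueError("min_size too large for the number of environments")
        best = None
        scan_rows = []
        for kk in range(2, k_max + 1):
            lab, sse, sil = run_kmeans(kk)
            ok = np.bincount(lab).min() >= min_size
            scan_rows.append({"k": kk, "sse": sse, "silhouette": sil,
                              "min_size_ok": ok})
            if ok and (best is None or sil > best[3]):
                best = (kk, lab, sse, sil)
        if best is None:
            raise ValueError(
                f"no k in 2..{k_max} yields clusters of size >= {min_size}"
            )
        kk, lab, sse, sil = best
        scan = pd.DataFrame(scan_rows)
    else:
        kk = int(k)
        if kk < 2:
            raise ValueError("k must be at least 2")
        lab, sse, sil = run_kmeans(kk)
        if np.bincount(lab).min() < min_size:
            raise ValueError(f"k={kk} produces a cluster smaller than {min_size}")
        scan = None
    return ClusterAssignment(
        assignment=pd.Series(lab, index=envs, name="cluster"),
        k=kk, sse=sse, silhouette=sil, coords=coords, scan=scan,
    )


def cophenetic_correlation(tree_a: Dendrogram, tree_b: Dendrogram) -> float:
    """Pearson correlation of two trees' cophenetic distances.

    Both trees must share the same leaf set; leaves are aligned by label.
    The correlation is on raw cophenetic heights, so it is invariant only
    to linear rescaling of a tree's heights.
    """
    if set(map(str, tree_a.labels)) != set(map(str, tree_b.labels)):
        raise ValueError("trees have different leaf sets")
    order_a = {str(lab): i for i, lab in enumerate(tree_a.labels)}
    idx = [order_a[str(lab)] for lab in tree_b.labels]
    A = tree_a.cophenetic[np.ix_(idx, idx)]
    B = tree_b.cophenetic
    iu = np.triu_indices_from(A, k=1)
    return float(np.corrcoef(A[iu], B[iu])[0, 1])


# ---------------------------------------------------------------------------
# EV importance via gradient boosting
# ---------------------------------------------------------------------------
@dataclass
class ImportanceResult:
    """Gain-based EV importances and classification accuracy."""

    accuracy: float
    per_column: pd.Series
    per_variable: pd.Series
    per_month: pd.Series
    long: pd.DataFrame  # variable, month, gain_scaled
    accuracy_splits: list = field(default_factory=list)


def ev_importance(
    ev: EVMatrix,
    clusters: ClusterAssignment,
    learning_rate: float = 0.1,
    n_estimators: int = 3000,
    max_depth: int = 30,
    n_splits: int = 5,
    n_repeats: int = 3,
    random_state: int = 1,
    early_stopping_rounds: int = 100,
    scale: str = "max",
) -> ImportanceResult:
    """Explain environment clusters with environment variables.

    A gradient-boosted tree classifier (multiclass log-loss) is first
    evaluated by repeated stratified K-fold accuracy, then refit on an
    80/20 train/validation split with early stopping to extract
    gain-based feature importances.  ``scale="max"`` maps gains to
    [0, 1]; ``scale="normalize"`` makes them sum to 1.  Gains are also
    aggregated per weather variable (mean over months) and per month.
    """
    import xgboost as xgb

    env_order = [e for e in ev.environments if e in clusters.assignment.index]
    X = ev.scaled().loc[env_order]
    y_raw = clusters.assignment.loc[env_order]
    classes, y = np.unique(y_raw, return_inverse=True)
    sizes = np.bincount(y)
    if sizes.min() < n_splits:
        raise ValueError(
            f"smallest cluster has {sizes.min()} environments < n_splits="
            f"{n_splits}; merge clusters, raise min_size or lower n_splits"
        )

    params = dict(
        learning_rate=learning_rate,
        n_estimators=n_estimators,
        max_depth=max_depth,
        verbosity=0,
    )
    # multiclass log-loss; xgboost's binary special case uses plain logloss
    metric = "mlogloss" if len(classes) > 2 else "logloss"
    rskf = RepeatedStratifiedKFold(
        n_splits=n_splits, n_repeats=n_repeats, random_state=random_state
    )
    accs = []
    Xv = X.to_numpy()
    for tr, te in rskf.split(Xv, y):
        clf = xgb.XGBClassifier(**params)
        clf.fit(Xv[tr], y[tr])
        accs.append(accuracy_score(y[te], clf.predict(Xv[te])))
    accuracy = float(np.mean(accs))

    X_tr, X_va, y_tr, y_va = train_test_split(
        Xv, y, test_size=0.2, random_state=random_state, stratify=y
    )
    final = xgb.XGBClassifier(
        **params,
        eval_metric=metric,
        early_stopping_rounds=early_stopping_rounds,
    )
    final.fit(X_tr, y_tr, eval_set=[(X_tr, y_tr), (X_va, y_va)], verbose=False)
    booster = final.get_booster()
    gain = booster.get_score(importance_type="gain")
    cols = list(X.columns)
    raw = np.zeros(len(cols))
    for feat, val in gain.items():
        # xgboost names features f0, f1, ... when fit on arrays
        raw[int(feat[1:])] = val
    if scale == "max":
        scaled = raw / raw.max() if raw.max() > 0 else raw
    elif scale == "normalize":
        scaled = raw / raw.sum() if raw.sum() > 0 else raw
    else:
        raise ValueError("scale must be 'max' or 'normalize'")
    per_column = pd.Series(scaled, index=cols, name="gain_scaled")

    month_names = [MONTH_NAMES[m] for m in SEASON_MONTHS]
    rows = []
    for col, val in per_column.items():
        var, month = col.rsplit("_", 1)
        rows.append({"variable": var, "month": month, "gain_scaled": val})
    long = pd.DataFrame(rows)
    long["month"] = pd.Categorical(long["month"], categories=month_names,
                                   ordered=True)
    per_variable = (
        long.groupby("variable", observed=True)["gain_scaled"].mean()
        .sort_values(ascending=False)
    )
    per_month = long.groupby("month", observed=True)["gain_scaled"].mean()
    return ImportanceResult(
        accuracy=accuracy,
        per_column=per_column,
        per_variable=per_variable,
        per_month=per_month,
        long=long,
        accuracy_splits=accs,
    )
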