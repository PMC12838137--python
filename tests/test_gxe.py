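"""Core-set selection, G-by-E patterns, clustering and EV importance."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from envgp.enviromics import EVMatrix, MONTH_NAMES, SEASON_MONTHS
from envgp.gxe import (
    cluster_gxe,
    cophenetic_correlation,
    ev_importance,
    extract_gxe_patterns,
    select_core_set,
)
from envgp.kernels import DistanceMatrix


def _planted_patterns(rng, n_g=50, n_e=30, k=3, strength=3.0, noise=0.5):
    truth = np.repeat(np.arange(k), n_e // k)
    load = rng.normal(0, 1, (n_g, k))
    pat = load[:, truth] * strength + rng.normal(0, noise, (n_g, n_e))
    pred = pd.DataFrame(
        80 + rng.normal(0, 2, n_g)[:, None] + rng.normal(0, 2, n_e)[None, :] + pat,
        index=[f"G{i}" for i in range(n_g)],
        columns=[f"E{j}" for j in range(n_e)],
    )
    return pred, truth


def _fake_ev(rng, n_env, prefix="E"):
    var_names = [f"var{v:02d}" for v in range(27)]
    cols = [f"{v}_{MONTH_NAMES[m]}" for v in var_names for m in SEASON_MONTHS]
    df = pd.DataFrame(rng.normal(0, 1, (n_env, 297)),
                      index=[f"{prefix}{j}" for j in range(n_env)], columns=cols)
    meta = pd.DataFrame({"site": "S1", "year": np.arange(n_env)}, index=df.index)
    return EVMatrix(df, meta)


class TestCoreSet:
    def _clustered_dm(self, rng):
        pts = np.vstack([rng.normal(0, 0.1, (5, 2)), rng.normal(5, 0.1, (5, 2))])
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        return DistanceMatrix([f"g{i}" for i in range(10)], D)

    def test_two_clusters_covered(self, rng):
        dm = self._clustered_dm(rng)
        sel = select_core_set(dm, 2)
        sides = {int(g[1:]) < 5 for g in sel}
        assert sides == {True, False}

    def test_full_set_is_identity(self, rng):
        dm = self._clustered_dm(rng)
        assert set(select_core_set(dm, 10)) == set(dm.labels)

    def test_beats_random_subsets(self, rng):
        n = 40
        pts = rng.normal(0, 1, (n, 5))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        dm = DistanceMatrix([f"g{i}" for i in range(n)], D)
        sel = select_core_set(dm, 8)
        idx = [dm.labels.index(g) for g in sel]

        def mean_nn(ix):
            sub = D[np.ix_(ix, ix)].copy()
            np.fill_diagonal(sub, np.inf)
            return sub.min(axis=1).mean()

        ours = mean_nn(idx)
        rand_scores = [
            mean_nn(rng.choice(n, 8, replace=False)) for _ in range(100)
        ]
        assert ours >= max(rand_scores)

    def test_too_small_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            select_core_set(self._clustered_dm(rng), 1)


class TestGxEPatterns:
    def test_additive_matrix_gives_zero_residuals(self, rng):
        g = rng.normal(0, 2, 40)
        e = rng.normal(0, 2, 12)
        pred = pd.DataFrame(
            50 + g[:, None] + e[None, :],
            index=[f"G{i}" for i in range(40)],
            columns=[f"E{j}" for j in range(12)],
        )
        pats = extract_gxe_patterns(pred, seed=1)
        sd = pred.to_numpy().std()
        assert np.abs(pats.values.to_numpy()).max() < 1e-6 * sd

    def test_rank_one_interaction_recovered(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(0, 1, 12)
        inter = np.outer(a - a.mean(), b - b.mean())
        pred = pd.DataFrame(
            50 + rng.normal(0, 2, 40)[:, None] + rng.normal(0, 2, 12)[None, :]
            + 3 * inter,
            index=[f"G{i}" for i in range(40)], columns=[f"E{j}" for j in range(12)],
        )
        pats = extract_gxe_patterns(pred, seed=1)
        r = np.corrcoef(pats.values.to_numpy().ravel(), inter.ravel())[0, 1]
        assert abs(r) > 0.95

    def test_constant_shift_invariant(self, rng):
        pred, _ = _planted_patterns(rng)
        p1 = extract_gxe_patterns(pred, seed=1)
        p2 = extract_gxe_patterns(pred + 100.0, seed=1)
        assert np.allclose(p1.values, p2.values, atol=1e-6)

    def test_residuals_orthogonal_to_main_effect_spaces(self, rng):
        pred, _ = _planted_patterns(rng)
        pats = extract_gxe_patterns(pred, seed=1)
        assert np.abs(pats.values.mean(axis=0)).max() < 1e-10
        assert np.abs(pats.values.mean(axis=1)).max() < 1e-10

    def test_gaps_rejected(self, rng):
        pred, _ = _planted_patterns(rng)
        pred.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="predict"):
            extract_gxe_patterns(pred)


class TestClusterGxE:
    def test_planted_partition_recovered_over_seeds(self, rng):
        hits = []
        for seed in range(20):
            r = np.random.default_rng(100 + seed)
            pred, truth = _planted_patterns(r)
            pats = extract_gxe_patterns(pred, seed=1)
            ca = cluster_gxe(pats, k=3, min_size=3, seed=seed)
            hits.append(adjusted_rand_score(truth, ca.assignment.to_numpy()))
        assert np.mean(hits) >= 0.8

    def test_auto_k_finds_planted_k(self, rng):
        pred, truth = _planted_patterns(rng, strength=4.0, noise=0.3)
        pats = extract_gxe_patterns(pred, seed=1)
        ca = cluster_gxe(pats, k="auto", min_size=3, seed=1)
        assert ca.k == 3
        assert ca.scan is not None and {"k", "sse", "silhouette"} <= set(ca.scan)

    def test_k_one_rejected(self, rng):
        pred, _ = _planted_patterns(rng)
        pats = extract_gxe_patterns(pred, seed=1)
        with pytest.raises(ValueError, match="at least 2"):
            cluster_gxe(pats, k=1)

    def test_duplicated_environments_cocluster(self, rng):
        pred, _ = _planted_patterns(rng)
        pred["E1"] = pred["E0"]  # identical columns
        pats = extract_gxe_patterns(pred, seed=1)
        ca = cluster_gxe(pats, k=3, min_size=3, seed=1)
        assert ca.assignment["E0"] == ca.assignment["E1"]

    def test_seed_stability(self, rng):
        pred, _ = _planted_patterns(rng, strength=4.0, noise=0.3)
        pats = extract_gxe_patterns(pred, seed=1)
        parts = [cluster_gxe(pats, k=3, seed=s).assignment for s in range(6)]
        agreements = [
            adjusted_rand_score(parts[i], parts[j])
            for i in range(6) for j in range(i + 1, 6)
        ]
        assert np.mean(np.array(agreements) == 1.0) >= 0.9


class TestCopheneticCorrelation:
    def test_independent_trees_near_zero(self, rng):
        from envgp._trees import average_linkage_tree

        n = 40
        labels = [f"L{i}" for i in range(n)]
        d1 = np.abs(rng.normal(0, 1, (n, n)));  d1 = (d1 + d1.T) / 2
        np.fill_diagonal(d1, 0)
        d2 = np.abs(rng.normal(0, 1, (n, n)));  d2 = (d2 + d2.T) / 2
        np.fill_diagonal(d2, 0)
        t1 = average_linkage_tree(d1, labels)
        t2 = average_linkage_tree(d2, labels)
        assert abs(cophenetic_correlation(t1, t2)) < 0.2

    def test_leaf_mismatch_rejected(self, rng):
        from envgp._trees import average_linkage_tree

        d = np.ones((4, 4)) - np.eye(4)
        t1 = average_linkage_tree(d, ["a", "b", "c", "d"])
        t2 = average_linkage_tree(d, ["a", "b", "c", "x"])
        with pytest.raises(ValueError, match="leaf"):
            cophenetic_correlation(t1, t2)

    def test_label_alignment_not_order(self, rng):
        from envgp._trees import average_linkage_tree

        n = 10
        d = np.abs(rng.normal(0, 1, (n, n)));  d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        labels = [f"L{i}" for i in range(n)]
        perm = rng.permutation(n)
        t1 = average_linkage_tree(d, labels)
        t2 = average_linkage_tree(d[np.ix_(perm, perm)],
                                  [labels[i] for i in perm])
        assert cophenetic_correlation(t1, t2) == pytest.approx(1.0)


class TestEVImportance:
    def _clustered_case(self, rng, n_env=40):
        ev = _fake_ev(rng, n_env)
        driver = ev.values.iloc[:, 40]
        labels = pd.Series((driver > driver.median()).astype(int),
                           index=ev.values.index, name="cluster")

        class _CA:
            assignment = labels

        return ev, _CA()

    def test_planted_driver_ranks_first(self, rng):
        ev, ca = self._clustered_case(rng)
        imp = ev_importance(ev, ca, n_estimators=300)
        assert imp.per_column.idxmax() == ev.values.columns[40]
        assert imp.accuracy > 0.8

    def test_random_labels_near_chance(self, rng):
        ev = _fake_ev(rng, 40)
        labels = pd.Series(rng.integers(0, 2, 40), index=ev.values.index)

        class _CA:
            assignment = labels

        imp = ev_importance(ev, _CA(), n_estimators=100)
        # chance level 1/2; binomial CI over 8-environment test folds
        assert abs(imp.accuracy - 0.5) < 0.25

    def test_normalized_scores_sum_to_one(self, rng):
        ev, ca = self._clustered_case(rng)
        imp = ev_importance(ev, ca, n_estimators=100, scale="normalize")
        assert imp.per_column.sum() == pytest.approx(1.0)

    def test_small_cluster_guidance(self, rng):
        ev = _fake_ev(rng, 12)
        labels = pd.Series([0] * 10 + [1] * 2, index=ev.values.index)

        class _CA:
            assignment = labels

        with pytest.raises(ValueError, match="n_splits"):
            ev_importance(ev, _CA())
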