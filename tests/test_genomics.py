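"""Marker QC, distances, kernels and population differentiation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from envgp.genomics import (
    GenotypeCatalog,
    MarkerMatrix,
    build_grms,
    deduplicate,
    derive_hybrid_genotypes,
    filter_markers,
    fst_windows,
    pcoa,
    rogers_distance,
    windowed_fst,
    _wc_components,
)
from envgp.kernels import DistanceMatrix


def _mm(codes, positions=None, chrom="chr1"):
    codes = pd.DataFrame(
        codes,
        index=[f"g{i}" for i in range(len(codes))],
        columns=[f"m{j}" for j in range(len(codes[0]))],
    )
    pos = positions if positions is not None else np.arange(1, codes.shape[1] + 1) * 100
    mmap = pd.DataFrame({"chrom": chrom, "pos": pos}, index=codes.columns)
    return MarkerMatrix(codes, mmap)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------
class TestFilterMarkers:
    def test_monomorphic_and_low_maf_removed(self):
        # 4 genotypes x 5 markers; m2 monomorphic, m4 has MAF 0.125 < 0.25
        m = _mm([
            [0, 0, 2, 0, 1],
            [2, 0, 0, 0, 1],
            [0, 0, 2, 0, 2],
            [2, 0, 0, 1, 0],
        ])
        out = filter_markers(m, max_missing=0.5, maf_min=0.25)
        assert list(out.codes.columns) == ["m0", "m2", "m4"]

    def test_high_missingness_removed_and_mean_imputed(self):
        codes = np.full((10, 2), 2.0)
        codes[:6, 0] = np.nan  # 60% missing > 0.5
        codes[:3, 1] = 0.0
        codes[3, 1] = np.nan  # 10% missing: imputed
        m = _mm(codes.tolist())
        out = filter_markers(m, max_missing=0.5, maf_min=0.01)
        assert list(out.codes.columns) == ["m1"]
        # mean of observed = (3*0 + 6*2)/9 = 1.33 -> rounds to 1
        assert out.codes.loc["g3", "m1"] == 1.0

    def test_all_filtered_raises(self):
        m = _mm([[2, 2], [2, 2]])
        with pytest.raises(ValueError, match="no markers"):
            filter_markers(m)


# ---------------------------------------------------------------------------
# Rogers distance
# ---------------------------------------------------------------------------
class TestRogersDistance:
    def test_identity_and_opposite_homozygotes(self):
        m = _mm([[0, 0, 0], [0, 0, 0], [2, 2, 2]])
        d = rogers_distance(m)
        assert d.values[0, 1] == 0.0
        assert d.values[0, 2] == 1.0

    def test_hand_computed_value(self):
        # x=(0,2,2), y=(2,2,0): (|0-2|/2 + 0 + |2-0|/2) / 3 = 2/3
        m = _mm([[0, 2, 2], [2, 2, 0]])
        d = rogers_distance(m)
        assert d.values[0, 1] == pytest.approx(2.0 / 3.0)

    def test_matches_allele_frequency_brute_force(self, rng):
        codes = rng.integers(0, 3, size=(8, 30)).astype(float)
        m = _mm(codes.tolist())
        d = rogers_distance(m)
        # brute force: per-locus distance between within-individual
        # allele frequency vectors (p, 1-p)
        for i, j in [(0, 1), (2, 5), (3, 7)]:
            per_locus = []
            for loc in range(30):
                pi, pj = codes[i, loc] / 2, codes[j, loc] / 2
                per_locus.append(
                    np.sqrt(((pi - pj) ** 2 + ((1 - pi) - (1 - pj)) ** 2) / 2)
                )
            assert d.values[i, j] == pytest.approx(np.mean(per_locus))

    def test_missing_codes_rejected(self):
        m = _mm([[0, np.nan], [2, 0]])
        with pytest.raises(ValueError, match="filter"):
            rogers_distance(m)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_triangle_inequality(self, seed):
        r = np.random.default_rng(seed)
        codes = r.integers(0, 3, size=(3, 12)).astype(float)
        d = rogers_distance(_mm(codes.tolist())).values
        assert d[0, 2] <= d[0, 1] + d[1, 2] + 1e-12


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------
class TestDeduplicate:
    def test_no_pairs_below_threshold(self):
        d = DistanceMatrix(["a", "b"], np.array([[0, 0.5], [0.5, 0]]))
        assert len(deduplicate(d)) == 0

    def test_single_linkage_chain(self):
        vals = np.array([
            [0.00, 0.02, 0.04],
            [0.02, 0.00, 0.02],
            [0.04, 0.02, 0.00],
        ])
        d = DistanceMatrix(["a", "b", "c"], vals)
        dd = deduplicate(d, threshold=0.03)
        assert dd.canonical("b") == "a" and dd.canonical("c") == "a"

    def test_idempotent_and_canonical_smallest(self):
        vals = np.zeros((3, 3))
        d = DistanceMatrix(["z", "a", "m"], vals)
        dd = deduplicate(d)
        assert dd.canonical("z") == "a"
        assert dd.canonical(dd.canonical("z")) == "a"

    def test_injected_duplicates_merge(self, small_study):
        dd = small_study["dedup"]
        groups = dd.groups()
        # 4 injected duplicates -> at least 4 mapped ids
        assert len(dd) >= 4
        for canon, members in groups.items():
            assert all(m != canon for m in members)


# ---------------------------------------------------------------------------
# GRMs
# ---------------------------------------------------------------------------
class TestGRMs:
    def test_additive_matches_hand_computation(self):
        # frozen from the VanRaden formula on a 3x2 toy (p = 2/3 both loci)
        m = _mm([[0, 2], [2, 0], [2, 2]])
        grm_a, _, _ = build_grms(m)
        expected = np.array([
            [2.5, -2.0, -0.5],
            [-2.0, 2.5, -0.5],
            [-0.5, -0.5, 1.0],
        ])
        assert np.allclose(grm_a.values, expected, atol=1e-6)

    def test_epistatic_mean_diag_is_one(self, small_study):
        grm_aa = small_study["kernels"]["GRM_aa"]
        assert np.diag(grm_aa.values).mean() == pytest.approx(1.0, abs=1e-6)

    def test_duplicates_share_rows(self, small_study):
        grm_a = small_study["kernels"]["GRM_a"]
        dd = small_study["dedup"]
        member, canon = next(iter(dd.mapping.items()))
        i = grm_a.labels.index(member)
        j = grm_a.labels.index(canon)
        assert grm_a.values[i, j] == pytest.approx(
            grm_a.values[i, i], abs=2e-8
        )

    def test_psd_and_symmetric(self, small_study):
        for kind in ("GRM_a", "GRM_d", "GRM_aa"):
            small_study["kernels"][kind].check()

    def test_monomorphic_rejected(self):
        m = _mm([[0, 0], [2, 0]])
        with pytest.raises(ValueError, match="monomorphic"):
            build_grms(m)


# ---------------------------------------------------------------------------
# hybrids
# ---------------------------------------------------------------------------
class TestHybridDerivation:
    def test_codes_are_parent_means(self):
        lines = _mm([[0, 2], [2, 2]])
        cat = GenotypeCatalog(pd.DataFrame({
            "genotype_id": ["g0", "g1", "h1"],
            "material_type": ["line", "line", "hybrid"],
            "female_parent": [None, None, "g0"],
            "male_parent": [None, None, "g1"],
            "series": ["A", "A", "A"],
        }))
        hyb = derive_hybrid_genotypes(lines, cat)
        assert list(hyb.codes.loc["h1"]) == [1.0, 2.0]

    def test_missing_parent_named(self):
        lines = _mm([[0, 2]])
        cat = GenotypeCatalog(pd.DataFrame({
            "genotype_id": ["g0", "gX", "h1"],
            "material_type": ["line", "line", "hybrid"],
            "female_parent": [None, None, "g0"],
            "male_parent": [None, None, "gX"],
            "series": ["A", "A", "A"],
        }))
        with pytest.raises(ValueError, match="h1"):
            derive_hybrid_genotypes(lines, cat)

    def test_simulated_hybrids_heterozygous_only(self, small_study):
        markers, catalog = small_study["markers"], small_study["catalog"]
        lines = markers.codes.loc[catalog.lines["genotype_id"]]
        assert not (lines == 1).any().any()
        hybrids = markers.codes.loc[catalog.hybrids["genotype_id"]]
        assert (hybrids == 1).any().any()


# ---------------------------------------------------------------------------
# windowed F_st
# ---------------------------------------------------------------------------
def _wc_fst_brute(codes_a, codes_b):
    """Independent single-window Weir-Cockerham transcription (r=2)."""
    n1, n2 = len(codes_a), len(codes_b)
    num = den = 0.0
    for loc in range(codes_a.shape[1]):
        p1 = codes_a[:, loc].mean() / 2
        p2 = codes_b[:, loc].mean() / 2
        h1 = np.mean(codes_a[:, loc] == 1)
        h2 = np.mean(codes_b[:, loc] == 1)
        nbar = (n1 + n2) / 2
        nc = (2 * nbar - (n1 * n1 + n2 * n2) / (2 * nbar))
        pbar = (n1 * p1 + n2 * p2) / (2 * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (n1 * h1 + n2 * h2) / (2 * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 / 2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 / 2 - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


class TestWindowedFst:
    def test_alternate_fixed_gives_one(self):
        codes = np.vstack([np.zeros((4, 6)), np.full((4, 6), 2.0)])
        m = _mm(codes.tolist())
        groups = {f"g{i}": ("A" if i < 4 else "B") for i in range(8)}
        fst = windowed_fst(m, groups)
        assert fst.values[0, 1] == pytest.approx(1.0)

    def test_random_split_near_zero(self, rng):
        codes = (rng.random((200, 1000)) < rng.uniform(0.2, 0.8, 1000)).astype(float) * 2
        m = _mm(codes.tolist(), positions=np.arange(1, 1001) * 500)
        groups = {f"g{i}": ("A" if i < 100 else "B") for i in range(200)}
        fst = windowed_fst(m, groups)
        assert abs(fst.raw[0, 1]) < 0.02

    def test_weighted_equals_single_window_oracle(self, rng):
        codes = rng.integers(0, 3, size=(30, 40)).astype(float)
        # all markers inside one window
        m = _mm(codes.tolist(), positions=np.arange(1, 41) * 100)
        groups = {f"g{i}": ("A" if i < 15 else "B") for i in range(30)}
        fst = windowed_fst(m, groups, window=299_999, step=29_999)
        brute = _wc_fst_brute(codes[:15], codes[15:])
        assert fst.raw[0, 1] == pytest.approx(brute, abs=1e-10)

    def test_window_enumeration_closed_form(self):
        wins = fst_windows(np.array([400_000]), 299_999, 29_999)
        assert len(wins) == int(np.ceil((400_000 - 299_999) / 29_999)) + 1
        assert [w[0] for w in wins[:3]] == [1, 30_000, 59_999]

    def test_small_group_rejected(self):
        m = _mm([[0, 2], [2, 0], [0, 0]])
        with pytest.raises(ValueError, match="fewer than two"):
            windowed_fst(m, {"g0": "A", "g1": "B", "g2": "B"})


# ---------------------------------------------------------------------------
# principal coordinates
# ---------------------------------------------------------------------------
class TestPCoA:
    def test_equilateral_triangle_equal_eigenvalues(self):
        d = DistanceMatrix(["a", "b", "c"], np.ones((3, 3)) - np.eye(3))
        _, eig = pcoa(d, 2)
        pos = eig[eig > 1e-10]
        assert len(pos) == 2 and pos[0] == pytest.approx(pos[1])

    def test_line_recovered(self, rng):
        pts = np.sort(rng.normal(0, 1, 25))
        d = DistanceMatrix(
            [f"p{i}" for i in range(25)], np.abs(np.subtract.outer(pts, pts))
        )
        coords, _ = pcoa(d, 1)
        assert abs(np.corrcoef(coords.iloc[:, 0], pts)[0, 1]) > 0.999

    def test_duplicates_identical_coordinates(self):
        vals = np.array([
            [0.0, 0.0, 1.0],
            [0.0, 0.0, 1.0],
            [1.0, 1.0, 0.0],
        ])
        coords, _ = pcoa(DistanceMatrix(["a", "b", "c"], vals), 1)
        assert coords.loc["a", "PCo1"] == pytest.approx(coords.loc["b", "PCo1"])

    def test_excess_axes_truncated_with_warning(self):
        d = DistanceMatrix(["a", "b", "c"], np.ones((3, 3)) - np.eye(3))
        with pytest.warns(UserWarning, match="truncating"):
            coords, _ = pcoa(d, 3)
        assert coords.shape[1] == 2


class TestVcfIO:
    def test_roundtrip_preserves_codes_and_map(self, tmp_path, rng):
        codes = rng.integers(0, 3, size=(6, 8)).astype(float)
        codes[0, 0] = np.nan
        m = _mm(codes.tolist(), positions=np.arange(1, 9) * 1000)
        path = tmp_path / "toy.vcf"
        m.to_vcf(path)
        back = MarkerMatrix.from_vcf(path)
        assert back.genotype_ids == m.genotype_ids
        assert np.allclose(back.values(), m.values(), equal_nan=True)
        assert list(back.marker_map["pos"]) == list(m.marker_map["pos"])
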