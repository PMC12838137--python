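"""Marker QC, genetic distances, genomic relationship matrices and
population differentiation.

Genotypes are biallelic SNPs coded 0/1/2 (minor-allele dosage).  Inbred
lines are fully homozygous (codes 0/2); heterozygous calls (code 1) arise
in single-cross hybrids whose SNP profiles are derived as the mean of the
parental profiles.  All genomic kernels and distances downstream are
computed from this coding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .kernels import DistanceMatrix, Kernel

__all__ = [
    "MarkerMatrix",
    "GenotypeCatalog",
    "DuplicateMap",
    "filter_markers",
    "rogers_distance",
    "deduplicate",
    "build_grms",
    "derive_hybrid_genotypes",
    "windowed_fst",
    "pcoa",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------
@dataclass
class MarkerMatrix:
    """Genotype-by-marker dosage matrix plus physical map.

    Parameters
    ----------
    codes : pandas.DataFrame
        Rows are genotypes, columns marker ids; values in {0, 1, 2} or NaN
        for missing calls.
    marker_map : pandas.DataFrame
        Indexed by marker id with columns ``chrom`` and ``pos`` (1-based bp).
    """

    codes: pd.DataFrame
    marker_map: pd.DataFrame

    def __post_init__(self):
        if self.codes.columns.duplicated().any():
            raise ValueError("marker ids must be unique")
        if self.codes.index.duplicated().any():
            raise ValueError("genotype ids must be unique")
        if not self.codes.columns.equals(self.marker_map.index):
            self.marker_map = self.marker_map.reindex(self.codes.columns)
            if self.marker_map["pos"].isna().any():
                raise ValueError("marker map does not cover all markers")
        vals = self.codes.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
        if bad.any():
            raise ValueError("marker codes must be 0/1/2 or missing")

    @property
    def genotype_ids(self) -> list:
        return list(self.codes.index)

    @property
    def marker_ids(self) -> list:
        return list(self.codes.columns)

    @property
    def n_genotypes(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def values(self) -> np.ndarray:
        return self.codes.to_numpy(dtype=float)

    # -- IO ------------------------------------------------------------
    def to_csv(self, codes_path, map_path) -> None:
        self.codes.to_csv(codes_path)
        self.marker_map.to_csv(map_path)

    @classmethod
    def from_csv(cls, codes_path, map_path) -> "MarkerMatrix":
        codes = pd.read_csv(codes_path, index_col=0)
        mmap = pd.read_csv(map_path, index_col=0)
        return cls(codes, mmap)

    def to_vcf(self, path) -> None:
        """Write a minimal unphased GT-only VCF (REF=A, ALT=B placeholders)."""
        gt_str = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            samples = "\t".join(str(g) for g in self.codes.index)
            fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
            vals = self.values()
            for j, mid in enumerate(self.codes.columns):
                chrom = self.marker_map.loc[mid, "chrom"]
                pos = int(self.marker_map.loc[mid, "pos"])
                calls = "\t".join(
                    "./." if np.isnan(v) else gt_str[v] for v in vals[:, j]
                )
                fh.write(f"{chrom}\t{pos}\t{mid}\tA\tB\t.\t.\t.\tGT\t{calls}\n")

    @classmethod
    def from_vcf(cls, path) -> "MarkerMatrix":
        """Read a biallelic GT-only VCF (via cyvcf2) into dosage coding."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        ids, chroms, poss, rows = [], [], [], []
        for var in vcf:
            if len(var.ALT) != 1:
                continue  # biallelic records only
            ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
            chroms.append(var.CHROM)
            poss.append(var.POS)
            # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
            g = np.array(var.gt_types, dtype=float)
            dose = np.where(g == 0, 0.0, np.where(g == 1, 1.0, np.where(g == 3, 2.0, np.nan)))
            rows.append(dose)
        codes = pd.DataFrame(np.array(rows).T, index=samples, columns=ids)
        mmap = pd.DataFrame({"chrom": chroms, "pos": poss}, index=ids)
        return cls(codes, mmap)


@dataclass
class GenotypeCatalog:
    """Catalog of lines and hybrids with parentage and series membership.

    ``table`` columns: genotype_id, material_type ('line'|'hybrid'),
    female_parent, male_parent, series.  Lines carry no parents; hybrids
    must name two parents that are themselves cataloged.
    """

    table: pd.DataFrame

    REQUIRED = ("genotype_id", "material_type", "female_parent", "male_parent", "series")

    def __post_init__(self):
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"catalog missing columns: {sorted(missing)}")
        if self.table["genotype_id"].duplicated().any():
            raise ValueError("catalog genotype ids must be unique")
        known = set(self.table["genotype_id"])
        hyb = self.table[self.table["material_type"] == "hybrid"]
        for _, row in hyb.iterrows():
            for p in (row["female_parent"], row["male_parent"]):
                if pd.isna(p) or p not in known:
                    raise ValueError(
                        f"hybrid {row['genotype_id']!r} has parent {p!r} "
                        "absent from the catalog"
                    )

    @property
    def lines(self) -> pd.DataFrame:
        return self.table[self.table["material_type"] == "line"]

    @property
    def hybrids(self) -> pd.DataFrame:
        return self.table[self.table["material_type"] == "hybrid"]

    def series_of(self) -> dict:
        return dict(zip(self.table["genotype_id"], self.table["series"]))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GenotypeCatalog":
        return cls(pd.read_csv(path))


@dataclass
class DuplicateMap:
    """Mapping of genotype ids to canonical ids after genomic deduplication."""

    mapping: dict = field(default_factory=dict)

    def canonical(self, genotype_id):
        return self.mapping.get(genotype_id, genotype_id)

    def groups(self) -> dict:
        out: dict = {}
        for gid, canon in self.mapping.items():
            out.setdefault(canon, set()).add(gid)
        return out

    def __len__(self) -> int:
        return len(self.mapping)


# ---------------------------------------------------------------------------
# marker QC
# ---------------------------------------------------------------------------
def _allele_freq(vals: np.ndarray) -> np.ndarray:
    """Per-marker frequency of the allele counted by the dosage coding."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(vals, axis=0) / 2.0


def filter_markers(
    m: MarkerMatrix, max_missing: float = 0.5, maf_min: float = 0.01
) -> MarkerMatrix:
    """Drop high-missingness, monomorphic and low-MAF markers; impute the rest.

    Markers with missing fraction > ``max_missing`` are removed first, then
    monomorphic markers and markers with minor allele frequency below
    ``maf_min``.  Surviving missing calls are replaced by the per-marker
    mean code rounded to the nearest integer (the package's stand-in for
    haplotype-based imputation).  Marker order is preserved.
    """
    if not (0 <= max_missing <= 1 and 0 <= maf_min <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    vals = m.values()
    miss_frac = np.isnan(vals).mean(axis=0)
    keep = miss_frac <= max_missing
    p = _allele_freq(vals)
    maf = np.minimum(p, 1 - p)
    keep &= (maf >= maf_min) & (maf > 0)
    if not keep.any():
        raise ValueError("no markers survive filtering")
    codes = m.codes.loc[:, keep].copy()
    vals = codes.to_numpy(dtype=float)
    if np.isnan(vals).any():
        col_mean = np.nanmean(vals, axis=0)
        fill = np.round(col_mean)
        idx = np.where(np.isnan(vals))
        vals[idx] = fill[idx[1]]
        codes = pd.DataFrame(vals, index=codes.index, columns=codes.columns)
    return MarkerMatrix(codes, m.marker_map.loc[codes.columns].copy())


# ---------------------------------------------------------------------------
# Rogers distance and deduplication
# ---------------------------------------------------------------------------
def rogers_distance(m: MarkerMatrix) -> DistanceMatrix:
    """Biallelic Rogers distance: mean per-locus allele-frequency distance.

    With dosage codes halved to within-individual allele frequencies this
    is ``d(x, y) = mean_l |c_xl - c_yl| / 2`` -- 0 for identical genotypes
    and 1 for opposite homozygotes at every locus.
    """
    vals = m.values()
    if np.isnan(vals).any():
        raise ValueError("missing codes present; run filter_markers first")
    d = pdist(vals, metric="cityblock") / (2.0 * m.n_markers)
    return DistanceMatrix(m.genotype_ids, squareform(d))


def deduplicate(d: DistanceMatrix, threshold: float = 0.03) -> DuplicateMap:
    """Group genotypes into genomic duplicates by single linkage.

    All pairs with distance < ``threshold`` are joined; connected
    components are the duplicate groups and each group is mapped to its
    lexicographically smallest member.  The mapping is idempotent.
    """
    adj = csr_matrix(d.values < threshold)
    n_comp, labels = connected_components(adj, directed=False)
    mapping: dict = {}
    order = np.argsort([str(lab) for lab in d.labels])
    canon: dict = {}
    for i in order:  # first visit per component is the smallest id
        comp = labels[i]
        canon.setdefault(comp, d.labels[i])
    for i, lab in enumerate(d.labels):
        c = canon[labels[i]]
        if c != lab:
            mapping[lab] = c
    return DuplicateMap(mapping)


# ---------------------------------------------------------------------------
# genomic relationship matrices
# ---------------------------------------------------------------------------
def build_grms(m: MarkerMatrix) -> tuple[Kernel, Kernel, Kernel]:
    """Additive, dominance and additive-epistatic genomic kernels.

    GRM_a follows VanRaden method 1: ``W W' / (2 sum p_j (1-p_j))`` with W
    the allele-frequency-centered dosages.  GRM_d uses the orthogonal
    dominance coding {0 -> -2p^2, 1 -> 2p(1-p), 2 -> -2(1-p)^2} normalized
    by ``sum (2 p_j (1-p_j))^2``.  GRM_aa is the Hadamard square of GRM_a
    scaled so its mean diagonal is 1.  All three receive a 1e-8 diagonal
    jitter.
    """
    vals = m.values()
    if np.isnan(vals).any():
        raise ValueError("missing codes present; run filter_markers first")
    if m.n_genotypes < 2:
        raise ValueError("need at least two genotypes")
    p = vals.mean(axis=0) / 2.0
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("monomorphic markers present; run filter_markers first")
    het = 2.0 * p * (1.0 - p)

    W = vals - 2.0 * p
    grm_a = (W @ W.T) / het.sum()

    D = np.empty_like(vals)
    for code, expr in ((0.0, -2.0 * p**2), (1.0, het), (2.0, -2.0 * (1 - p) ** 2)):
        mask = vals == code
        D[mask] = np.broadcast_to(expr, vals.shape)[mask]
    grm_d = (D @ D.T) / (het**2).sum()

    aa = grm_a * grm_a
    grm_aa = aa / np.diag(aa).mean()

    ids = m.genotype_ids
    out = []
    for values, kind in ((grm_a, "GRM_a"), (grm_d, "GRM_d"), (grm_aa, "GRM_aa")):
        k = Kernel(ids, values, kind).jittered()
        out.append(k)
    return tuple(out)


def derive_hybrid_genotypes(lines: MarkerMatrix, catalog: GenotypeCatalog) -> MarkerMatrix:
    """Hybrid SNP profiles as the mean of the two parental profiles."""
    hybrids = catalog.hybrids
    have = set(lines.genotype_ids)
    rows, ids = [], []
    vals = lines.codes
    for _, row in hybrids.iterrows():
        f, mparent = row["female_parent"], row["male_parent"]
        if f not in have or mparent not in have:
            raise ValueError(
                f"hybrid {row['genotype_id']!r} lacks genotyped parent(s)"
            )
        rows.append((vals.loc[f].to_numpy() + vals.loc[mparent].to_numpy()) / 2.0)
        ids.append(row["genotype_id"])
    codes = pd.DataFrame(np.array(rows), index=ids, columns=lines.marker_ids)
    return MarkerMatrix(codes, lines.marker_map.copy())


# ---------------------------------------------------------------------------
# windowed Weir-Cockerham F_st
# ---------------------------------------------------------------------------
def _wc_components(codes_a: np.ndarray, codes_b: np.ndarray):
    """Per-locus Weir & Cockerham (1984) a, b, c variance components.

    Inputs are dosage matrices (individuals x loci) of the two
    populations; heterozygote frequency is the frequency of code 1.
    """
    r = 2.0
    n1, n2 = codes_a.shape[0], codes_b.shape[0]
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    p1 = codes_a.mean(axis=0) / 2.0
    p2 = codes_b.mean(axis=0) / 2.0
    h1 = (codes_a == 1).mean(axis=0)
    h2 = (codes_b == 1).mean(axis=0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
    )
    c = hbar / 2.0
    return a, b, c


def fst_windows(positions: np.ndarray, window: int, step: int) -> list[tuple[int, int]]:
    """Half-open bp windows [start, start+window) covering 1..max(pos)."""
    if len(positions) == 0:
        return []
    last = int(positions.max())
    if last <= window:
        n_win = 1
    else:
        n_win = int(np.ceil((last - window) / step)) + 1
    return [(1 + k * step, 1 + k * step + window) for k in range(n_win)]


def windowed_fst(
    m: MarkerMatrix,
    groups: dict,
    window: int = 299_999,
    step: int = 29_999,
) -> DistanceMatrix:
    """Pairwise weighted F_st between groups from sliding bp windows.

    The Weir-Cockerham estimator is formed per window (half-open 1-based
    [start, start+window) per chromosome) and the weighted pairwise
    estimate is the ratio of summed numerators to summed denominators
    across all windows.
    """
    names = sorted(set(groups.values()), key=str)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    members = {g: [gid for gid, grp in groups.items() if grp == g] for g in names}
    for g, mem in members.items():
        if len(mem) < 2:
            raise ValueError(f"group {g!r} has fewer than two genotypes")
    vals = m.codes
    if vals.isna().any().any():
        raise ValueError("missing codes present; run filter_markers first")

    # assign each marker to its windows once
    chrom = m.marker_map["chrom"].to_numpy()
    pos = m.marker_map["pos"].to_numpy(dtype=int)
    win_marker_idx: list[np.ndarray] = []
    for ch in pd.unique(chrom):
        on_ch = np.where(chrom == ch)[0]
        for lo, hi in fst_windows(pos[on_ch], window, step):
            sel = on_ch[(pos[on_ch] >= lo) & (pos[on_ch] < hi)]
            if sel.size:
                win_marker_idx.append(sel)

    out = np.zeros((len(names), len(names)))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            A = vals.loc[members[names[i]]].to_numpy()
            B = vals.loc[members[names[j]]].to_numpy()
            a, b_, c = _wc_components(A, B)
            num = den = 0.0
            for sel in win_marker_idx:
                num += a[sel].sum()
                den += (a[sel] + b_[sel] + c[sel]).sum()
            fst = num / den if den != 0 else 0.0
            out[i, j] = out[j, i] = fst
    # F_st can be slightly negative by sampling; clamp tiny negatives for
    # the distance-matrix contract but keep the raw value accessible
    dm_vals = np.clip(out, 0.0, None)
    dm = DistanceMatrix(names, dm_vals)
    dm.raw = out  # type: ignore[attr-defined]
    return dm


# ---------------------------------------------------------------------------
# principal coordinates
# ---------------------------------------------------------------------------
def pcoa(d: DistanceMatrix, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical metric multidimensional scaling of a distance matrix.

    Returns coordinates scaled by the square root of the eigenvalues and
    the full eigenvalue vector.  Axes use a deterministic sign convention
    (the largest-magnitude loading on each axis is positive).  If ``k``
    exceeds the number of positive eigenvalues the result is truncated
    with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    from skbio import DistanceMatrix as SkbioDM
    from skbio.stats.ordination import pcoa as _pcoa

    ids = [str(lab) for lab in d.labels]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _pcoa(SkbioDM(d.values, ids=ids), method="eigh")
    eigvals = res.eigvals.to_numpy()
    n_pos = int((eigvals > 1e-10 * max(eigvals.max(), 1e-300)).sum())
    if k > n_pos:
        warnings.warn(
            f"requested {k} axes but only {n_pos} positive eigenvalues; truncating"
        )
        k = n_pos
    coords = res.samples.iloc[:, :k].to_numpy()
    for j in range(coords.shape[1]):
        if coords[np.abs(coords[:, j]).argmax(), j] < 0:
            coords[:, j] = -coords[:, j]
    frame = pd.DataFrame(
        coords, index=d.labels, columns=[f"PCo{j + 1}" for j in range(k)]
    )
    return frame, eigvals
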