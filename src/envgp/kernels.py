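"""Labeled relationship kernels and distance matrices.

A :class:`Kernel` is a symmetric positive-semidefinite relationship matrix
over a set of labeled entities (genotypes, environments, years, sites or
genotype-by-environment cells).  All covariance structures used by the
prediction models -- genomic (GRM), environmental (ERM), year/site
(YRM/SRM), their Hadamard products (GERM/GYRM) and identities -- are
carried in this one container so that model construction can treat them
uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Kernel", "DistanceMatrix", "hadamard"]

#: kinds a Kernel may declare; free-form kinds are allowed but these are
#: the ones produced by the package itself
KNOWN_KINDS = {
    "GRM_a", "GRM_d", "GRM_aa", "ERM_l", "ERM_nl", "YRM", "SRM",
    "GERM", "GYRM", "GS", "identity",
}

JITTER = 1e-8


def _as_labels(labels) -> list:
    out = list(labels)
    if len(set(out)) != len(out):
        raise ValueError("kernel labels must be unique")
    return out


@dataclass
class Kernel:
    """Symmetric PSD relationship matrix with entity labels."""

    labels: list
    values: np.ndarray
    kind: str = "identity"
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.labels = _as_labels(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"kernel values shape {self.values.shape} does not match "
                f"{n} labels"
            )
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    # ------------------------------------------------------------------
    @classmethod
    def identity(cls, labels, kind: str = "identity") -> "Kernel":
        labels = list(labels)
        return cls(labels, np.eye(len(labels)), kind)

    @property
    def n(self) -> int:
        return len(self.labels)

    def loc(self, rows, cols=None) -> np.ndarray:
        """Cross-block of the kernel for arbitrary label sequences."""
        ri = np.asarray([self._index[r] for r in rows])
        ci = ri if cols is None else np.asarray([self._index[c] for c in cols])
        return self.values[np.ix_(ri, ci)]

    def subset(self, labels) -> "Kernel":
        return Kernel(list(labels), self.loc(labels), self.kind)

    # ------------------------------------------------------------------
    def check(self, sym_tol: float = 1e-10, eig_tol: float = -1e-8) -> None:
        """Validate symmetry and near-PSD-ness; raise on violation."""
        if not np.allclose(self.values, self.values.T, atol=sym_tol, rtol=0.0):
            raise ValueError(f"kernel {self.kind!r} is not symmetric")
        w = np.linalg.eigvalsh(self.values)
        if w.min() < eig_tol:
            raise ValueError(
                f"kernel {self.kind!r} has eigenvalue {w.min():.3e} < {eig_tol}"
            )

    def jittered(self, jitter: float = JITTER) -> "Kernel":
        """Return a copy with `jitter` added to the diagonal."""
        v = self.values.copy()
        v[np.diag_indices_from(v)] += jitter
        return Kernel(self.labels, v, self.kind)

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path, kind: str = "identity") -> "Kernel":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index), df.to_numpy(dtype=float), kind)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with zero diagonal."""

    labels: list
    values: np.ndarray

    def __post_init__(self):
        self.labels = _as_labels(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index), df.to_numpy(dtype=float))

    def condensed(self) -> np.ndarray:
        from scipy.spatial.distance import squareform

        return squareform(self.values, checks=False)


def hadamard(a: Kernel, b: Kernel, kind: str = "GERM") -> Kernel:
    """Element-wise product of two kernels over identical labels.

    By the Schur product theorem the result is PSD whenever both inputs
    are.  Labels must match exactly (use row-expanded kernels for
    unbalanced data; see the mixed-model module).
    """
    if a.labels != b.labels:
        raise ValueError("hadamard product requires identical label order")
    return Kernel(a.labels, a.values * b.values, kind)
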