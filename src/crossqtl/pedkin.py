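"""Numerator relationship matrix A and multi-trait Kronecker covariance.

A is built by the tabular method: a_ij = (a_{j,sire(i)} + a_{j,dam(i)})/2
for j < i and a_ii = 1 + a_{sire(i),dam(i)}/2, with an unknown parent
contributing zero.  Storage is dense; the pedigrees this package handles
are a few hundred animals at most.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import Pedigree


class PedigreeCycleError(ValueError):
    pass


@dataclass
class RelationshipMatrix:
    ids: list
    matrix: np.ndarray

    @property
    def inbreeding(self) -> np.ndarray:
        """F_i = a_ii - 1."""
        return np.diag(self.matrix) - 1.0

    def submatrix(self, keep_ids) -> "RelationshipMatrix":
        """Principal submatrix over a subset of individuals (the marginal
        covariance of their breeding values)."""
        idx = [self.ids.index(i) for i in keep_ids]
        return RelationshipMatrix(list(keep_ids), self.matrix[np.ix_(idx, idx)])

    def to_tsv(self, path) -> None:
        """Lower triangle as (id_i, id_j, a_ij) rows."""
        with open(path, "w") as fh:
            fh.write("id_i\tid_j\ta\n")
            for i, ii in enumerate(self.ids):
                for j in range(i + 1):
                    fh.write(f"{ii}\t{self.ids[j]}\t{self.matrix[i, j]:.8g}\n")


def numerator_relationship(pedigree: Pedigree) -> RelationshipMatrix:
    """Tabular-method additive relationship matrix in pedigree order."""
    tab = pedigree.table
    ids = list(tab["id"])
    index = {ind: k for k, ind in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    for i, row in enumerate(tab.itertuples(index=False)):
        s = index.get(row.sire, -1) if row.sire else -1
        d = index.get(row.dam, -1) if row.dam else -1
        if s >= i or d >= i:
            raise PedigreeCycleError(
                f"individual {row.id!r} precedes one of its parents"
            )
        for j in range(i):
            a = 0.0
            if s >= 0:
                a += A[j, s]
            if d >= 0:
                a += A[j, d]
            A[i, j] = A[j, i] = 0.5 * a
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return RelationshipMatrix(ids, A)


class KroneckerCovariance:
    """(A x G0) evaluated through the eigenstructure of the two factors.

    Ordering convention is individual-major, trait-minor: entry
    (i*k + t, j*k + s) equals A[i, j] * G0[t, s].  Log-determinants and
    quadratic forms use the Kronecker eigenvalue factorization rather
    than the materialized nk x nk matrix; ``full_matrix`` is provided
    for small cross-checks.
    """

    def __init__(self, A: RelationshipMatrix, G0: np.ndarray, tol: float = 1e-8):
        G0 = np.asarray(G0, dtype=float)
        if G0.ndim != 2 or G0.shape[0] != G0.shape[1]:
            raise ValueError("G0 must be square")
        if not np.allclose(G0, G0.T, atol=1e-10):
            raise ValueError("G0 must be symmetric")
        w, V = np.linalg.eigh(G0)
        if w.min() < -tol:
            warnings.warn("G0 not PSD; projecting negative eigenvalues to zero")
            G0 = (V * np.clip(w, 0.0, None)) @ V.T
            w = np.clip(w, 0.0, None)
        self.A = A
        self.G0 = G0
        self.k = G0.shape[0]
        self.n = A.matrix.shape[0]
        self._dA, self._UA = np.linalg.eigh(A.matrix)
        self._wG, self._VG = w, V

    def full_matrix(self) -> np.ndarray:
        return np.kron(self.A.matrix, self.G0)

    def logdet(self) -> float:
        """logdet(A x G0) = k logdet(A) + n logdet(G0)."""
        dA = np.clip(self._dA, 1e-300, None)
        wG = np.clip(self._wG, 1e-300, None)
        return self.k * float(np.sum(np.log(dA))) + self.n * float(
            np.sum(np.log(wG))
        )

    def quadratic(self, x: np.ndarray) -> float:
        """x' (A x G0)^-1 x for a vector in individual-major order."""
        X = np.asarray(x, dtype=float).reshape(self.n, self.k)
        Y = self._UA.T @ X @ self._VG
        scale = np.outer(self._dA, self._wG)
        if (scale <= 0).any():
            raise np.linalg.LinAlgError("singular Kronecker covariance")
        return float(np.sum(Y**2 / scale))
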