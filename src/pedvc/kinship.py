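"""Additive relationship matrix and inbreeding from a pedigree.

The additive (numerator) relationship matrix ``A`` holds the expected
proportion of alleles shared identical by descent, doubled kinship:
``a_ij = 2 * phi_ij`` and ``a_ii = 1 + F_i`` where ``F_i`` is the
inbreeding coefficient.  ``A`` is computed by the tabular method in a
topological order of the pedigree:

    a_ii = 1 + 0.5 * a_{fm}
    a_ij = 0.5 * (a_{jf} + a_{jm})      (j already placed)

where ``f``/``m`` are the parents of ``i`` and terms with a missing parent
drop.  An individual with one known parent is treated as having a unique,
unrelated and non-inbred founder for the other, the standard convention.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pedio import Pedigree

__all__ = [
    "RelationshipMatrix",
    "additive_relationship",
    "inbreeding",
    "align_to_samples",
]


class RelationshipMatrix:
    """Symmetric PSD additive-relationship matrix indexed by individual id.

    Also caches the eigendecomposition and a (jittered) Cholesky factor,
    which downstream REML fits and simulators reuse.
    """

    def __init__(self, ids: Sequence[str], A: np.ndarray):
        A = np.asarray(A, dtype=float)
        if A.shape != (len(ids), len(ids)):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(A, A.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")
        self.ids = list(ids)
        self._index = {iid: k for k, iid in enumerate(self.ids)}
        self.A = A
        self._eig: tuple[np.ndarray, np.ndarray] | None = None
        self._chol: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.ids)

    def loc(self, i: str, j: str) -> float:
        return float(self.A[self._index[i], self._index[j]])

    @property
    def kinship(self) -> np.ndarray:
        """Kinship matrix Phi = A / 2."""
        return self.A / 2.0

    @property
    def inbreeding(self) -> pd.Series:
        """F_i = a_ii - 1 per individual."""
        return pd.Series(np.diag(self.A) - 1.0, index=self.ids, name="F")

    def eigendecomposition(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (clipped at 0) and eigenvectors of A, cached."""
        if self._eig is None:
            d, U = np.linalg.eigh(self.A)
            self._eig = (np.clip(d, 0.0, None), U)
        return self._eig

    def cholesky(self) -> np.ndarray:
        """Lower factor L with L L' = A (eigen-based, tolerant of PSD rank loss)."""
        if self._chol is None:
            d, U = self.eigendecomposition()
            self._chol = U * np.sqrt(d)
        return self._chol

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.A, index=self.ids, columns=self.ids)

    def to_triplets(self) -> pd.DataFrame:
        """Long-form (id1, id2, a) rows for the upper triangle, nonzero only."""
        rows = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i, n):
                a = self.A[i, j]
                if a != 0.0:
                    rows.append((self.ids[i], self.ids[j], a))
        return pd.DataFrame(rows, columns=["id1", "id2", "a"])

    def write(self, prefix: str | Path) -> None:
        """Write square (TSV) and triplet forms under a common prefix."""
        prefix = Path(prefix)
        self.to_frame().to_csv(prefix.with_suffix(".square.tsv"), sep="\t")
        self.to_triplets().to_csv(
            prefix.with_suffix(".triplets.tsv"), sep="\t", index=False
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"RelationshipMatrix({len(self)} individuals)"


def additive_relationship(ped: Pedigree) -> RelationshipMatrix:
    """Tabular-method additive relationship matrix for a pedigree.

    Handles inbreeding loops and multiple disconnected families (the matrix
    is block-diagonal across them, up to id ordering).
    """
    order = ped.topological_order()
    index = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for iid in order:
        i = index[iid]
        fid, mid = ped.parents(iid)
        f = index[fid] if fid is not None else None
        m = index[mid] if mid is not None else None
        # relationship to previously placed individuals
        if f is not None or m is not None:
            row = np.zeros(n)
            if f is not None:
                row += A[f]
            if m is not None:
                row += A[m]
            A[i, :i] = 0.5 * row[:i]
            A[:i, i] = A[i, :i]
        A[i, i] = 1.0 + (0.5 * A[f, m] if f is not None and m is not None else 0.0)
    # restore file order
    perm = [order.index(iid) for iid in ped.ids]
    A = A[np.ix_(perm, perm)]
    return RelationshipMatrix(ped.ids, A)


def inbreeding(ped: Pedigree) -> pd.Series:
    """Per-individual inbreeding coefficient F_i = Phi(father_i, mother_i).

    Founders (and single-parent individuals) have F = 0.
    """
    return additive_relationship(ped).inbreeding


def align_to_samples(
    rm: RelationshipMatrix, ids: Sequence[str]
) -> RelationshipMatrix:
    """Principal submatrix restricted to ``ids`` in the requested order."""
    missing = [iid for iid in ids if iid not in rm._index]
    if missing:
        raise KeyError(f"ids not in relationship matrix: {missing}")
    idx = [rm._index[iid] for iid in ids]
    return RelationshipMatrix(list(ids), rm.A[np.ix_(idx, idx)])
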