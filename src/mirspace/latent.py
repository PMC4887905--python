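"""Truncated SVD of the combined matrix and cosine-ranked disease queries.

The combined matrix X (m miRNAs x n features) is factored as
X ~= U_r S_r V_r^T. miRNA i is embedded as row i of U_r * S_r and disease d
as its row of V_r * S_r (both sides scaled by the singular values before the
cosine). Queries rank every miRNA by cosine similarity to the disease vector,
descending, ties broken lexicographically by miRNA id.
"""

from __future__ import annotations

import difflib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.sparse.linalg import svds

from .features import CombinedMatrix

__all__ = ["LatentSpace", "RankedList", "max_rank", "fit", "disease_vector", "query", "fold_in"]

logger = logging.getLogger(__name__)

DEFAULT_RANK = 400


@dataclass
class LatentSpace:
    """Rank-r factors of the combined matrix plus the label maps."""

    U: np.ndarray  # m x r, orthonormal columns
    s: np.ndarray  # r singular values, non-increasing
    V: np.ndarray  # n x r, orthonormal columns
    rank: int
    row_labels: list[str]
    col_labels: list[str]
    column_blocks: list[tuple[str, int, int]]

    def validate(self, tol: float = 1e-8) -> None:
        r = self.rank
        if self.U.shape != (len(self.row_labels), r) or self.V.shape != (len(self.col_labels), r):
            raise ValueError("factor shapes inconsistent with labels and rank")
        if np.any(np.diff(self.s) > tol) or np.any(self.s <= 0):
            raise ValueError("singular values must be positive and non-increasing")
        for F in (self.U, self.V):
            if not np.allclose(F.T @ F, np.eye(r), atol=1e-6):
                raise ValueError("factor columns not orthonormal")

    def mirna_vectors(self) -> np.ndarray:
        return self.U * self.s

    def block_slice(self, block: str) -> slice:
        for name, start, stop in self.column_blocks:
            if name == block:
                return slice(start, stop)
        raise KeyError(f"no block {block!r}")


@dataclass
class RankedList:
    """Per-disease ordered (miRNA, cosine score) pairs, scores non-increasing."""

    disease: str
    entries: list[tuple[str, float]]

    def scores(self) -> dict[str, float]:
        return dict(self.entries)


def max_rank(cm: CombinedMatrix) -> int:
    """Largest admissible truncation rank for this matrix."""
    return min(cm.shape) - 1


def fit(cm: CombinedMatrix, rank: int, seed: int = 0, cap: bool = False) -> LatentSpace:
    """Truncated SVD with deterministic start vector and canonical signs.

    ``cap=True`` silently lowers an oversized ``rank`` to the maximum feasible
    value (with a logged warning) instead of raising; useful for small
    synthetic datasets run with the production default of 400.
    """
    feasible = max_rank(cm)
    if rank < 1:
        raise ValueError("rank must be positive")
    if rank > feasible:
        if not cap:
            raise ValueError(f"rank {rank} too large for shape {cm.shape}; max is {feasible}")
        logger.warning("rank %d capped to %d for shape %s", rank, feasible, cm.shape)
        rank = feasible
    if cm.X.nnz == 0:
        raise ValueError("combined matrix has no nonzero entries")

    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal(min(cm.shape))
    U, s, Vt = svds(cm.X.asfptype(), k=rank, v0=v0)
    order = np.argsort(s)[::-1]
    U, s, V = U[:, order], s[order], Vt[order].T

    # sign canonicalization: largest-magnitude component of each left singular
    # vector is made positive, for reproducibility across solver runs
    for k in range(rank):
        pivot = np.argmax(np.abs(U[:, k]))
        if U[pivot, k] < 0:
            U[:, k] = -U[:, k]
            V[:, k] = -V[:, k]

    ls = LatentSpace(
        U=U,
        s=s,
        V=V,
        rank=rank,
        row_labels=list(cm.row_labels),
        col_labels=list(cm.col_labels),
        column_blocks=list(cm.column_blocks),
    )
    return ls


def _disease_column(ls: LatentSpace, disease: str) -> int:
    s = ls.block_slice("disease")
    labels = ls.col_labels[s]
    try:
        return s.start + labels.index(disease)
    except ValueError:
        hints = difflib.get_close_matches(disease, labels, n=5, cutoff=0.3)
        raise KeyError(
            f"unknown disease {disease!r}; closest labels: {hints or labels[:5]}"
        ) from None


def disease_vector(ls: LatentSpace, disease: str) -> np.ndarray:
    """Latent embedding of a disease column: its row of V_r scaled by S_r."""
    return ls.V[_disease_column(ls, disease)] * ls.s


def query(ls: LatentSpace, disease: str) -> RankedList:
    """Rank every miRNA by cosine similarity to the disease vector.

    Zero-norm vectors (either side) score 0. The full ranking is returned,
    descending score, ties broken by miRNA id.
    """
    dvec = disease_vector(ls, disease)
    mvecs = ls.mirna_vectors()
    dnorm = np.linalg.norm(dvec)
    mnorms = np.linalg.norm(mvecs, axis=1)
    if dnorm == 0:
        scores = np.zeros(len(mnorms))
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            scores = (mvecs @ dvec) / (mnorms * dnorm)
        scores[mnorms == 0] = 0.0
    # round away solver noise so duplicate rows tie exactly and the
    # lexicographic tie-break is reproducible
    scores = np.round(scores, 12)
    entries = sorted(zip(ls.row_labels, scores.tolist()), key=lambda e: (-e[1], e[0]))
    return RankedList(disease=disease, entries=entries)


def fold_in(ls: LatentSpace, x_new: np.ndarray) -> np.ndarray:
    """Project a new feature row into the latent space (x V_r / S_r, rescaled).

    The projection x V_r S_r^-1 gives the left-factor coordinates; rescaling
    by S_r puts the result on the same scale as ``mirna_vectors`` so it can be
    scored against disease vectors. The two scalings cancel to ``x @ V_r``.
    """
    x_new = np.asarray(x_new).ravel()
    if x_new.shape[0] != len(ls.col_labels):
        raise ValueError(
            f"fold-in vector has length {x_new.shape[0]}, expected {len(ls.col_labels)}"
        )
    return x_new @ ls.V


def save(ls: LatentSpace, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / "U.npy", ls.U)
    np.save(directory / "s.npy", ls.s)
    np.save(directory / "V.npy", ls.V)
    meta = {
        "rank": ls.rank,
        "row_labels": ls.row_labels,
        "col_labels": ls.col_labels,
        "column_blocks": [list(b) for b in ls.column_blocks],
    }
    (directory / "meta.json").write_text(json.dumps(meta), encoding="utf-8")


def load(directory: str | Path) -> LatentSpace:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text(encoding="utf-8"))
    return LatentSpace(
        U=np.load(directory / "U.npy"),
        s=np.load(directory / "s.npy"),
        V=np.load(directory / "V.npy"),
        rank=meta["rank"],
        row_labels=meta["row_labels"],
        col_labels=meta["col_labels"],
        column_blocks=[tuple(b) for b in meta["column_blocks"]],
    )
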