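"""Pairwise cosine similarity between forum emotion profiles.

Each forum's K occurrence-frequency percentages form a nonnegative
K-vector; the cosine of the angle between two such vectors measures how
alike two forums' emotional compositions are (1 = identical composition,
0 = disjoint categories).  Cosine is scale-invariant, so percentages and
raw counts give the same matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .scoring import CorpusProfile

__all__ = [
    "SimilarityMatrix",
    "SimilarityError",
    "cosine_similarity",
    "similarity_matrix",
    "top_k_similar",
]


class SimilarityError(ValueError):
    pass


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric forum-by-forum cosine similarity with unit diagonal."""

    forums: Tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.forums)
        if self.values.shape != (n, n):
            raise SimilarityError("matrix shape does not match forum list")

    def loc(self, a: str, b: str) -> float:
        i, j = self.forums.index(a), self.forums.index(b)
        return float(self.values[i, j])


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u.v / (|u| |v|); raises on a zero vector."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise SimilarityError("cosine similarity undefined for zero vector")
    return float(np.dot(u, v) / (nu * nv))


def similarity_matrix(profiles: Sequence[CorpusProfile]) -> SimilarityMatrix:
    """All pairwise cosine similarities over profiles sharing one lexicon."""
    if len(profiles) < 2:
        raise SimilarityError("need at least 2 profiles")
    lex = profiles[0].lexicon_name
    order = tuple(profiles[0].frequencies)
    for p in profiles[1:]:
        if p.lexicon_name != lex or tuple(p.frequencies) != order:
            raise SimilarityError(
                f"profile {p.forum!r} scored with a different lexicon")
    X = np.array([p.vector() for p in profiles])
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise SimilarityError("zero profile vector")
    Xn = X / norms[:, None]
    M = Xn @ Xn.T
    # guard against |x| = 1 + eps rounding; profiles are nonnegative
    np.clip(M, 0.0, 1.0, out=M)
    np.fill_diagonal(M, 1.0)
    M = (M + M.T) / 2.0
    return SimilarityMatrix(tuple(p.forum for p in profiles), M)


def top_k_similar(matrix: SimilarityMatrix, target: str,
                  k: int = 5) -> List[Tuple[str, float]]:
    """The k non-self forums most similar to ``target``, descending.

    Ties are broken lexicographically by forum name so the ranking is
    reproducible across runs and snapshots.
    """
    if target not in matrix.forums:
        raise SimilarityError(f"forum {target!r} not in matrix")
    if k >= len(matrix.forums):
        raise SimilarityError(
            f"k={k} but only {len(matrix.forums) - 1} other forums")
    i = matrix.forums.index(target)
    pairs = [(f, float(matrix.values[i, j]))
             for j, f in enumerate(matrix.forums) if j != i]
    pairs.sort(key=lambda fs: (-fs[1], fs[0]))
    return pairs[:k]
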