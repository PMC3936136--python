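"""Local alignment with affine gap penalties, generic in the reward.

Both alignment phases fill the same recurrence over a similarity matrix
H with zero boundary row/column (indices 1-based over the two element
chains, reward r for the element pair under a cell):

    H[i,j] = max( H[i-1,j-1] + r[i,j],  E[i,j],  F[i,j],  0 )
    E[i,j] = max( E[i,j-1] - g_E,  H[i,j-1] - g_O )   (gap in the
                                                       vertical chain)
    F[i,j] = max( F[i-1,j] - g_E,  H[i-1,j] - g_O )   (gap in the
                                                       horizontal chain)

and the chain-pair similarity Score is the maximum cell of H.  Note the
gap-open branch charges g_O from the adjacent H cell directly (no
additional g_E on the opening step).

Because H[i,j] depends only on its three neighbours, the Score and its
position can be computed keeping one row of H, one row of F and one
scalar E — the linear-space scorer used for whole-database scans.  The
full matrices are materialized only for the handful of top hits whose
residue-level alignment path is backtracked.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np

__all__ = [
    "GAP",
    "GapPenalties",
    "ScoreResult",
    "AlignmentPath",
    "local_affine_score",
    "local_affine_matrix",
    "backtrack",
]

GAP = None  # gap marker inside AlignmentPath.pairs

_NEG = -np.inf
_TOL = 1e-9

Reward = Union[np.ndarray, Callable[[int, int], float]]


@dataclass(frozen=True)
class GapPenalties:
    """Affine gap cost: ``open`` (g_O) to open, ``extend`` (g_E) per step."""

    open: float
    extend: float

    def __post_init__(self) -> None:
        if not (self.open >= self.extend >= 0.0):
            raise ValueError("gap penalties must satisfy open >= extend >= 0")


@dataclass(frozen=True)
class ScoreResult:
    """Maximum similarity-matrix cell and its 0-based (query, db) argmax."""

    score: float
    pos: tuple[int, int]


@dataclass(frozen=True)
class AlignmentPath:
    """Backtracked local alignment.

    ``pairs`` holds (query index | None, db index | None) tuples in
    alignment order; ``None`` marks a gap.  Indices strictly increase
    along each chain and no pair is (None, None).
    """

    pairs: tuple[tuple[Optional[int], Optional[int]], ...]
    score: float

    def aligned_pairs(self) -> list[tuple[int, int]]:
        """Gap-free (query, db) index pairs."""
        return [(i, j) for i, j in self.pairs if i is not None and j is not None]

    def n_gaps(self) -> int:
        return sum(1 for i, j in self.pairs if i is None or j is None)


def _reward_matrix(reward: Reward, n_query: int, n_db: int) -> np.ndarray:
    if callable(reward):
        return np.array(
            [[float(reward(i, j)) for j in range(n_db)] for i in range(n_query)]
        )
    r = np.asarray(reward, dtype=float)
    if r.shape != (n_query, n_db):
        raise ValueError(f"reward matrix shape {r.shape} != ({n_query}, {n_db})")
    return r


def local_affine_score(
    reward: Reward, n_query: int, n_db: int, gaps: GapPenalties
) -> ScoreResult:
    """Maximum local-alignment score in O(n_query·n_db) time, O(n_db) memory.

    ``reward`` is either an (n_query, n_db) array or a callable
    ``(i, j) -> float`` over 0-based element indices.  Argmax ties are
    broken toward the smallest query index, then the smallest db index.
    An empty dimension yields score 0 at (0, 0).
    """
    if n_query == 0 or n_db == 0:
        return ScoreResult(0.0, (0, 0))
    r = _reward_matrix(reward, n_query, n_db)
    g_o, g_e = gaps.open, gaps.extend

    prev = np.zeros(n_db + 1)  # H row i-1
    f_row = np.full(n_db + 1, _NEG)  # F row i (vectorized update from row i-1)
    best = 0.0
    best_pos = (0, 0)
    for i in range(1, n_query + 1):
        f_row = np.maximum(f_row - g_e, prev - g_o)
        cur = np.zeros(n_db + 1)
        row_r = r[i - 1]
        e = _NEG
        h_left = 0.0  # H[i, j-1]
        for j in range(1, n_db + 1):
            e = max(e - g_e, h_left - g_o)
            h = max(prev[j - 1] + row_r[j - 1], e, f_row[j], 0.0)
            cur[j] = h
            h_left = h
            if h > best:
                best = h
                best_pos = (i - 1, j - 1)
        prev = cur
    return ScoreResult(float(best), best_pos)


def local_affine_matrix(
    reward: Reward, n_query: int, n_db: int, gaps: GapPenalties
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Materialize the full H, E, F matrices (shape (n_query+1, n_db+1)).

    Row/column 0 is the zero boundary; cell (i, j) with i, j ≥ 1 refers
    to the element pair (i-1, j-1).  The maximum of H equals
    :func:`local_affine_score` on the same instance.
    """
    r = _reward_matrix(reward, n_query, n_db)
    g_o, g_e = gaps.open, gaps.extend
    H = np.zeros((n_query + 1, n_db + 1))
    E = np.full((n_query + 1, n_db + 1), _NEG)
    F = np.full((n_query + 1, n_db + 1), _NEG)
    for i in range(1, n_query + 1):
        for j in range(1, n_db + 1):
            E[i, j] = max(E[i, j - 1] - g_e, H[i, j - 1] - g_o)
            F[i, j] = max(F[i - 1, j] - g_e, H[i - 1, j] - g_o)
            H[i, j] = max(H[i - 1, j - 1] + r[i - 1, j - 1], E[i, j], F[i, j], 0.0)
    return H, E, F


def backtrack(
    H: np.ndarray,
    E: np.ndarray,
    F: np.ndarray,
    reward: Reward,
    start: tuple[int, int],
    gaps: GapPenalties,
) -> AlignmentPath:
    """Trace the local alignment ending at ``start`` back to a zero cell.

    ``start`` is a 0-based (query, db) element pair, normally the
    ``pos`` of a :class:`ScoreResult`.  At each matrix cell the move is
    chosen in priority order diagonal, then vertical gap (consume a
    query element), then horizontal gap (consume a db element), among
    the moves consistent with the recurrence.  A start cell of value
    ≤ 0 yields an empty path.
    """
    n_query, n_db = H.shape[0] - 1, H.shape[1] - 1
    r = _reward_matrix(reward, n_query, n_db)
    g_o, g_e = gaps.open, gaps.extend
    i, j = start[0] + 1, start[1] + 1
    score = float(H[i, j])
    if score <= 0.0:
        return AlignmentPath(pairs=(), score=0.0)

    pairs: list[tuple[Optional[int], Optional[int]]] = []
    state = "M"
    while i > 0 and j > 0:
        if state == "M":
            h = H[i, j]
            if h <= _TOL:
                break
            if abs(h - (H[i - 1, j - 1] + r[i - 1, j - 1])) <= _TOL:
                pairs.append((i - 1, j - 1))
                i, j = i - 1, j - 1
            elif abs(h - F[i, j]) <= _TOL:
                state = "F"
            elif abs(h - E[i, j]) <= _TOL:
                state = "E"
            else:  # pragma: no cover - recurrence violated
                raise AssertionError("inconsistent DP matrices in backtrack")
        elif state == "F":  # gap run in the db chain (consume query)
            pairs.append((i - 1, GAP))
            from_open = abs(F[i, j] - (H[i - 1, j] - g_o)) <= _TOL
            i -= 1
            if from_open:
                state = "M"
            # else F[i,j] == F[i-1,j] - g_e: stay in F after the move
        else:  # state == "E": gap run in the query chain (consume db)
            pairs.append((GAP, j - 1))
            from_open = abs(E[i, j] - (H[i, j - 1] - g_o)) <= _TOL
            j -= 1
            if from_open:
                state = "M"
    pairs.reverse()
    return AlignmentPath(pairs=tuple(pairs), score=score)
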