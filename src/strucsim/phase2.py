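"""High-resolution alignment of molecular residue descriptor chains.

The reward for aligning query descriptor s_i with database descriptor
s_j is the weighted sum of four similarity components, each in [0, 1]:

    ss_ij = w_C·σ^C + w_γ·σ^γ + w_SSE·σ^SSE + w_r·σ^r

    σ^C   = exp(−(|C_i| − |C_j|)²)      backbone-vector lengths, Å
    σ^γ   = exp(−(γ_i − γ_j)²)          inter-vector angles, rad
    σ^SSE = phase-1 rules (i)–(iii)     secondary-structure codes
    σ^r   = min–max normalized BLOSUM62 amino-acid similarity

All weights default to 1; setting w_r = 0 searches for structural
similarity with the sequence term disabled.  The reward is pure (≥ 0):
descriptor divergence is penalized through the Gaussian fall-off, the
local zero clamp and the gap costs, not through negative match scores.
The resulting Score ranks the database chains that survived the
phase-1 filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from .align_core import (
    AlignmentPath,
    GapPenalties,
    ScoreResult,
    backtrack,
    local_affine_matrix,
    local_affine_score,
)
from .descriptors import DescriptorChain, ResidueDescriptor
from .phase1 import sse_sigma

__all__ = [
    "DEFAULT_GAPS2",
    "STANDARD_RESIDUES",
    "Phase2Weights",
    "NormalizedSubstitution",
    "normalize_blosum62",
    "sigma_c",
    "sigma_gamma",
    "residue_reward",
    "phase2_score",
    "phase2_align",
]

#: Default phase-2 affine gap penalties.
DEFAULT_GAPS2 = GapPenalties(open=2.0, extend=0.2)

#: The 20 standard amino acids (one-letter), the normalization domain.
STANDARD_RESIDUES = "ARNDCQEGHILKMFPSTWYV"


@dataclass(frozen=True)
class Phase2Weights:
    """Participation weights of the four reward components (defaults 1)."""

    w_c: float = 1.0
    w_gamma: float = 1.0
    w_sse: float = 1.0
    w_r: float = 1.0

    def __post_init__(self) -> None:
        if min(self.w_c, self.w_gamma, self.w_sse, self.w_r) < 0:
            raise ValueError("weights must be non-negative")

    def total(self) -> float:
        return self.w_c + self.w_gamma + self.w_sse + self.w_r


@dataclass(frozen=True)
class NormalizedSubstitution:
    """BLOSUM62 rescaled to [0, 1]; unknown residues ('X') score 0."""

    alphabet: str  # standard residues; anything else maps to 'X'
    table: np.ndarray  # (20, 20) float in [0, 1], symmetric

    def lookup(self, a: str, b: str) -> float:
        ia = self.alphabet.find(a)
        ib = self.alphabet.find(b)
        if ia < 0 or ib < 0:
            return 0.0
        return float(self.table[ia, ib])

    def rows(self, residues: list[str]) -> np.ndarray:
        """(len(residues), 20) slice; zero row for unknown residues."""
        out = np.zeros((len(residues), len(self.alphabet)))
        for k, r in enumerate(residues):
            i = self.alphabet.find(r)
            if i >= 0:
                out[k] = self.table[i]
        return out


@lru_cache(maxsize=1)
def normalize_blosum62() -> NormalizedSubstitution:
    """Min–max normalize the standard 20×20 BLOSUM62 to [0, 1].

    The rescale is global, (v − min)/(max − min), over the 20 standard
    residues (min −4, max 11 = W↔W), preserving symmetry.
    """
    raw = substitution_matrices.load("BLOSUM62")
    n = len(STANDARD_RESIDUES)
    table = np.empty((n, n))
    for i, a in enumerate(STANDARD_RESIDUES):
        for j, b in enumerate(STANDARD_RESIDUES):
            table[i, j] = raw[a][b]
    lo, hi = table.min(), table.max()
    table = (table - lo) / (hi - lo)
    return NormalizedSubstitution(alphabet=STANDARD_RESIDUES, table=table)


def sigma_c(c_q: float, c_d: float) -> float:
    """Backbone-vector length similarity exp(−(|C_q|−|C_d|)²) ∈ (0, 1]."""
    return math.exp(-((c_q - c_d) ** 2))


def sigma_gamma(g_q: float, g_d: float) -> float:
    """Inter-vector angle similarity exp(−(γ_q−γ_d)²) ∈ (0, 1]."""
    return math.exp(-((g_q - g_d) ** 2))


def residue_reward(
    s_q: ResidueDescriptor,
    s_d: ResidueDescriptor,
    w: Phase2Weights = Phase2Weights(),
    sub: NormalizedSubstitution | None = None,
) -> float:
    """Weighted four-component reward ss for one descriptor pair."""
    if sub is None:
        sub = normalize_blosum62()
    return (
        w.w_c * sigma_c(s_q.c_len, s_d.c_len)
        + w.w_gamma * sigma_gamma(s_q.gamma, s_d.gamma)
        + w.w_sse * sse_sigma(s_q.sse, s_d.sse)
        + w.w_r * sub.lookup(s_q.residue, s_d.residue)
    )


def reward_matrix(
    query: DescriptorChain,
    db: DescriptorChain,
    w: Phase2Weights = Phase2Weights(),
    sub: NormalizedSubstitution | None = None,
) -> np.ndarray:
    """Vectorized (len(query), len(db)) matrix of :func:`residue_reward`."""
    if sub is None:
        sub = normalize_blosum62()
    cq = query.c_lens()[:, None]
    cd = db.c_lens()[None, :]
    gq = query.gammas()[:, None]
    gd = db.gammas()[None, :]
    r = w.w_c * np.exp(-((cq - cd) ** 2)) + w.w_gamma * np.exp(-((gq - gd) ** 2))
    if w.w_sse:
        sq = query.sse_codes()
        sd = db.sse_codes()
        sse = np.array([[sse_sigma(a, b) for b in sd] for a in sq])
        r += w.w_sse * sse
    if w.w_r:
        rows = sub.rows(query.residue_codes())  # (nq, 20)
        cols = np.array(
            [sub.alphabet.find(x) for x in db.residue_codes()]
        )  # -1 for unknown
        sub_r = np.zeros((len(query), len(db)))
        known = cols >= 0
        sub_r[:, known] = rows[:, cols[known]]
        r += w.w_r * sub_r
    return r


def phase2_score(
    query: DescriptorChain,
    db: DescriptorChain,
    gaps: GapPenalties = DEFAULT_GAPS2,
    w: Phase2Weights = Phase2Weights(),
) -> ScoreResult:
    """High-resolution Score of two descriptor chains (ranking measure)."""
    if len(query) == 0 or len(db) == 0:
        raise ValueError("empty descriptor chain")
    r = reward_matrix(query, db, w)
    return local_affine_score(r, len(query), len(db), gaps)


def phase2_align(
    query: DescriptorChain,
    db: DescriptorChain,
    gaps: GapPenalties = DEFAULT_GAPS2,
    w: Phase2Weights = Phase2Weights(),
) -> AlignmentPath:
    """Full-matrix alignment with backtracking from the maximum cell.

    The path score equals :func:`phase2_score` on the same pair.  Only
    run for the few top-ranked hits: memory is O(len(query)·len(db)).
    """
    if len(query) == 0 or len(db) == 0:
        raise ValueError("empty descriptor chain")
    r = reward_matrix(query, db, w)
    res = local_affine_score(r, len(query), len(db), gaps)
    if res.score <= 0.0:
        return AlignmentPath(pairs=(), score=0.0)
    H, E, F = local_affine_matrix(r, len(query), len(db), gaps)
    return backtrack(H, E, F, r, res.pos, gaps)
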