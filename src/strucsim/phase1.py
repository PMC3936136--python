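"""Low-resolution alignment of reduced secondary-structure chains.

This is the pre-selection filter of the two-phase search.  Two SE
regions are rewarded by

    δ = σ · (1 − |L_d − L_q| / (L_d + L_q))        with σ from:

    (i)   σ = 1    both regions α-helix, or both β-strand
    (ii)  σ = 0.5  at least one region is loop/turn/coil/undetermined
    (iii) σ = 0    one region helix, the other strand

so δ ∈ [0, σ], reaching σ at equal lengths and falling off with the
relative length difference.  A database chain qualifies for the
high-resolution phase when Score(Q,D) / Score(Q,Q) ≥ Q_t.

For whole-database scans the per-region σ lookups are precomputed into
a *query profile*: one row per query SE region holding the coefficient
against each possible database symbol (H, E, L, plus a neutral padding
symbol scoring 0), stored in the byte-sized integer encoding
0 → 0, 1 → 1, 0.5 → 2.  Scoring always uses the decoded real values;
the integer code exists for compact serialization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align_core import GapPenalties, ScoreResult, local_affine_score
from .descriptors import ReducedChain, SERegion
from .structure_io import SSEType

__all__ = [
    "DEFAULT_GAPS1",
    "Phase1Profile",
    "sse_sigma",
    "region_delta",
    "encode_sigma",
    "decode_sigma",
    "build_phase1_profile",
    "phase1_score",
    "phase1_self_score",
]

#: Default phase-1 affine gap penalties (configurable in all entry points).
DEFAULT_GAPS1 = GapPenalties(open=1.0, extend=0.1)

#: Column order of a profile row: the three SSE symbols then the neutral
#: padding symbol (always 0).
PROFILE_COLUMNS = (SSEType.H, SSEType.E, SSEType.L, None)

_ENCODE = {0.0: 0, 1.0: 1, 0.5: 2}
_DECODE = {0: 0.0, 1: 1.0, 2: 0.5}


def sse_sigma(a: SSEType, b: SSEType) -> float:
    """Secondary-structure similarity coefficient σ ∈ {0, 0.5, 1}."""
    if a is SSEType.L or b is SSEType.L:
        return 0.5
    return 1.0 if a is b else 0.0


def region_delta(q: SERegion, d: SERegion) -> float:
    """Similarity reward δ = σ·(1 − |L_d − L_q|/(L_d + L_q)) ∈ [0, 1]."""
    sigma = sse_sigma(q.sse, d.sse)
    return sigma * (1.0 - abs(d.length - q.length) / (d.length + q.length))


def encode_sigma(sigma: float) -> int:
    """Map a σ coefficient to its 1-byte profile code (0→0, 1→1, 0.5→2)."""
    try:
        return _ENCODE[sigma]
    except KeyError:
        raise ValueError(f"σ must be one of 0, 0.5, 1; got {sigma!r}") from None


def decode_sigma(code: int) -> float:
    """Inverse of :func:`encode_sigma`."""
    try:
        return _DECODE[code]
    except KeyError:
        raise ValueError(f"profile code must be 0, 1 or 2; got {code!r}") from None


@dataclass(frozen=True)
class Phase1Profile:
    """Query-specific substitution table for the phase-1 scan.

    ``codes[i, t]`` is the encoded σ of query region i against database
    symbol ``PROFILE_COLUMNS[t]``; the neutral column is all zeros.
    ``lengths[i]`` carries L_i of the query regions for the δ length
    damping.
    """

    codes: np.ndarray  # (n_regions, 4) uint8
    lengths: np.ndarray  # (n_regions,) int

    def sigma_row(self, db_sse: SSEType) -> np.ndarray:
        """Decoded σ of every query region against one database symbol."""
        t = PROFILE_COLUMNS.index(db_sse)
        return np.array([_DECODE[int(c)] for c in self.codes[:, t]])


def build_phase1_profile(query: ReducedChain) -> Phase1Profile:
    """Precompute all σ coefficients of a query's SE regions."""
    if len(query) == 0:
        raise ValueError("empty reduced chain")
    codes = np.zeros((len(query), len(PROFILE_COLUMNS)), dtype=np.uint8)
    for i, region in enumerate(query.regions):
        for t, sym in enumerate(PROFILE_COLUMNS):
            if sym is None:
                codes[i, t] = 0  # neutral padding symbol
            else:
                codes[i, t] = _ENCODE[sse_sigma(region.sse, sym)]
    lengths = np.array([r.length for r in query.regions], dtype=int)
    return Phase1Profile(codes=codes, lengths=lengths)


def _delta_matrix(profile: Phase1Profile, db: ReducedChain) -> np.ndarray:
    """δ reward matrix (query regions × db regions) via the profile."""
    n = len(profile.lengths)
    m = len(db.regions)
    r = np.empty((n, m))
    lq = profile.lengths.astype(float)
    for j, region in enumerate(db.regions):
        sigma = profile.sigma_row(region.sse)
        ld = float(region.length)
        r[:, j] = sigma * (1.0 - np.abs(ld - lq) / (ld + lq))
    return r


def phase1_score(
    query: ReducedChain,
    db: ReducedChain,
    gaps: GapPenalties = DEFAULT_GAPS1,
    profile: Phase1Profile | None = None,
) -> ScoreResult:
    """Low-resolution Score of two reduced chains.

    A prebuilt query ``profile`` may be passed to amortize σ lookups
    across a database scan; scores are identical either way.
    """
    if len(query) == 0 or len(db) == 0:
        raise ValueError("empty reduced chain")
    if profile is None:
        profile = build_phase1_profile(query)
    reward = _delta_matrix(profile, db)
    return local_affine_score(reward, len(query), len(db), gaps)


def phase1_self_score(query: ReducedChain, gaps: GapPenalties = DEFAULT_GAPS1) -> float:
    """Score of the query against itself (Score^QQ, the filter denominator).

    Equals the closed form  #(H or E regions) + 0.5 · #(L regions):
    every diagonal reward is σ(s,s) ≥ 0.5 > 0, so the best local path is
    the full diagonal and gaps cannot help.
    """
    return phase1_score(query, query, gaps).score
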