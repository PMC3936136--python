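"""The two in-memory representations of a protein chain.

Phase 2 (high resolution) works on *molecular residue descriptors*: one
feature vector per residue,

    s_i = <|C_i|, γ_i, SSE_i, r_i>

where C_i is the vector from Cα(i) to Cα(i+1), |C_i| its length in Å,
γ_i the angle between successive vectors C_i and C_{i+1} (radians by
default), SSE_i the residue's secondary-structure code and r_i its
amino-acid type.  Terminal positions where a vector or angle is
undefined are zero-filled.

Phase 1 (low resolution) works on *reduced chains of secondary
structures*: the run-length encoding of the per-residue SSE string into
SE regions [type, length], e.g. HHHHEEELL → (H,4)(E,3)(L,2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure_io import CalphaTrace, EmptyTraceError, SSEType

__all__ = [
    "ResidueDescriptor",
    "DescriptorChain",
    "SERegion",
    "ReducedChain",
    "build_descriptor_chain",
    "reduce_chain",
]


@dataclass(frozen=True)
class ResidueDescriptor:
    """Per-residue feature vector <|C_i|, γ_i, SSE_i, r_i>."""

    c_len: float  # |C_i|, Å, ≥ 0 (0 where undefined)
    gamma: float  # γ_i ∈ [0, π] rad (0 where undefined)
    sse: SSEType
    residue: str  # one-letter code, 'X' if non-standard

    def __post_init__(self) -> None:
        if self.c_len < 0:
            raise ValueError("c_len must be non-negative")


@dataclass(frozen=True)
class DescriptorChain:
    id: str
    descriptors: tuple[ResidueDescriptor, ...]

    def __len__(self) -> int:
        return len(self.descriptors)

    # columnar views used by the vectorized phase-2 reward
    def c_lens(self) -> np.ndarray:
        return np.array([s.c_len for s in self.descriptors])

    def gammas(self) -> np.ndarray:
        return np.array([s.gamma for s in self.descriptors])

    def sse_codes(self) -> list[SSEType]:
        return [s.sse for s in self.descriptors]

    def residue_codes(self) -> list[str]:
        return [s.residue for s in self.descriptors]


@dataclass(frozen=True)
class SERegion:
    """One SE region [SSE type, length in residues] of a reduced chain."""

    sse: SSEType
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("region length must be >= 1")


@dataclass(frozen=True)
class ReducedChain:
    id: str
    regions: tuple[SERegion, ...]

    def __len__(self) -> int:
        return len(self.regions)

    def n_residues(self) -> int:
        return sum(r.length for r in self.regions)


def build_descriptor_chain(
    trace: CalphaTrace, angle_unit: str = "radians"
) -> DescriptorChain:
    """Compute the descriptor chain of a Cα trace.

    For a trace of length q (0-based index i):

    * ``c_len[i] = ‖coord[i+1] − coord[i]‖`` for i < q−1, else 0;
    * ``gamma[i]`` = angle between C_i and C_{i+1} for i < q−2, else 0.

    ``angle_unit`` may be ``"radians"`` (default) or ``"degrees"``; it
    rescales γ only, and must match between any two chains that are
    later aligned.
    """
    if angle_unit not in ("radians", "degrees"):
        raise ValueError(f"unknown angle unit {angle_unit!r}")
    q = len(trace)
    if q < 1:
        raise EmptyTraceError("empty trace")
    vecs = np.diff(trace.coords, axis=0)  # C_i, shape (q-1, 3)
    norms = np.linalg.norm(vecs, axis=1)
    c_len = np.zeros(q)
    c_len[: q - 1] = norms
    gamma = np.zeros(q)
    for i in range(q - 2):
        denom = norms[i] * norms[i + 1]
        if denom == 0.0:
            continue  # coincident Cα positions: leave angle 0
        cosang = float(np.dot(vecs[i], vecs[i + 1]) / denom)
        gamma[i] = math.acos(min(1.0, max(-1.0, cosang)))
    if angle_unit == "degrees":
        gamma = np.degrees(gamma)
    descs = tuple(
        ResidueDescriptor(float(c_len[i]), float(gamma[i]), trace.sse[i], trace.residues[i])
        for i in range(q)
    )
    return DescriptorChain(id=f"{trace.structure_id}_{trace.chain_id}", descriptors=descs)


def reduce_chain(chain: DescriptorChain) -> ReducedChain:
    """Run-length encode the SSE sequence of a descriptor chain.

    Adjacent regions always differ in type (maximal runs), region
    lengths sum to the chain length, and expanding the regions back
    reproduces the SSE sequence exactly.
    """
    if len(chain) == 0:
        raise EmptyTraceError("empty chain")
    regions: list[SERegion] = []
    run_sse = chain.descriptors[0].sse
    run_len = 0
    for s in chain.descriptors:
        if s.sse is run_sse:
            run_len += 1
        else:
            regions.append(SERegion(run_sse, run_len))
            run_sse, run_len = s.sse, 1
    regions.append(SERegion(run_sse, run_len))
    return ReducedChain(id=chain.id, regions=tuple(regions))
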