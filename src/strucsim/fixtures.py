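"""Deterministic synthetic structures for tests and demonstrations.

Generates Cα traces with idealized secondary-structure geometry —
helices with 1.5 Å rise, 2.3 Å radius and 100°/residue twist; strands
as near-linear 3.4 Å-rise segments; loops as seeded 3.8 Å-step random
walks — writes them as standard PDB text (ATOM + HELIX/SHEET records),
and perturbs descriptor chains with seeded Gaussian noise.  Everything
is a pure function of its spec: the same seed always reproduces the
same bytes.

These are geometric decoys, not physical proteins: they have no side
chains, no excluded volume and random sequences.  They exercise the
representation, scoring and search machinery, not folding realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .descriptors import DescriptorChain, ResidueDescriptor
from .structure_io import _THREE_TO_ONE, CalphaTrace, SSEType

__all__ = ["FixtureSpec", "make_trace", "write_pdb", "perturb", "random_layout", "write_database"]

_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}
_ONE_TO_THREE["X"] = "UNK"

HELIX_RISE = 1.5  # Å per residue along the axis
HELIX_RADIUS = 2.3  # Å
HELIX_TWIST = math.radians(100.0)  # per residue
STRAND_RISE = 3.4  # Å per residue
LOOP_STEP = 3.8  # Å Cα–Cα


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic chain.

    ``sse_layout`` is a list of (SSEType, length) runs whose lengths
    must sum to ``n_residues``; noise fields feed :func:`perturb`.
    """

    seed: int
    n_residues: int
    sse_layout: tuple[tuple[SSEType, int], ...]
    noise_c: float = 0.0  # Å sd
    noise_gamma: float = 0.0  # rad sd

    def __post_init__(self) -> None:
        if sum(n for _, n in self.sse_layout) != self.n_residues:
            raise ValueError("sse_layout lengths must sum to n_residues")
        if self.n_residues < 1:
            raise ValueError("need at least one residue")


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _rotation_to(axis: np.ndarray) -> np.ndarray:
    """Proper rotation taking ẑ to the given unit vector."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    s = np.linalg.norm(v)
    c = float(np.dot(z, axis))
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def _segment(kind: SSEType, n: int, rng: np.random.Generator) -> np.ndarray:
    """Idealized segment geometry in a local frame, first point at origin."""
    if kind is SSEType.H:
        k = np.arange(n)
        pts = np.stack(
            [
                HELIX_RADIUS * np.cos(k * HELIX_TWIST),
                HELIX_RADIUS * np.sin(k * HELIX_TWIST),
                HELIX_RISE * k,
            ],
            axis=1,
        )
    elif kind is SSEType.E:
        k = np.arange(n)
        wobble = 0.3 * np.stack([np.cos(k * math.pi), np.sin(k * math.pi), np.zeros(n)], axis=1)
        pts = np.stack([np.zeros(n), np.zeros(n), STRAND_RISE * k], axis=1) + wobble
    else:
        pts = np.zeros((n, 3))
        for i in range(1, n):
            pts[i] = pts[i - 1] + LOOP_STEP * _random_unit(rng)
    return pts - pts[0]


def make_trace(spec: FixtureSpec, structure_id: str = "SYNT", chain_id: str = "A") -> CalphaTrace:
    """Build a synthetic Cα trace with the spec's SSE layout.

    Deterministic per seed; successive segments are chained end-to-end
    in seeded random orientations with a ~3.8 Å junction step.
    """
    rng = np.random.default_rng(spec.seed)
    coords: list[np.ndarray] = []
    cursor = np.zeros(3)
    for kind, n in spec.sse_layout:
        seg = _segment(kind, n, rng) @ _rotation_to(_random_unit(rng)).T
        if coords:
            cursor = coords[-1] + LOOP_STEP * _random_unit(rng)
        coords.extend(cursor + p for p in seg)
    sse = [kind for kind, n in spec.sse_layout for _ in range(n)]
    residues = [
        "ARNDCQEGHILKMFPSTWYV"[i] for i in rng.integers(0, 20, size=spec.n_residues)
    ]
    return CalphaTrace(
        structure_id=structure_id,
        chain_id=chain_id,
        coords=np.array(coords),
        residues=residues,
        sse=sse,
        seq_ids=list(range(1, spec.n_residues + 1)),
    )


def _format_atom_records(trace: CalphaTrace, coords: np.ndarray) -> str:
    lines = []
    for i in range(len(trace)):
        res3 = _ONE_TO_THREE.get(trace.residues[i], "UNK")
        x, y, z = coords[i]
        lines.append(
            f"ATOM  {i + 1:5d}  CA  {res3:<3s} {trace.chain_id}{trace.seq_ids[i]:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_pdb(trace: CalphaTrace) -> str:
    """Serialize a trace as PDB text that round-trips through the reader.

    Emits one HELIX record per H run and one SHEET strand per E run,
    then Cα-only ATOM records.  Coordinates survive to the format's
    0.001 Å precision.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    header: list[str] = []
    n_helix = 0
    n_sheet = 0
    i = 0
    while i < len(trace):
        j = i
        while j < len(trace) and trace.sse[j] is trace.sse[i]:
            j += 1
        first, last = trace.seq_ids[i], trace.seq_ids[j - 1]
        res_f = _ONE_TO_THREE.get(trace.residues[i], "UNK")
        res_l = _ONE_TO_THREE.get(trace.residues[j - 1], "UNK")
        c = trace.chain_id
        if trace.sse[i] is SSEType.H:
            n_helix += 1
            header.append(
                f"HELIX  {n_helix:3d} {n_helix:3d} {res_f:<3s} {c} {first:4d}  "
                f"{res_l:<3s} {c} {last:4d}  1{'':30s}{j - i:5d}"
            )
        elif trace.sse[i] is SSEType.E:
            n_sheet += 1
            header.append(
                f"SHEET  {1:3d} {str(n_sheet % 1000):>3s} 1 {res_f:<3s} {c}{first:4d}  "
                f"{res_l:<3s} {c}{last:4d}  0"
            )
        i = j
    return "\n".join(header + [""]).lstrip("\n") + _format_atom_records(trace, trace.coords)


def perturb(
    chain: DescriptorChain, noise_c: float, noise_gamma: float, seed: int
) -> DescriptorChain:
    """Add seeded Gaussian noise to descriptor features.

    c_len gets N(0, noise_c²) clamped at 0; gamma gets N(0, noise_gamma²)
    clamped to [0, π].  SSE codes and residue types are untouched; zero
    noise is the identity.
    """
    if noise_c < 0 or noise_gamma < 0:
        raise ValueError("noise must be non-negative")
    if noise_c == 0 and noise_gamma == 0:
        return chain
    rng = np.random.default_rng(seed)
    out = []
    for s in chain.descriptors:
        c = max(0.0, s.c_len + rng.normal(0.0, noise_c)) if noise_c else s.c_len
        g = s.gamma + rng.normal(0.0, noise_gamma) if noise_gamma else s.gamma
        g = min(math.pi, max(0.0, g))
        out.append(ResidueDescriptor(c, g, s.sse, s.residue))
    return DescriptorChain(id=chain.id, descriptors=tuple(out))


def random_layout(
    rng: np.random.Generator, n_residues: int, min_run: int = 2, max_run: int = 12
) -> tuple[tuple[SSEType, int], ...]:
    """Random SSE layout with runs of 2–12 residues summing to n_residues."""
    kinds = [SSEType.H, SSEType.E, SSEType.L]
    layout: list[tuple[SSEType, int]] = []
    left = n_residues
    prev = None
    while left > 0:
        n = int(rng.integers(min_run, max_run + 1))
        n = min(n, left)
        choices = [k for k in kinds if k is not prev]
        kind = choices[int(rng.integers(0, len(choices)))]
        layout.append((kind, n))
        prev = kind
        left -= n
    return tuple(layout)


def write_database(out_dir, n_chains: int, seed: int, min_len: int = 30, max_len: int = 90):
    """Write ``n_chains`` synthetic single-chain PDB files into a directory.

    Chain lengths are uniform in [min_len, max_len]; layouts are random
    mixed H/E/L runs.  Returns the list of file paths (deterministic per
    seed).  This is the study database used by the search demonstrations.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths = []
    for k in range(n_chains):
        n = int(rng.integers(min_len, max_len + 1))
        layout = random_layout(rng, n)
        spec = FixtureSpec(seed=int(rng.integers(0, 2**31)), n_residues=n, sse_layout=layout)
        trace = make_trace(spec, structure_id=f"S{k:04d}")
        p = out_dir / f"S{k:04d}.pdb"
        p.write_text(write_pdb(trace))
        paths.append(p)
    return paths
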