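"""Rigid-body superposition of aligned Cα pairs and RMSD.

Given N aligned atom pairs, the Kabsch algorithm finds the proper
rotation R and translation t minimizing

    RMSD = sqrt( (1/N) Σ_i ‖fixed_i − (R·mobile_i + t)‖² )

via the SVD of the coordinate cross-covariance, with the determinant
correction that forbids reflections.  The pairs come from the
backtracked high-resolution alignment path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align_core import AlignmentPath
from .structure_io import CalphaTrace

__all__ = ["SuperpositionResult", "kabsch_superpose", "rmsd_of_path", "write_superposed_pdb"]


class DegenerateGeometryError(ValueError):
    """Point set is collinear or coincident; rotation is underdetermined."""


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid transform mobile → fixed and the resulting RMSD."""

    rotation: np.ndarray  # (3, 3) proper orthonormal
    translation: np.ndarray  # (3,) Å
    rmsd: float  # Å
    n_pairs: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) coordinate array."""
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(fixed: np.ndarray, mobile: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``fixed``.

    Both inputs are (N, 3) arrays with N ≥ 3 non-collinear points.
    Raises ``ValueError`` for fewer than 3 pairs and
    ``DegenerateGeometryError`` for collinear/coincident sets (where
    the optimal rotation is not unique).
    """
    fixed = np.asarray(fixed, dtype=float).reshape(-1, 3)
    mobile = np.asarray(mobile, dtype=float).reshape(-1, 3)
    if fixed.shape != mobile.shape:
        raise ValueError("point sets must have equal shapes")
    n = len(fixed)
    if n < 3:
        raise ValueError("insufficient pairs: need >= 3 aligned atoms")

    cf = fixed.mean(axis=0)
    cm = mobile.mean(axis=0)
    x = mobile - cm
    y = fixed - cf
    # degenerate if either centered set has rank < 2 (collinear/coincident)
    if np.linalg.matrix_rank(x, tol=1e-8) < 2 or np.linalg.matrix_rank(y, tol=1e-8) < 2:
        raise DegenerateGeometryError("degenerate geometry: collinear or coincident points")

    cov = x.T @ y
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cf - rot @ cm
    diff = fixed - (mobile @ rot.T + trans)
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd, n_pairs=n)


def rmsd_of_path(
    path: AlignmentPath, trace_q: CalphaTrace, trace_d: CalphaTrace
) -> SuperpositionResult:
    """Superpose the db trace onto the query over a path's aligned pairs.

    Gap elements are discarded; the db coordinates are the mobile set.
    """
    pairs = path.aligned_pairs()
    if not pairs:
        raise ValueError("insufficient pairs: path has no aligned residues")
    qi = [i for i, _ in pairs]
    dj = [j for _, j in pairs]
    return kabsch_superpose(trace_q.coords[qi], trace_d.coords[dj])


def write_superposed_pdb(trace: CalphaTrace, result: SuperpositionResult) -> str:
    """PDB text of a trace's Cα atoms after applying a superposition."""
    coords = result.apply(trace.coords)
    from .fixtures import _format_atom_records  # local import avoids cycle

    return _format_atom_records(trace, coords)
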