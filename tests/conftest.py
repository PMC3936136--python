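"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from strucsim.descriptors import DescriptorChain, ReducedChain, ResidueDescriptor, SERegion
from strucsim.structure_io import SSEType

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

SSE_KINDS = (SSEType.H, SSEType.E, SSEType.L)
RESIDUES = "ARNDCQEGHILKMFPSTWYV"


# ------------------------------------------------------------ random inputs


def random_reduced_chain(rng: np.random.Generator, max_regions: int = 10) -> ReducedChain:
    n = int(rng.integers(1, max_regions + 1))
    regions = []
    prev = None
    for _ in range(n):
        choices = [k for k in SSE_KINDS if k is not prev]
        kind = choices[int(rng.integers(0, len(choices)))]
        regions.append(SERegion(kind, int(rng.integers(1, 20))))
        prev = kind
    return ReducedChain(id="rand", regions=tuple(regions))


def random_descriptor(rng: np.random.Generator) -> ResidueDescriptor:
    return ResidueDescriptor(
        c_len=float(rng.uniform(2.0, 6.0)),
        gamma=float(rng.uniform(0.0, np.pi)),
        sse=SSE_KINDS[int(rng.integers(0, 3))],
        residue=RESIDUES[int(rng.integers(0, 20))],
    )


def random_descriptor_chain(rng: np.random.Generator, n: int, cid: str = "rand") -> DescriptorChain:
    return DescriptorChain(id=cid, descriptors=tuple(random_descriptor(rng) for _ in range(n)))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


# ------------------------------------------------------- independent oracles


def gap_run_cost(k: int, g_o: float, g_e: float) -> float:
    """Affine cost of a maximal run of k gaps (open charges g_o alone)."""
    return 0.0 if k == 0 else g_o + (k - 1) * g_e


def enumerate_local_best(r: np.ndarray, g_o: float, g_e: float) -> float:
    """Exhaustive local-alignment optimum on a tiny reward matrix.

    Enumerates every sequence of matched cells that is strictly
    monotone in both indices; between consecutive matches each chain
    may skip elements as its own maximal gap run (runs in the two
    chains open independently — the recurrence composes them through
    the intervening similarity cell).  Scores are reward sums minus
    affine gap-run costs; the maximum is taken against the empty
    alignment (0).  Exponential — use only for n, m ≤ ~5.
    """
    n, m = r.shape
    best = 0.0

    def extend(i: int, j: int, score: float) -> None:
        nonlocal best
        best = max(best, score)
        for i2 in range(i + 1, n):
            for j2 in range(j + 1, m):
                a, b = i2 - i - 1, j2 - j - 1  # skipped elements per chain
                cost = gap_run_cost(a, g_o, g_e) + gap_run_cost(b, g_o, g_e)
                extend(i2, j2, score + r[i2, j2] - cost)

    for i in range(n):
        for j in range(m):
            extend(i, j, r[i, j])
    return best


def quaternion_superpose(fixed: np.ndarray, mobile: np.ndarray):
    """Horn's closed-form quaternion solution for optimal rigid superposition.

    Independent of the SVD route: builds the 4×4 key matrix from the
    coordinate cross-covariance and takes the eigenvector of its largest
    eigenvalue as the rotation quaternion.  Returns (R, t, rmsd).
    """
    fixed = np.asarray(fixed, float)
    mobile = np.asarray(mobile, float)
    cf, cm = fixed.mean(0), mobile.mean(0)
    y, x = fixed - cf, mobile - cm
    s = x.T @ y
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    w, v = np.linalg.eigh(k)
    q0, q1, q2, q3 = v[:, np.argmax(w)]
    rot = np.array(
        [
            [q0**2 + q1**2 - q2**2 - q3**2, 2 * (q1 * q2 - q0 * q3), 2 * (q1 * q3 + q0 * q2)],
            [2 * (q1 * q2 + q0 * q3), q0**2 - q1**2 + q2**2 - q3**2, 2 * (q2 * q3 - q0 * q1)],
            [2 * (q1 * q3 - q0 * q2), 2 * (q2 * q3 + q0 * q1), q0**2 - q1**2 - q2**2 + q3**2],
        ]
    )
    t = cf - rot @ cm
    diff = fixed - (mobile @ rot.T + t)
    rmsd = float(np.sqrt((diff**2).sum() / len(fixed)))
    return rot, t, rmsd


def phase1_closed_form_self_score(chain: ReducedChain) -> float:
    """#(H/E regions) + 0.5·#(L regions)."""
    return sum(1.0 if reg.sse is not SSEType.L else 0.5 for reg in chain.regions)
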