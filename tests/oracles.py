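"""Independent oracles used by the test suite.

Every oracle here deliberately takes a different computational route from
the package implementation it checks: quaternion eigenvalue superposition
vs SVD Kabsch, rotation-vector screw extraction vs trace/antisymmetric-part
decomposition, closed-form spherical caps vs point sampling, exhaustive
enumeration vs dynamic programming / KD-trees.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def quaternion_rmsd(moving: np.ndarray, fixed: np.ndarray) -> float:
    """Minimal RMSD via Horn's quaternion eigenvalue method."""
    P = np.asarray(moving, float) - np.mean(moving, axis=0)
    Q = np.asarray(fixed, float) - np.mean(fixed, axis=0)
    n = len(P)
    M = P.T @ Q
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    e2 = ((P**2).sum() + (Q**2).sum() - 2.0 * lam) / n
    return math.sqrt(max(e2, 0.0))


def screw_from_rotvec(rot: np.ndarray, trans: np.ndarray):
    """(angle_deg, unit axis with rise >= 0, rise) via scipy's rotation vector."""
    from scipy.spatial.transform import Rotation

    rv = Rotation.from_matrix(rot).as_rotvec()
    angle = math.degrees(np.linalg.norm(rv))
    axis = rv / np.linalg.norm(rv)
    rise = float(np.asarray(trans) @ axis)
    signed = angle
    if rise < 0:
        axis, rise, signed = -axis, -rise, -angle
    return abs(angle), axis, rise, signed


def sphere_area(radius: float, probe: float) -> float:
    return 4.0 * math.pi * (radius + probe) ** 2


def two_sphere_sasa(r1: float, r2: float, d: float, probe: float) -> tuple[float, float]:
    """Accessible areas of two overlapping probe-expanded spheres (caps removed)."""
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return 4 * math.pi * R1**2, 4 * math.pi * R2**2
    if d <= abs(R1 - R2):
        # smaller sphere fully engulfed
        if R1 > R2:
            return 4 * math.pi * R1**2, 0.0
        return 0.0, 4 * math.pi * R2**2
    # cap height on sphere 1 buried inside sphere 2
    h1 = R1 - (d**2 + R1**2 - R2**2) / (2 * d)
    h2 = R2 - (d**2 + R2**2 - R1**2) / (2 * d)
    a1 = 4 * math.pi * R1**2 - 2 * math.pi * R1 * h1
    a2 = 4 * math.pi * R2**2 - 2 * math.pi * R2 * h2
    return a1, a2


def exhaustive_global_alignment(
    a: str, b: str, matrix, gap_open: float, gap_extend: float
) -> float:
    """Best affine-gap global alignment score by exhaustive enumeration.

    Enumerates all monotone alignments of the two strings (viable only for
    short inputs) and scores each with affine gap penalties: a run of k
    consecutive gaps costs gap_open + (k - 1) * gap_extend.
    """
    best = [-math.inf]

    def score_gap_run(k: int) -> float:
        return gap_open + (k - 1) * gap_extend if k else 0.0

    def rec(i: int, j: int, acc: float, gap_a: int, gap_b: int):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], acc + score_gap_run(gap_a) + score_gap_run(gap_b))
            return
        if i < len(a) and j < len(b):
            rec(
                i + 1,
                j + 1,
                acc + matrix[a[i], b[j]] + score_gap_run(gap_a) + score_gap_run(gap_b),
                0,
                0,
            )
        if i < len(a):  # a[i] against gap in b
            rec(i + 1, j, acc + score_gap_run(gap_a), 0, gap_b + 1)
        if j < len(b):  # gap in a
            rec(i, j + 1, acc + score_gap_run(gap_b), gap_a + 1, 0)

    # note: the two gap runs cannot be interleaved ambiguously because we
    # close a run whenever the other kind of step is taken
    rec(0, 0, 0.0, 0, 0)
    return best[0]


def brute_force_pairs(atoms_a, atoms_b, d_max: float):
    """All cross pairs within d_max by a plain double loop."""
    out = []
    for i, x in enumerate(atoms_a):
        for j, y in enumerate(atoms_b):
            d = math.dist(x.pos, y.pos)
            if d <= d_max:
                out.append((i, j, d))
    return out


def brute_force_p1_neighbors(structure, radius: float, max_shift: int = 3):
    """Generator keys of P1 lattice copies within radius, by enumeration."""
    from dixpol.structure_model import apply_op

    asu = np.vstack([ch.coords() for ch in structure.chains])
    keys = set()
    rng = range(-max_shift, max_shift + 1)
    for ch in structure.chains:
        for sx, sy, sz in itertools.product(rng, rng, rng):
            shift = (sx, sy, sz)
            copy = apply_op(structure, ch.chain_id, 0, shift)
            if shift == (0, 0, 0):
                keys.add(copy.key)
                continue
            d = np.sqrt(
                ((copy.coords()[:, None, :] - asu[None, :, :]) ** 2).sum(axis=2)
            )
            if d.min() <= radius:
                keys.add(copy.key)
    return keys
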