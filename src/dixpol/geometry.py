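"""Rigid-body superposition and screw geometry of helical filaments.

A helical homopolymer is characterised by the screw transform relating
consecutive subunits: a rotation (*twist*, degrees per subunit) about the
filament axis combined with a translation (*rise*, Angstrom per subunit)
along it.  One full turn then spans ``pitch = rise * 360 / |twist|``
Angstroms and contains ``360 / |twist|`` subunits.

Handedness convention
---------------------
A filament is **left**-handed when successive subunits advance clockwise
viewed down the advance direction, i.e. when the twist is negative under the
right-hand rule with the axis oriented so the rise is non-negative.  Signed
twists are used throughout; ``HelixParameters.twist`` keeps the sign and the
derived quantities (pitch, subunits per turn) use its magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure_model import CoordinateSet

__all__ = [
    "SuperpositionResult",
    "ScrewParameters",
    "HelixParameters",
    "superpose",
    "superpose_arrays",
    "average_pairwise_rmsd",
    "screw_decompose",
    "screw_compose",
    "helix_parameters",
    "helix_parameters_from_coords",
    "dimer_rotation_difference",
    "rotation_angle_deg",
]


@dataclass
class SuperpositionResult:
    """Least-squares rigid fit: ``fixed ~ rot @ moving + trans``."""

    rot: np.ndarray
    trans: np.ndarray
    rmsd: float
    n_pairs: int


@dataclass
class ScrewParameters:
    """Axis/angle/rise decomposition of a proper rigid transform.

    ``axis`` is oriented so that ``rise >= 0``; ``angle`` is the unsigned
    rotation magnitude in degrees and ``twist`` the signed rotation about
    ``axis`` under the right-hand rule (negative = left-handed advance).
    """

    angle: float
    axis: np.ndarray
    rise: float
    handedness: str

    @property
    def twist(self) -> float:
        return -self.angle if self.handedness == "left" else self.angle


@dataclass
class HelixParameters:
    rise: float
    twist: float  # signed, degrees per subunit
    pitch: float
    subunits_per_turn: float
    handedness: str
    n_pairs_averaged: int
    axis: np.ndarray | None = None

    @classmethod
    def from_rise_twist(
        cls, rise: float, twist: float, n_pairs: int = 0, axis=None
    ) -> "HelixParameters":
        if twist == 0:
            raise ValueError("twist must be nonzero")
        return cls(
            rise=rise,
            twist=twist,
            pitch=rise * 360.0 / abs(twist),
            subunits_per_turn=360.0 / abs(twist),
            handedness="left" if twist < 0 else "right",
            n_pairs_averaged=n_pairs,
            axis=None if axis is None else np.asarray(axis, float),
        )


def _as_array(points) -> np.ndarray:
    if isinstance(points, CoordinateSet):
        return points.coords
    return np.asarray(points, dtype=float).reshape(-1, 3)


def superpose_arrays(moving: np.ndarray, fixed: np.ndarray) -> SuperpositionResult:
    """Kabsch least-squares superposition of paired point sets.

    Finds the proper rotation ``R`` and translation ``t`` minimising
    ``|R @ moving + t - fixed|``; reflections are corrected so
    ``det(R) = +1``.  Requires at least three non-collinear pairs.
    """
    P = _as_array(moving)
    Q = _as_array(fixed)
    if P.shape != Q.shape:
        raise ValueError(f"point sets differ in shape: {P.shape} vs {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 paired points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    # collinearity check: second principal extent must be non-degenerate
    if np.linalg.svd(P0, compute_uv=False)[1] < 1e-8:
        raise ValueError("degenerate (collinear) point set")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    delta = (P0 @ R.T) - Q0
    rmsd = float(np.sqrt((delta**2).sum() / n))
    return SuperpositionResult(rot=R, trans=t, rmsd=rmsd, n_pairs=n)


def superpose(moving, fixed) -> SuperpositionResult:
    """Superpose two order-paired coordinate sets (see superpose_arrays)."""
    return superpose_arrays(_as_array(moving), _as_array(fixed))


def pair_common_residues(
    a: CoordinateSet, b: CoordinateSet
) -> tuple[np.ndarray, np.ndarray]:
    """Pair two CA selections on shared author residue numbers."""
    map_a = {rid: pos for rid, _name, pos in a.entries}
    map_b = {rid: pos for rid, _name, pos in b.entries}
    common = sorted(set(map_a) & set(map_b))
    pa = np.array([map_a[r] for r in common], dtype=float).reshape(-1, 3)
    pb = np.array([map_b[r] for r in common], dtype=float).reshape(-1, 3)
    return pa, pb


def average_pairwise_rmsd(chains: list[CoordinateSet]) -> tuple[np.ndarray, float]:
    """Symmetric matrix and mean of pairwise CA RMSDs over common residues."""
    n = len(chains)
    if n < 2:
        raise ValueError("need at least two chains")
    mat = np.zeros((n, n))
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            pa, pb = pair_common_residues(chains[i], chains[j])
            if len(pa) < 3:
                raise ValueError(
                    f"chains {i} and {j} share fewer than 3 common residues"
                )
            r = superpose_arrays(pa, pb).rmsd
            mat[i, j] = mat[j, i] = r
            vals.append(r)
    return mat, float(np.mean(vals))


def rotation_angle_deg(rot: np.ndarray) -> float:
    """Unsigned rotation angle of a proper rotation matrix, degrees."""
    tr = float(np.trace(rot))
    return math.degrees(math.acos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0)))


def screw_decompose(rot: np.ndarray, trans: np.ndarray) -> ScrewParameters:
    """Decompose a rigid transform into screw (axis, angle, rise) form.

    The rotation angle comes from the trace, the axis from the antisymmetric
    part (eigen-decomposition near 180 deg), and the rise is the component of
    the translation along the axis.  The axis sign is chosen so the rise is
    non-negative; the signed twist follows the handedness convention in the
    module docstring.  Near-pure translations (angle < 0.1 deg) are rejected.
    """
    R = np.asarray(rot, dtype=float).reshape(3, 3)
    t = np.asarray(trans, dtype=float).reshape(3)
    if abs(np.linalg.det(R) - 1.0) > 1e-6 or not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
        raise ValueError("rot must be a proper orthonormal matrix")
    angle = rotation_angle_deg(R)
    if angle < 0.1:
        raise ValueError("pure translation: rotation angle below 0.1 degrees")

    if angle < 179.5:
        v = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
        axis = v / np.linalg.norm(v)  # right-hand rule: rotation is +angle about axis
    else:
        # antisymmetric part vanishes; axis spans the +1 eigenspace of R
        M = R + np.eye(3)
        col = M[:, int(np.argmax(np.linalg.norm(M, axis=0)))]
        axis = col / np.linalg.norm(col)

    rise = float(t @ axis)
    sign = 1.0
    if rise < 0:
        axis, rise, sign = -axis, -rise, -1.0
    twist = sign * angle
    handedness = "left" if twist < 0 else "right"
    return ScrewParameters(angle=abs(angle), axis=axis, rise=rise, handedness=handedness)


def screw_compose(
    angle_deg: float, axis: np.ndarray, rise: float, point: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Build the rigid transform of a screw about an axis through ``point``.

    Inverse of :func:`screw_decompose` (up to the axis location, which a
    decomposition of the rotation/translation pair does not need to fix).
    """
    from scipy.spatial.transform import Rotation

    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    R = Rotation.from_rotvec(np.radians(angle_deg) * a).as_matrix()
    p = np.zeros(3) if point is None else np.asarray(point, dtype=float)
    trans = p - R @ p + rise * a
    return R, trans


def _circular_mean_deg(angles_deg: np.ndarray) -> float:
    a = np.radians(np.asarray(angles_deg, dtype=float))
    return math.degrees(math.atan2(np.sin(a).sum(), np.cos(a).sum()))


def _circular_spread_deg(angles_deg: np.ndarray) -> float:
    m = _circular_mean_deg(angles_deg)
    d = (np.asarray(angles_deg) - m + 180.0) % 360.0 - 180.0
    return float(np.max(np.abs(d))) if len(d) else 0.0


def helix_parameters_from_coords(
    subunit_coords: list[np.ndarray], max_twist_spread: float = 15.0
) -> HelixParameters:
    """Helix parameters from the ordered subunits of one protofilament.

    Each consecutive pair is superposed (paired point sets, e.g. CA atoms of
    common residues) and screw-decomposed; the twist is averaged circularly,
    the rise arithmetically.  A twist spread beyond ``max_twist_spread``
    degrees raises ``ValueError`` ("not a regular helix").
    """
    if len(subunit_coords) < 2:
        raise ValueError("need at least two consecutive subunits")
    twists, rises, axes = [], [], []
    for a, b in zip(subunit_coords[:-1], subunit_coords[1:]):
        sup = superpose_arrays(a, b)
        sp = screw_decompose(sup.rot, sup.trans)
        twists.append(sp.twist)
        rises.append(sp.rise)
        axes.append(sp.axis)
    twists = np.array(twists)
    if _circular_spread_deg(twists) > max_twist_spread:
        raise ValueError(
            f"not a regular helix: twist spread {_circular_spread_deg(twists):.1f} deg "
            f"exceeds {max_twist_spread} deg"
        )
    mean_twist = _circular_mean_deg(twists)
    mean_rise = float(np.mean(rises))
    mean_axis = np.mean(np.array(axes), axis=0)
    nrm = np.linalg.norm(mean_axis)
    mean_axis = mean_axis / nrm if nrm > 0 else None
    return HelixParameters.from_rise_twist(
        mean_rise, mean_twist, n_pairs=len(rises), axis=mean_axis
    )


def helix_parameters(filament, max_twist_spread: float = 15.0) -> HelixParameters:
    """Helix parameters of a :class:`~dixpol.assembly.FilamentModel` protofilament.

    Accepts a FilamentModel (first protofilament is measured) or a plain list
    of per-subunit coordinate arrays.
    """
    if hasattr(filament, "protofilaments"):
        coords = _protofilament_ca_arrays(filament.protofilaments[0])
    else:
        coords = [_as_array(c) for c in filament]
    return helix_parameters_from_coords(coords, max_twist_spread=max_twist_spread)


def _protofilament_ca_arrays(copies) -> list[np.ndarray]:
    """CA arrays over the residues common to every subunit of a protofilament."""
    ca_maps = [c.ca_coords() for c in copies]
    common = sorted(set.intersection(*(set(m) for m in ca_maps)))
    if len(common) < 3:
        raise ValueError("protofilament subunits share fewer than 3 CA atoms")
    return [np.array([m[r] for r in common]) for m in ca_maps]


def dimer_rotation_difference(
    dimer_a: tuple[np.ndarray, np.ndarray],
    dimer_b: tuple[np.ndarray, np.ndarray],
    anchor: str = "tail",
) -> float:
    """Residual head rotation (degrees) between two head-to-tail dimers.

    Each dimer is given as (tail coords, head coords), already paired point
    by point between the two dimers.  The dimers are superposed on the anchor
    subunit (default the tail, which donates the beta2-beta1-beta5 sheet) and
    the rotation that then maps the other subunit of dimer A onto that of
    dimer B is returned as its angle.
    """
    if anchor not in ("tail", "head"):
        raise ValueError("anchor must be 'tail' or 'head'")
    ta, ha = (_as_array(x) for x in dimer_a)
    tb, hb = (_as_array(x) for x in dimer_b)
    if anchor == "head":
        ta, ha = ha, ta
        tb, hb = hb, tb
    sup_anchor = superpose_arrays(ta, tb)
    ha_t = ha @ sup_anchor.rot.T + sup_anchor.trans
    residual = superpose_arrays(ha_t, hb)
    return rotation_angle_deg(residual.rot)
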