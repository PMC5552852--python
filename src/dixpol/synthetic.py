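"""Synthetic helical-filament fixtures with exact ground truth.

The generator emulates what a crystal of a head-to-tail DIX-domain polymer
gives the pipeline: a rigid pseudo-domain repeated along an ideal screw axis
(stated rise, twist and handedness), optionally a second protofilament
related by a stated rotation and axial offset, optional isotropic Gaussian
coordinate noise, all packed into a triclinic P1 cell whose c edge equals
the filament repeat so that lattice translation genuinely extends the
filament.

Each subunit is one chain.  Besides a compact jittered-lattice body, every
subunit carries an idealized parallel beta-bridge: a three-residue "beta2"
strand (residues 1-3) and a "beta4" strand (residues 4-6) placed so that the
beta4 amides of subunit k sit exactly 2.9 A from the beta2 carbonyls of
subunit k+1 -- three main-chain hydrogen bonds per interface, the canonical
head-to-tail signature.  Double-helical specs additionally plant a salt
bridge (Asp loop12 / Lys beta4) and a hydrophobic pair (Leu loop12 /
Leu loop34) across the two protofilaments, giving the typed-contact
detectors a known inventory.

No attempt is made at chemically realistic protein geometry; only rigid-body
and contact geometry matter to the pipeline.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .geometry import HelixParameters
from .structure_model import (
    Atom,
    Chain,
    CrystalStructure,
    Residue,
    SymOp,
    UnitCell,
    write_structure,
)

__all__ = ["FilamentSpec", "GroundTruth", "make_toy_subunit", "generate_filament", "write_fixture", "read_ground_truth"]

BODY_FIRST_RESIDUE = 10


@dataclass
class FilamentSpec:
    """Recipe for one synthetic crystal.

    rise: A per subunit; twist: signed degrees per subunit (negative =
    left-handed); second_strand: optional (phase_deg, axial_offset_A)
    relating the second protofilament to the first about the common axis.
    """

    rise: float = 11.43
    twist: float = -360.0 / 7.0  # seven subunits per left-handed turn
    n_subunits: int = 7
    second_strand: tuple[float, float] | None = None
    noise_sigma: float = 0.0
    seed: int = 0
    cell_padding: float = 25.0
    subunit_atoms: int = 40
    # large enough that the two strands of a double helix touch only through
    # the planted zipper atoms, not their bodies
    helix_radius: float = 18.0

    def __post_init__(self) -> None:
        if self.twist == 0:
            raise ValueError("twist must be nonzero")
        if self.n_subunits < 3:
            raise ValueError("need at least 3 subunits")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass
class GroundTruth:
    helix: HelixParameters
    architecture: str
    planted_contacts: list[dict] = field(default_factory=list)
    seed: int = 0
    n_subunits: int = 0
    chains_strand1: list[str] = field(default_factory=list)
    chains_strand2: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "helix": {
                "rise": self.helix.rise,
                "twist": self.helix.twist,
                "pitch": self.helix.pitch,
                "subunits_per_turn": self.helix.subunits_per_turn,
                "handedness": self.helix.handedness,
            },
            "architecture": self.architecture,
            "planted_contacts": self.planted_contacts,
            "seed": self.seed,
            "n_subunits": self.n_subunits,
            "chains_strand1": self.chains_strand1,
            "chains_strand2": self.chains_strand2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        h = d["helix"]
        return cls(
            helix=HelixParameters.from_rise_twist(h["rise"], h["twist"]),
            architecture=d["architecture"],
            planted_contacts=list(d.get("planted_contacts", [])),
            seed=d.get("seed", 0),
            n_subunits=d.get("n_subunits", 0),
            chains_strand1=list(d.get("chains_strand1", [])),
            chains_strand2=list(d.get("chains_strand2", [])),
        )


def _rot_z(deg: float) -> np.ndarray:
    t = math.radians(deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def make_toy_subunit(seed: int, n_atoms: int = 40) -> list[Residue]:
    """Compact pseudo-domain on a jittered lattice, gyration radius ~8 A.

    Residues are four-atom ALA-like bodies (side-chain carbon names, so they
    are inert to the main-chain hydrogen-bond detector) plus a handful of
    designated polar/hydrophobic marker atoms (SER OG, LYS NZ, ASP OD1,
    LEU CD1) useful for contact-detector toys.  Deterministic for a given
    seed.
    """
    if n_atoms < 10:
        raise ValueError("n_atoms must be >= 10")
    rng = np.random.default_rng(seed)
    # jittered cubic lattice inside a sphere, scaled to gyration radius ~8
    side = int(math.ceil(n_atoms ** (1 / 3))) + 1
    grid = np.array(
        [[x, y, z] for x in range(side) for y in range(side) for z in range(side)],
        dtype=float,
    )
    grid -= grid.mean(axis=0)
    order = np.argsort(np.linalg.norm(grid, axis=1), kind="stable")
    pts = grid[order[:n_atoms]] * 3.4 + rng.normal(0.0, 0.45, (n_atoms, 3))
    rg = math.sqrt(float((np.linalg.norm(pts - pts.mean(0), axis=1) ** 2).mean()))
    pts *= 8.0 / max(rg, 1e-6)

    marker_cycle = [
        ("SER", "OG", "O"),
        ("LYS", "NZ", "N"),
        ("ASP", "OD1", "O"),
        ("LEU", "CD1", "C"),
    ]
    residues: list[Residue] = []
    per_res = 4
    n_res = (n_atoms + per_res - 1) // per_res
    k = 0
    for ri in range(n_res):
        chunk = pts[ri * per_res: (ri + 1) * per_res]
        if ri % 5 == 4 and len(chunk) == per_res:
            resname, special, elem = marker_cycle[(ri // 5) % len(marker_cycle)]
            names = ["CA", "CB", "CG1", special]
            elems = ["C", "C", "C", elem]
        else:
            resname = "ALA"
            names = ["CA", "CB", "CG1", "CG2"][: len(chunk)]
            elems = ["C"] * len(chunk)
        atoms = [
            Atom(name=nm, element=el, pos=p, b_factor=20.0)
            for nm, el, p in zip(names, elems, chunk)
        ]
        residues.append(Residue(seq_id=BODY_FIRST_RESIDUE + ri, name=resname, atoms=atoms))
        k += len(chunk)
    return residues


def _beta_bridge_strands(rise: float, twist: float, radius: float):
    """beta2 (residues 1-3) and beta4 (residues 4-6) template residues.

    beta4 amide nitrogens are the screw image of the beta2 carbonyl oxygens
    displaced 2.9 A perpendicular to the (rotated) strand direction, so
    exactly three main-chain N...O bonds of 2.9 A link consecutive subunits.
    """
    S_rot = _rot_z(twist)
    S_tr = np.array([0.0, 0.0, rise])
    strand_dir = np.array([0.0, 1.0, 0.0])
    base = np.array([radius + 5.0, -3.4, 1.0])

    beta2: list[Residue] = []
    n_pos, o_pos = [], []
    for r in range(3):
        s = base + strand_dir * (3.4 * r)
        n = s + np.array([0.0, -1.0, 0.0])
        ca = s + np.array([0.7, -0.4, 0.5])
        c = s + np.array([0.4, 0.4, 0.0])
        o = s + np.array([0.0, 0.7, 0.0])
        n_pos.append(n)
        o_pos.append(o)
        beta2.append(
            Residue(
                seq_id=1 + r,
                name="GLY",
                atoms=[
                    Atom("N", "N", n),
                    Atom("CA", "C", ca),
                    Atom("C", "C", c),
                    Atom("O", "O", o),
                ],
            )
        )

    rot_dir = S_rot @ strand_dir
    perp = np.cross(rot_dir, np.array([0.0, 0.0, 1.0]))
    perp /= np.linalg.norm(perp)
    # point away from the helix axis so the bridge sits on the outside
    probe = S_rot @ o_pos[1] + S_tr
    if float(perp @ np.array([probe[0], probe[1], 0.0])) < 0:
        perp = -perp

    beta4: list[Residue] = []
    for r in range(3):
        n = S_rot @ o_pos[r] + S_tr + 2.9 * perp
        ca = n + rot_dir * 1.2 + np.array([0.0, 0.0, 0.4])
        c = n + rot_dir * 2.0
        o = n + 2.2 * perp  # kept off the bridge line: no extra N...O bond
        resname = "LYS" if r == 1 else "GLY"
        beta4.append(
            Residue(
                seq_id=4 + r,
                name=resname,
                atoms=[
                    Atom("N", "N", n),
                    Atom("CA", "C", ca),
                    Atom("C", "C", c),
                    Atom("O", "O", o),
                ],
            )
        )
    return beta2, beta4


def _apply(rot: np.ndarray, tr: np.ndarray, residues: list[Residue]) -> list[Residue]:
    return [
        Residue(
            seq_id=r.seq_id,
            name=r.name,
            atoms=[
                Atom(a.name, a.element, rot @ a.pos + tr, a.occupancy, a.b_factor)
                for a in r.atoms
            ],
        )
        for r in residues
    ]


def generate_filament(spec: FilamentSpec) -> tuple[CrystalStructure, GroundTruth]:
    """Build a P1 crystal holding one (or two) ideal helical protofilaments.

    Subunit k of the first protofilament is the template transformed by the
    screw (k * twist about z, k * rise along z); the optional second
    protofilament applies the stated phase rotation and axial offset first.
    Gaussian noise (sigma = spec.noise_sigma) is added per atom with the
    spec seed.  The c cell edge equals n_subunits * rise, so the +/-c
    lattice translations of the crystal extend the filament; a and b are
    sized to the content plus ``cell_padding``.  Raises when the two strands
    clash (inter-strand minimum distance < 1.5 A).
    """
    rng = np.random.default_rng(spec.seed)
    body = make_toy_subunit(spec.seed, spec.subunit_atoms)
    # subunits in a filament stack at the rise, so the body's axial extent is
    # compressed to the stacking distance (lateral dimensions untouched)
    pts = np.vstack([[a.pos for a in r.atoms] for r in body])
    z_half = float(np.abs(pts[:, 2] - pts[:, 2].mean()).max())
    fz = min(1.0, 0.45 * spec.rise / max(z_half, 1e-9))
    squash = np.diag([1.0, 1.0, fz])
    body = _apply(squash, np.zeros(3), body)
    body = _apply(np.eye(3), np.array([spec.helix_radius, 0.0, spec.rise * 0.5]), body)
    beta2, beta4 = _beta_bridge_strands(spec.rise, spec.twist, spec.helix_radius)
    template = beta2 + beta4 + body

    S_rot = _rot_z(spec.twist)
    S_tr = np.array([0.0, 0.0, spec.rise])

    def world(k: int, second: bool) -> tuple[np.ndarray, np.ndarray]:
        rot = np.linalg.matrix_power(S_rot, k)
        tr = np.array([0.0, 0.0, spec.rise * k])
        if second:
            phase, offset = spec.second_strand  # type: ignore[misc]
            rot2 = _rot_z(phase)
            tr2 = np.array([0.0, 0.0, offset])
            return rot @ rot2, rot @ tr2 + tr
        return rot, tr

    planted: list[dict] = []
    templates = [template, template]
    if spec.second_strand is not None:
        plants = _planted_interfilament_residues(spec, world, planted)
        # each strand carries only its own half of the zipper contacts
        templates = [
            _merge_residues(template, [r for s, r in plants if s == 0]),
            _merge_residues(template, [r for s, r in plants if s == 1]),
        ]

    chains: list[Chain] = []
    labels = [chr(ord("A") + i) for i in range(2 * spec.n_subunits)]
    strand1 = labels[: spec.n_subunits]
    strand2 = labels[spec.n_subunits: 2 * spec.n_subunits] if spec.second_strand else []
    coords_by_strand: list[np.ndarray] = []
    for strand_idx, strand_labels in enumerate([strand1] + ([strand2] if strand2 else [])):
        strand_pts = []
        for k, label in enumerate(strand_labels):
            rot, tr = world(k, strand_idx == 1)
            residues = _apply(rot, tr, templates[strand_idx])
            if spec.noise_sigma > 0:
                for r in residues:
                    for a in r.atoms:
                        a.pos = a.pos + rng.normal(0.0, spec.noise_sigma, 3)
            chains.append(Chain(chain_id=label, residues=residues))
            strand_pts.append(chains[-1].coords())
        coords_by_strand.append(np.vstack(strand_pts))

    if len(coords_by_strand) == 2:
        from scipy.spatial import cKDTree

        d, _ = cKDTree(coords_by_strand[0]).query(coords_by_strand[1], k=1)
        if float(np.min(d)) < 1.5:
            raise ValueError(
                f"clashing strands: inter-strand minimum distance "
                f"{float(np.min(d)):.2f} A < 1.5 A"
            )

    all_xyz = np.vstack(coords_by_strand)
    pad = spec.cell_padding
    a_edge = float(np.ptp(all_xyz[:, 0]) + 2 * pad)
    b_edge = float(np.ptp(all_xyz[:, 1]) + 2 * pad)
    # A lattice translation along c continues the helix only when a full cell
    # of subunits rotates by a multiple of 360 deg; otherwise the cell merely
    # contains the filament, with padding so the +/-c copies stay clear.
    wrap = abs((spec.n_subunits * spec.twist + 180.0) % 360.0 - 180.0)
    if wrap < 1e-6:
        c_edge = float(spec.n_subunits * spec.rise)
    else:
        c_edge = float(spec.n_subunits * spec.rise + 2 * pad)
    cell = UnitCell(a_edge, b_edge, c_edge, 90.0, 90.0, 90.0)

    structure = CrystalStructure(
        chains=chains,
        waters=[],
        cell=cell,
        symops=[SymOp(np.eye(3), np.zeros(3))],
        space_group="P 1",
        name=f"synthetic rise={spec.rise} twist={spec.twist}",
    )
    truth = GroundTruth(
        helix=HelixParameters.from_rise_twist(
            spec.rise, spec.twist, n_pairs=spec.n_subunits - 1, axis=[0, 0, 1]
        ),
        architecture="double" if spec.second_strand else "single",
        planted_contacts=planted,
        seed=spec.seed,
        n_subunits=spec.n_subunits,
        chains_strand1=strand1,
        chains_strand2=strand2,
    )
    return structure, truth


def _merge_residues(template: list[Residue], extra: list[Residue]) -> list[Residue]:
    """Merge extra residues/atoms into a template by author residue number."""
    by_id = {r.seq_id: Residue(r.seq_id, r.name, list(r.atoms)) for r in template}
    for r in extra:
        if r.seq_id in by_id:
            by_id[r.seq_id].atoms.extend(r.atoms)
        else:
            by_id[r.seq_id] = r
    return [by_id[i] for i in sorted(by_id)]


def _planted_interfilament_residues(spec: FilamentSpec, world, planted: list[dict]) -> list[Residue]:
    """Marker residues realizing the zipper contacts of a double helix.

    In world space, midway between strand-2 subunit 0 and its nearest
    strand-1 subunit j*, a salt-bridge pair (Lys NZ on strand 1 / Asp OD1 on
    strand 2, 3.0 A) and a hydrophobic pair (two Leu CD1 carbons, 4.0 A) are
    placed, then pulled back into the shared template so the contacts repeat
    all along the seam.  Atom bookkeeping: NZ lives on residue 5 (beta4),
    OD1 on residue 8 (loop12), the Leu carbons on residues 26 (loop34) and
    9 (loop12).
    """
    # representative template centroid (body sits near (R, 0, rise/2))
    c_template = np.array([spec.helix_radius, 0.0, spec.rise * 0.5])
    rot2, tr2 = world(0, True)
    c2 = rot2 @ c_template + tr2
    best_j, best_d = 0, np.inf
    for j in range(spec.n_subunits - 1):
        rot1, tr1 = world(j, False)
        c1 = rot1 @ c_template + tr1
        d = float(np.linalg.norm(c1 - c2))
        if d < best_d:
            best_j, best_d = j, d
    if best_d < 3.0:
        raise ValueError(
            f"clashing strands: protofilament centroids {best_d:.2f} A apart"
        )
    inv2_rot, inv2_tr = rot2.T, -rot2.T @ tr2

    def _midpoint_pair(j: int, lateral: float):
        rot1, tr1 = world(j, False)
        c1 = rot1 @ c_template + tr1
        u = (c2 - c1) / max(np.linalg.norm(c2 - c1), 1e-9)
        v = np.cross(u, np.array([0.0, 0.0, 1.0]))
        if np.linalg.norm(v) < 1e-6:
            v = np.cross(u, np.array([1.0, 0.0, 0.0]))
        v /= np.linalg.norm(v)
        mid = 0.5 * (c1 + c2) + lateral * v
        return (rot1.T, -rot1.T @ tr1), mid, u

    # type II-style salt bridge toward the nearest strand-1 subunit
    (inv1_rot, inv1_tr), mid, u = _midpoint_pair(best_j, 3.0)
    q_nz = mid - 1.5 * u
    q_od = mid + 1.5 * u
    # type I-style hydrophobic pair toward the next strand-1 subunit up
    (inv1b_rot, inv1b_tr), mid_b, u_b = _midpoint_pair(best_j + 1, -3.0)
    q_cd_a = mid_b - 2.0 * u_b
    q_cd_b = mid_b + 2.0 * u_b

    res = [
        (0, Residue(5, "LYS", [Atom("NZ", "N", inv1_rot @ q_nz + inv1_tr)])),
        (1, Residue(8, "ASP", [Atom("OD1", "O", inv2_rot @ q_od + inv2_tr)])),
        (0, Residue(26, "LEU", [Atom("CD1", "C", inv1b_rot @ q_cd_a + inv1b_tr)])),
        (1, Residue(9, "LEU", [Atom("CD1", "C", inv2_rot @ q_cd_b + inv2_tr)])),
    ]
    planted.append(
        {
            "kind": "salt_bridge",
            "site": "typeII",
            "strand1_residue": ["LYS", 5],
            "strand2_residue": ["ASP", 8],
            "distance": 3.0,
            "strand1_subunit_offset": best_j,
        }
    )
    planted.append(
        {
            "kind": "hydrophobic",
            "site": "typeI",
            "strand1_residue": ["LEU", 26],
            "strand2_residue": ["LEU", 9],
            "distance": 4.0,
            "strand1_subunit_offset": best_j + 1,
        }
    )
    return res


def write_fixture(
    structure: CrystalStructure,
    ground_truth: GroundTruth,
    directory: str,
    basename: str = "fixture",
    format: str = "pdb",
) -> dict[str, str]:
    """Write coordinates (PDB or mmCIF) plus JSON ground truth; returns paths."""
    os.makedirs(directory, exist_ok=True)
    ext = {"pdb": "pdb", "mmcif": "cif"}[format]
    coord_path = os.path.join(directory, f"{basename}.{ext}")
    json_path = os.path.join(directory, f"{basename}.truth.json")
    write_structure(structure, coord_path, format=format)
    with open(json_path, "w") as fh:
        json.dump(ground_truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"coordinates": coord_path, "ground_truth": json_path}


def read_ground_truth(path: str) -> GroundTruth:
    with open(path) as fh:
        return GroundTruth.from_dict(json.load(fh))
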