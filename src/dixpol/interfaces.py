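"""Solvent accessibility, buried interface area, and typed contacts.

Accessible surface area follows the classic sphere-sampling construction: a
probe of radius 1.4 A is rolled over van der Waals spheres, approximated by a
deterministic golden-spiral point lattice on each expanded sphere.  Before
sampling, coordinates are moved into a canonical frame derived from the
molecule's own principal axes, so the point lattice rotates with the molecule
and the computed area is invariant under rigid motion to floating-point
precision.

Buried surface area (BSA) of a pair is reported as the sum of the area each
partner loses on complex formation (dASA_A + dASA_B).  The per-side values
are always available, since published interface areas are quoted in both
conventions.

Contact typing is heavy-atom and distance-only: the crystal structures this
package targets carry no hydrogens, so donor/acceptor roles are assigned
from atom identity and no angular criteria are applied.  Default cutoffs:
hydrogen bond 3.5 A (N/O donor...acceptor), salt bridge 4.0 A (Asp/Glu
side-chain O vs Lys/Arg/His side-chain N), hydrophobic 4.5 A (side-chain
C...C), water-mediated 3.5 A per leg.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_model import Atom, Chain, PlacedCopy

__all__ = [
    "RadiiTable",
    "ContactRecord",
    "InterfaceReport",
    "AtomRef",
    "atoms_of",
    "sasa",
    "buried_surface_area",
    "find_hbonds",
    "find_salt_bridges",
    "find_water_mediated",
    "find_hydrophobic",
    "interface_fingerprint",
]

MAINCHAIN_NAMES = {"N", "CA", "C", "O"}


@dataclass
class RadiiTable:
    """Van der Waals radii by element, plus probe radius (Angstrom)."""

    radii: dict[str, float] = field(
        default_factory=lambda: {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
    )
    probe: float = 1.4
    fallback: float = 1.70

    def radius(self, element: str) -> float:
        r = self.radii.get(element.upper().strip())
        if r is None:
            warnings.warn(
                f"no van der Waals radius for element {element!r}; "
                f"using fallback {self.fallback} A"
            )
            return self.fallback
        return r


@dataclass(frozen=True)
class AtomRef:
    """An atom with enough identity for contact bookkeeping."""

    copy_id: str
    res_id: int
    res_name: str
    atom_name: str
    element: str
    pos: tuple[float, float, float]

    @property
    def xyz(self) -> np.ndarray:
        return np.array(self.pos, dtype=float)


@dataclass
class ContactRecord:
    kind: str  # hbond | mainchain_hbond | salt_bridge | hydrophobic | water_mediated
    atom_a: AtomRef
    atom_b: AtomRef
    distance: float
    water: AtomRef | None = None
    waters: tuple[AtomRef, ...] = ()
    site: str = "unassigned"

    def residues(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return (
            (self.atom_a.copy_id, self.atom_a.res_id),
            (self.atom_b.copy_id, self.atom_b.res_id),
        )


@dataclass
class InterfaceReport:
    bsa_total: float
    bsa_per_side: tuple[float, float]
    contacts: list[ContactRecord]

    def by_kind(self, kind: str) -> list[ContactRecord]:
        return [c for c in self.contacts if c.kind == kind]

    def by_site(self, site: str) -> list[ContactRecord]:
        return [c for c in self.contacts if c.site == site]


def atoms_of(obj, copy_id: str | None = None) -> list[AtomRef]:
    """Flatten a Chain / PlacedCopy / list of AtomRef into AtomRef records."""
    if isinstance(obj, PlacedCopy):
        cid = copy_id or f"{obj.source_chain}/{obj.op_index}/{obj.lattice_shift}"
        return atoms_of(obj.chain, copy_id=cid)
    if isinstance(obj, Chain):
        cid = copy_id or obj.chain_id
        return [
            AtomRef(cid, r.seq_id, r.name, a.name, a.element, tuple(a.pos))
            for r in obj.residues
            for a in r.atoms
        ]
    if isinstance(obj, (list, tuple)) and (not obj or isinstance(obj[0], AtomRef)):
        return list(obj)
    raise TypeError(f"cannot interpret {type(obj)} as an atom list")


def water_refs(waters: list[Atom], copy_id: str = "W") -> list[AtomRef]:
    return [
        AtomRef(copy_id, i + 1, "HOH", w.name, w.element, tuple(w.pos))
        for i, w in enumerate(waters)
    ]


# ---------------------------------------------------------------------------
# SASA


def _golden_spiral(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden-angle spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _canonical_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid + principal-axes rotation, sign-fixed by third moments.

    The frame is equivariant: rotating the molecule rotates the frame with
    it, which is what makes the sampled SASA rotation-invariant.
    """
    centroid = coords.mean(axis=0)
    X = coords - centroid
    if len(coords) < 3:
        return centroid, np.eye(3)
    cov = X.T @ X
    _w, vecs = np.linalg.eigh(cov)
    thirds = []
    for k in range(3):
        proj = X @ vecs[:, k]
        s = float((proj**3).sum())
        if s < 0 or (s == 0 and vecs[0, k] < 0):
            vecs[:, k] = -vecs[:, k]
            s = -s
        thirds.append(abs(s))
    if np.linalg.det(vecs) < 0:
        vecs[:, int(np.argmin(thirds))] *= -1
    return centroid, vecs


def _sample_areas(coords: np.ndarray, expanded: np.ndarray, n_points: int) -> np.ndarray:
    """Shrake-Rupley sampling in the frame the coordinates arrive in."""
    unit = _golden_spiral(n_points)
    tree = cKDTree(coords)
    rmax = expanded.max() if len(expanded) else 0.0
    areas = np.zeros(len(coords))
    for i, (c, ri) in enumerate(zip(coords, expanded)):
        nbrs = [j for j in tree.query_ball_point(c, ri + rmax) if j != i]
        # coincident-sphere tie-break: the lower-index duplicate keeps its
        # surface, the higher-index one contributes nothing
        if any(
            j < i
            and expanded[j] >= ri - 1e-9
            and float(np.linalg.norm(coords[j] - c)) < 1e-6
            for j in nbrs
        ):
            continue
        pts = c + ri * unit
        if nbrs:
            d2 = ((pts[:, None, :] - coords[nbrs][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (expanded[nbrs] ** 2)[None, :] - 1e-9).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * math.pi * ri * ri
    return areas


def sasa(
    atoms,
    radii: RadiiTable | None = None,
    n_points: int = 960,
    canonicalize: bool = True,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Angstrom^2).

    ``atoms`` is a list of AtomRef (or anything :func:`atoms_of` accepts).
    ``n_points`` test points are placed on each probe-expanded sphere; a
    point survives if it lies outside every other expanded sphere.
    """
    refs = atoms_of(atoms)
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    radii = radii or RadiiTable()
    coords = np.array([a.pos for a in refs], dtype=float).reshape(-1, 3)
    expanded = np.array([radii.radius(a.element) + radii.probe for a in refs])
    if canonicalize and len(coords) >= 3:
        centroid, frame = _canonical_frame(coords)
        coords = (coords - centroid) @ frame
    return _sample_areas(coords, expanded, n_points)


def buried_surface_area(
    part_a,
    part_b,
    radii: RadiiTable | None = None,
    n_points: int = 960,
) -> tuple[float, tuple[float, float]]:
    """Interface area buried between two atom sets.

    Returns ``(bsa_total, (bsa_a, bsa_b))`` where ``bsa_x`` is the SASA atom
    set ``x`` loses when the complex forms and ``bsa_total`` their sum.
    Raises if an identical atom appears on both sides.
    """
    a = atoms_of(part_a)
    b = atoms_of(part_b)
    keys_a = {(r.copy_id, r.res_id, r.atom_name) for r in a}
    keys_b = {(r.copy_id, r.res_id, r.atom_name) for r in b}
    if keys_a & keys_b:
        raise ValueError(f"atoms shared between both parts: {sorted(keys_a & keys_b)[:3]}")
    radii = radii or RadiiTable()
    coords = np.array([r.pos for r in a + b], dtype=float).reshape(-1, 3)
    expanded = np.array([radii.radius(r.element) + radii.probe for r in a + b])
    # one shared frame for part-alone and complex evaluations, so atoms far
    # from the interface keep identical sample points and cancel exactly
    centroid, frame = _canonical_frame(coords)
    coords = (coords - centroid) @ frame
    na = len(a)
    sasa_a = _sample_areas(coords[:na], expanded[:na], n_points)
    sasa_b = _sample_areas(coords[na:], expanded[na:], n_points)
    sasa_ab = _sample_areas(coords, expanded, n_points)
    bsa_a = float(sasa_a.sum() - sasa_ab[:na].sum())
    bsa_b = float(sasa_b.sum() - sasa_ab[na:].sum())
    return bsa_a + bsa_b, (bsa_a, bsa_b)


# ---------------------------------------------------------------------------
# donor / acceptor chemistry (heavy-atom, identity-based)

_SIDECHAIN_DONORS = {
    ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("ASN", "ND2"), ("GLN", "NE2"), ("HIS", "ND1"), ("HIS", "NE2"),
    ("TRP", "NE1"), ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
}
_SIDECHAIN_ACCEPTORS = {
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"), ("HIS", "ND1"), ("HIS", "NE2"),
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
}

_ACIDIC_O = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_BASIC_N = {
    ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("HIS", "ND1"), ("HIS", "NE2"),
}


def _is_donor(a: AtomRef) -> bool:
    if a.atom_name == "N":
        return True  # backbone amide
    key = (a.res_name, a.atom_name)
    if key in _SIDECHAIN_DONORS:
        return True
    # toy/unknown residues: any polar atom may donate
    return a.res_name not in _KNOWN_RES and a.element in ("N", "O")


def _is_acceptor(a: AtomRef) -> bool:
    if a.atom_name == "O":
        return True  # backbone carbonyl
    key = (a.res_name, a.atom_name)
    if key in _SIDECHAIN_ACCEPTORS:
        return True
    return a.res_name not in _KNOWN_RES and a.element in ("N", "O")


_KNOWN_RES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def _hbond_capable(a: AtomRef) -> bool:
    return a.element in ("N", "O")


def _cross_pairs(a: list[AtomRef], b: list[AtomRef], d_max: float):
    """(i, j, distance) for all cross pairs within d_max."""
    if not a or not b:
        return
    ca = np.array([x.pos for x in a], dtype=float)
    cb = np.array([x.pos for x in b], dtype=float)
    tree = cKDTree(cb)
    for i, p in enumerate(ca):
        for j in tree.query_ball_point(p, d_max):
            yield i, j, float(np.linalg.norm(p - cb[j]))


def find_hbonds(part_a, part_b, d_max: float = 3.5) -> list[ContactRecord]:
    """Donor...acceptor N/O pairs across two atom sets within ``d_max``.

    Main-chain N...O pairs are flagged ``mainchain_hbond``; every record is
    reported once per unordered atom pair.
    """
    a = atoms_of(part_a)
    b = atoms_of(part_b)
    records: dict[tuple, ContactRecord] = {}
    for i, j, d in _cross_pairs(a, b, d_max):
        x, y = a[i], b[j]
        ok = (_is_donor(x) and _is_acceptor(y)) or (_is_donor(y) and _is_acceptor(x))
        if not ok:
            continue
        mc = (
            x.atom_name in ("N", "O")
            and y.atom_name in ("N", "O")
            and x.atom_name != y.atom_name
        )
        kind = "mainchain_hbond" if mc else "hbond"
        key = (x.copy_id, x.res_id, x.atom_name, y.copy_id, y.res_id, y.atom_name)
        if key not in records:
            records[key] = ContactRecord(kind=kind, atom_a=x, atom_b=y, distance=d)
    return sorted(
        records.values(),
        key=lambda r: (r.atom_a.res_id, r.atom_a.atom_name, r.atom_b.res_id, r.atom_b.atom_name),
    )


def find_salt_bridges(part_a, part_b, d_max: float = 4.0) -> list[ContactRecord]:
    """Asp/Glu side-chain O vs Lys/Arg/His side-chain N pairs within d_max."""
    a = atoms_of(part_a)
    b = atoms_of(part_b)

    def roles(at: AtomRef) -> str | None:
        key = (at.res_name, at.atom_name)
        if key in _ACIDIC_O:
            return "acid"
        if key in _BASIC_N:
            return "base"
        return None

    out = []
    for i, j, d in _cross_pairs(a, b, d_max):
        ra, rb = roles(a[i]), roles(b[j])
        if {ra, rb} == {"acid", "base"}:
            out.append(ContactRecord("salt_bridge", a[i], b[j], d))
    return sorted(out, key=lambda r: (r.atom_a.res_id, r.atom_b.res_id, r.distance))


def find_hydrophobic(part_a, part_b, d_max: float = 4.5) -> list[ContactRecord]:
    """Side-chain carbon...carbon contacts, aggregated per residue pair.

    One record per residue pair, carrying the closest C...C distance.
    """
    a = [x for x in atoms_of(part_a) if x.element == "C" and x.atom_name not in MAINCHAIN_NAMES]
    b = [x for x in atoms_of(part_b) if x.element == "C" and x.atom_name not in MAINCHAIN_NAMES]
    best: dict[tuple, ContactRecord] = {}
    for i, j, d in _cross_pairs(a, b, d_max):
        key = (a[i].copy_id, a[i].res_id, b[j].copy_id, b[j].res_id)
        if key not in best or d < best[key].distance:
            best[key] = ContactRecord("hydrophobic", a[i], b[j], d)
    return sorted(best.values(), key=lambda r: (r.atom_a.res_id, r.atom_b.res_id))


def find_water_mediated(
    part_a, part_b, waters, d_max: float = 3.5, depth: int = 1
) -> list[ContactRecord]:
    """Hydrogen bonds bridged by one (depth 1) or two (depth 2) waters.

    A record links an H-bond-capable atom of each part through water oxygens
    with every leg within ``d_max``.
    """
    a = [x for x in atoms_of(part_a) if _hbond_capable(x)]
    b = [x for x in atoms_of(part_b) if _hbond_capable(x)]
    if isinstance(waters, list) and waters and isinstance(waters[0], Atom):
        w = water_refs(waters)
    else:
        w = atoms_of(waters)
    out: list[ContactRecord] = []
    if not (a and b and w):
        return out
    wc = np.array([x.pos for x in w], dtype=float)

    def near(refs: list[AtomRef], point: np.ndarray) -> list[tuple[AtomRef, float]]:
        res = []
        for r in refs:
            d = float(np.linalg.norm(r.xyz - point))
            if d <= d_max:
                res.append((r, d))
        return res

    for wi, wat in enumerate(w):
        na = near(a, wc[wi])
        nb = near(b, wc[wi])
        for ra, da in na:
            for rb, db in nb:
                out.append(
                    ContactRecord(
                        "water_mediated", ra, rb, max(da, db), water=wat, waters=(wat,)
                    )
                )
    if depth >= 2:
        seen = {(r.atom_a, r.atom_b, r.waters) for r in out}
        for wi, w1 in enumerate(w):
            for wj, w2 in enumerate(w):
                if wi == wj or np.linalg.norm(wc[wi] - wc[wj]) > d_max:
                    continue
                for ra, da in near(a, wc[wi]):
                    for rb, db in near(b, wc[wj]):
                        rec = ContactRecord(
                            "water_mediated", ra, rb, max(da, db), water=w1, waters=(w1, w2)
                        )
                        if (rec.atom_a, rec.atom_b, rec.waters) not in seen:
                            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# combined fingerprint


def _region_of(res_id: int, regions: dict[str, tuple[int, int]]) -> str | None:
    for name, (lo, hi) in regions.items():
        if lo <= res_id <= hi:
            return name
    return None


_SHEET_REGIONS = {"beta1", "beta5", "beta3", "beta4"}


def assign_site(
    rec: ContactRecord, regions_a: dict, regions_b: dict
) -> str:
    """Classify a contact into the interface sites of the head-to-tail /
    zipper nomenclature.

    Head-to-tail contacts: *site1* couples the beta3/beta4 edge to the
    beta2-beta1-beta5 sheet; *site2* couples beta4 to loop beta1-beta2.
    Inter-filament contacts: *typeI* couples loop beta1-beta2 to loop
    beta3-beta4; *typeII* couples loop beta1-beta2 to the sheet.
    """
    ra = _region_of(rec.atom_a.res_id, regions_a)
    rb = _region_of(rec.atom_b.res_id, regions_b)
    pair = {ra, rb}
    if ra is None or rb is None:
        return "unassigned"
    if pair == {"loop12", "loop34"}:
        return "typeI"
    if "loop12" in pair and pair - {"loop12"} <= _SHEET_REGIONS:
        return "typeII"
    if ("beta4" in pair or "beta3" in pair or "loop34" in pair) and (
        pair & {"beta1", "beta2", "beta5"}
    ):
        return "site1"
    if "loop12" in pair:
        return "site2"
    return "unassigned"


def interface_fingerprint(
    part_a,
    part_b,
    strand_defs_a: dict[str, tuple[int, int]] | None = None,
    strand_defs_b: dict[str, tuple[int, int]] | None = None,
    waters=None,
    radii: RadiiTable | None = None,
    n_points: int = 960,
    water_depth: int = 1,
) -> InterfaceReport:
    """Run every contact detector plus BSA on a pair of atom sets."""
    a = [x for x in atoms_of(part_a) if x.res_name != "HOH"]
    b = [x for x in atoms_of(part_b) if x.res_name != "HOH"]
    contacts: list[ContactRecord] = []
    contacts += find_hbonds(a, b)
    contacts += find_salt_bridges(a, b)
    contacts += find_hydrophobic(a, b)
    if waters:
        contacts += find_water_mediated(a, b, waters, depth=water_depth)
    if strand_defs_a and strand_defs_b:
        for rec in contacts:
            rec.site = assign_site(rec, strand_defs_a, strand_defs_b)
    if a and b:
        bsa_total, per_side = buried_surface_area(a, b, radii, n_points)
    else:
        bsa_total, per_side = 0.0, (0.0, 0.0)
    return InterfaceReport(bsa_total=bsa_total, bsa_per_side=per_side, contacts=contacts)
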