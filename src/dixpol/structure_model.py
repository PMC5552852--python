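"""Crystal structures with full crystallographic context.

The asymmetric unit of a crystal is represented as a :class:`CrystalStructure`:
polymer chains (residues of atoms), a separate water list, the unit cell and
the space-group operators.  All downstream analysis -- symmetry expansion,
screw-parameter estimation, interface typing -- works on coordinate selections
and rigid transforms produced here.

Conventions
-----------
* Residue numbers are the author-assigned numbers of the deposited entry and
  are used everywhere in the public API; sequential indices are internal.
* Coordinates are orthogonal Angstroms in the frame of the deposited entry.
* Residue ranges are 1-based and inclusive.
* Models carry no hydrogens; all geometry downstream is heavy-atom based.
* Alternate locations are resolved to the highest-occupancy conformer
  (ties broken by altloc label order), so every residue holds a single
  conformer.

File I/O and space-group tables are delegated to gemmi; this module owns the
in-memory model and the transform algebra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "UnitCell",
    "SymOp",
    "CrystalStructure",
    "CoordinateSet",
    "read_structure",
    "write_structure",
    "select_coords",
    "apply_op",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: space groups the pipeline is routinely run on; anything gemmi resolves is
#: accepted, but error messages point users at this list.
SUPPORTED_SPACE_GROUPS = ("P 1", "P 21 21 21", "P 61")


@dataclass
class Atom:
    """A single heavy atom in orthogonal coordinates (Angstrom)."""

    name: str
    element: str
    pos: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_water: bool = False

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise ValueError("atom position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        if not self.element:
            raise ValueError("element must be non-empty")


@dataclass
class Residue:
    """One residue identified by its author-assigned number."""

    seq_id: int
    name: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_backbone_complete(self) -> bool:
        names = {a.name for a in self.atoms}
        return all(n in names for n in BACKBONE_ATOMS)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.seq_id for r in self.residues]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate residue numbers in chain {self.chain_id}")
        if ids != sorted(ids):
            self.residues = sorted(self.residues, key=lambda r: r.seq_id)

    def residue(self, seq_id: int) -> Residue | None:
        for r in self.residues:
            if r.seq_id == seq_id:
                return r
        return None

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def coords(self) -> np.ndarray:
        """All atom positions as an (n, 3) array, residue/atom order."""
        return np.array(
            [a.pos for r in self.residues for a in r.atoms], dtype=float
        ).reshape(-1, 3)


@dataclass
class UnitCell:
    """Cell edges (Angstrom) and angles (degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell edges must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180)")
        g = gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)
        self._orth = np.array(g.orth.mat.tolist(), dtype=float)
        self._frac = np.array(g.frac.mat.tolist(), dtype=float)
        if not np.all(np.isfinite(self._frac)):
            raise ValueError("orthogonalization matrix not invertible")

    @property
    def orth_matrix(self) -> np.ndarray:
        """Fractional -> orthogonal matrix."""
        return self._orth

    @property
    def frac_matrix(self) -> np.ndarray:
        """Orthogonal -> fractional matrix."""
        return self._frac

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self._orth.T

    def fractionalize(self, orth: np.ndarray) -> np.ndarray:
        return np.asarray(orth, dtype=float) @ self._frac.T


@dataclass
class SymOp:
    """A space-group operator in fractional space: x' = rot @ x + trans."""

    rot: np.ndarray
    trans: np.ndarray

    def __post_init__(self) -> None:
        self.rot = np.asarray(self.rot, dtype=float).reshape(3, 3)
        self.trans = np.asarray(self.trans, dtype=float).reshape(3)
        if abs(np.linalg.det(self.rot) - 1.0) > 1e-9:
            raise ValueError("symmetry operator must be a proper rotation")

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.rot, np.eye(3)) and np.allclose(self.trans, 0.0)

    def compose(self, other: "SymOp") -> "SymOp":
        """self after other (fractional space)."""
        return SymOp(self.rot @ other.rot, self.rot @ other.trans + self.trans)


@dataclass
class PlacedCopy:
    """A symmetry-generated instance of a chain.

    Carries the generator (operator index and integer lattice shift) so every
    placed subunit in a reconstructed filament is traceable to the asymmetric
    unit.
    """

    source_chain: str
    op_index: int
    lattice_shift: tuple[int, int, int]
    chain: Chain

    @property
    def key(self) -> tuple[str, int, tuple[int, int, int]]:
        return (self.source_chain, self.op_index, self.lattice_shift)

    def coords(self) -> np.ndarray:
        return self.chain.coords()

    def ca_coords(self) -> dict[int, np.ndarray]:
        """Author residue number -> CA position."""
        out: dict[int, np.ndarray] = {}
        for r in self.chain.residues:
            ca = r.atom("CA")
            if ca is not None:
                out[r.seq_id] = ca.pos
        return out


@dataclass
class CrystalStructure:
    chains: list[Chain]
    waters: list[Atom]
    cell: UnitCell
    symops: list[SymOp]
    space_group: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.symops:
            raise ValueError("structure must carry at least one symmetry operator")
        if not self.symops[0].is_identity:
            # keep identity first for stable generator indices
            idx = next(
                (i for i, op in enumerate(self.symops) if op.is_identity), None
            )
            if idx is None:
                raise ValueError("symmetry operators must include the identity")
            self.symops.insert(0, self.symops.pop(idx))

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(f"no chain {chain_id!r}; have {[c.chain_id for c in self.chains]}")

    @property
    def n_atoms(self) -> int:
        return sum(ch.n_atoms for ch in self.chains) + len(self.waters)


# CoordinateSet: ordered atom selection ready for superposition.
@dataclass
class CoordinateSet:
    """Ordered list of (residue seq_id, atom name, position)."""

    entries: list[tuple[int, str, np.ndarray]]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def coords(self) -> np.ndarray:
        return np.array([e[2] for e in self.entries], dtype=float).reshape(-1, 3)

    @property
    def residue_ids(self) -> list[int]:
        return [e[0] for e in self.entries]


# ---------------------------------------------------------------------------
# reading / writing


def _resolve_altlocs(gres: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc."""
    by_name: dict[str, gemmi.Atom] = {}
    for at in gres:
        prev = by_name.get(at.name)
        # higher occupancy wins; on an exact tie the earlier altloc label
        # (e.g. 'A' before 'B') is kept
        if (
            prev is None
            or at.occ > prev.occ
            or (at.occ == prev.occ and at.altloc < prev.altloc)
        ):
            by_name[at.name] = at
    return list(by_name.values())


def read_structure(path: str, format: str | None = None) -> CrystalStructure:
    """Read a crystal structure (mmCIF or PDB) into a :class:`CrystalStructure`.

    Waters are separated from polymer chains; alternate locations are resolved
    to a single conformer.  Raises ``ValueError`` when the file lacks unit-cell
    or space-group records, or names a space group gemmi cannot resolve.
    """
    if format is None:
        fmt = gemmi.CoorFormat.Detect
    else:
        fmt = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}[
            format.lower()
        ]
    st = gemmi.read_structure(str(path), format=fmt)
    st.merge_chain_parts()

    if st.cell.a <= 0 or st.cell.volume <= 0:
        raise ValueError(f"{path}: missing or invalid unit-cell (CRYST1/_cell) record")
    hm = st.spacegroup_hm
    if not hm:
        raise ValueError(f"{path}: missing space-group record")
    sg = gemmi.find_spacegroup_by_name(hm)
    if sg is None:
        raise ValueError(
            f"{path}: unknown space group {hm!r}; routinely supported groups: "
            + ", ".join(SUPPORTED_SPACE_GROUPS)
        )

    cell = UnitCell(
        st.cell.a, st.cell.b, st.cell.c, st.cell.alpha, st.cell.beta, st.cell.gamma
    )
    den = float(gemmi.Op.DEN)
    symops = [
        SymOp(np.array(op.rot, dtype=float) / den, np.array(op.tran, dtype=float) / den)
        for op in sg.operations()
    ]

    chains: list[Chain] = []
    waters: list[Atom] = []
    model = st[0]
    for gch in model:
        residues: list[Residue] = []
        for gres in gch:
            is_water = gres.is_water()
            atoms = []
            for at in _resolve_altlocs(gres):
                atoms.append(
                    Atom(
                        name=at.name,
                        element=at.element.name or "X",
                        pos=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=min(max(at.occ, 0.0), 1.0),
                        b_factor=at.b_iso,
                        is_water=is_water,
                    )
                )
            if is_water:
                waters.extend(atoms)
            elif atoms:
                residues.append(Residue(seq_id=gres.seqid.num, name=gres.name, atoms=atoms))
        if residues:
            chains.append(Chain(chain_id=gch.name, residues=residues))

    return CrystalStructure(
        chains=chains,
        waters=waters,
        cell=cell,
        symops=symops,
        space_group=sg.hm,
        name=str(path),
    )


def write_structure(structure: CrystalStructure, path: str, format: str = "pdb") -> None:
    """Write a structure as PDB or mmCIF (used for synthetic fixtures)."""
    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(
        structure.cell.a,
        structure.cell.b,
        structure.cell.c,
        structure.cell.alpha,
        structure.cell.beta,
        structure.cell.gamma,
    )
    st.spacegroup_hm = structure.space_group
    model = gemmi.Model("1")
    for ch in structure.chains:
        gch = gemmi.Chain(ch.chain_id)
        for r in ch.residues:
            gres = gemmi.Residue()
            gres.name = r.name
            gres.seqid = gemmi.SeqId(r.seq_id, " ")
            for a in r.atoms:
                gat = gemmi.Atom()
                gat.name = a.name
                gat.element = gemmi.Element(a.element)
                gat.pos = gemmi.Position(*a.pos)
                gat.occ = a.occupancy
                gat.b_iso = a.b_factor
                gres.add_atom(gat)
            gch.add_residue(gres)
        model.add_chain(gch)
    if structure.waters:
        wch = gemmi.Chain("W")
        for i, w in enumerate(structure.waters, start=1):
            gres = gemmi.Residue()
            gres.name = "HOH"
            gres.seqid = gemmi.SeqId(i, " ")
            gres.het_flag = "H"
            gat = gemmi.Atom()
            gat.name = w.name
            gat.element = gemmi.Element(w.element)
            gat.pos = gemmi.Position(*w.pos)
            gat.occ = w.occupancy
            gat.b_iso = w.b_factor
            gres.add_atom(gat)
            wch.add_residue(gres)
        model.add_chain(wch)
    st.add_model(model)
    st.setup_entities()
    if format.lower() == "pdb":
        st.write_pdb(str(path))
    elif format.lower() == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format {format!r} (use 'pdb' or 'mmcif')")


# ---------------------------------------------------------------------------
# selections and transforms


def select_coords(
    structure: CrystalStructure,
    chain_id: str,
    residue_range: tuple[int, int] | None = None,
    atom_filter: str = "CA-only",
) -> CoordinateSet:
    """Ordered coordinate selection from one chain.

    ``atom_filter`` is one of ``CA-only``, ``backbone``, ``all``.  Residues in
    the requested range that are missing from the model are skipped; their
    numbers are available on the returned set as ``missing_residues``.
    """
    chain = structure.chain(chain_id)
    if residue_range is None:
        lo, hi = chain.residues[0].seq_id, chain.residues[-1].seq_id
    else:
        lo, hi = residue_range
    wanted = {"CA-only": ("CA",), "backbone": BACKBONE_ATOMS, "all": None}
    if atom_filter not in wanted:
        raise ValueError(f"unknown atom filter {atom_filter!r}")
    names = wanted[atom_filter]

    entries: list[tuple[int, str, np.ndarray]] = []
    present = {r.seq_id for r in chain.residues}
    for r in chain.residues:
        if not lo <= r.seq_id <= hi:
            continue
        atoms = r.atoms if names is None else [a for n in names if (a := r.atom(n))]
        for a in atoms:
            entries.append((r.seq_id, a.name, a.pos))
    if not entries:
        raise ValueError(
            f"empty selection: chain {chain_id}, residues {lo}-{hi}, {atom_filter}"
        )
    cs = CoordinateSet(entries)
    cs.missing_residues = sorted(set(range(lo, hi + 1)) - present)  # type: ignore[attr-defined]
    return cs


def op_orth_transform(
    structure: CrystalStructure, op_index: int, lattice_shift=(0, 0, 0)
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal-space (rot, trans) for a symmetry operator + lattice shift."""
    if not 0 <= op_index < len(structure.symops):
        raise IndexError(f"operator index {op_index} out of range")
    op = structure.symops[op_index]
    O = structure.cell.orth_matrix
    F = structure.cell.frac_matrix
    rot = O @ op.rot @ F
    trans = O @ (op.trans + np.asarray(lattice_shift, dtype=float))
    return rot, trans


def apply_op(
    structure: CrystalStructure,
    chain_id: str,
    op_index: int,
    lattice_shift: tuple[int, int, int] = (0, 0, 0),
) -> PlacedCopy:
    """Place a symmetry copy of a chain.

    Coordinates are carried orthogonal -> fractional -> (rot, trans + shift)
    -> orthogonal; the copy records its generator so expansions stay
    deduplicable.
    """
    rot, trans = op_orth_transform(structure, op_index, lattice_shift)
    src = structure.chain(chain_id)
    new_residues = []
    for r in src.residues:
        new_atoms = [
            Atom(
                name=a.name,
                element=a.element,
                pos=rot @ a.pos + trans,
                occupancy=a.occupancy,
                b_factor=a.b_factor,
                is_water=a.is_water,
            )
            for a in r.atoms
        ]
        new_residues.append(Residue(seq_id=r.seq_id, name=r.name, atoms=new_atoms))
    return PlacedCopy(
        source_chain=chain_id,
        op_index=op_index,
        lattice_shift=tuple(int(s) for s in lattice_shift),
        chain=Chain(chain_id=src.chain_id, residues=new_residues),
    )


def symops_closed(structure: CrystalStructure, tol: float = 1e-9) -> bool:
    """True when the operator set is closed under composition mod lattice."""
    ops = structure.symops
    for a in ops:
        for b in ops:
            c = a.compose(b)
            ok = False
            for d in ops:
                if np.allclose(c.rot, d.rot, atol=tol):
                    diff = c.trans - d.trans
                    if np.allclose(diff, np.round(diff), atol=1e-6):
                        ok = True
                        break
            if not ok:
                return False
    return True
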