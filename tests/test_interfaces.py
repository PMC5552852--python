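import math

import numpy as np
import pytest

import dixpol.interfaces as itf
from dixpol.interfaces import AtomRef
from oracles import brute_force_pairs, sphere_area, two_sphere_sasa


def _atom(copy, rid, rname, aname, elem, pos):
    return AtomRef(copy, rid, rname, aname, elem, tuple(float(x) for x in pos))


def _cloud(rng, n, copy="A", elem="C", spread=6.0, offset=(0, 0, 0)):
    pts = rng.normal(size=(n, 3)) * spread + np.asarray(offset, float)
    return [
        _atom(copy, i + 1, "UNK", f"X{i}", elem, p) for i, p in enumerate(pts)
    ]


class TestSasa:
    def test_single_atom_matches_analytic_sphere(self):
        a = [_atom("A", 1, "UNK", "C1", "C", (0, 0, 0))]
        area = itf.sasa(a, n_points=960).sum()
        assert area == pytest.approx(sphere_area(1.70, 1.4), rel=0.01)

    def test_fully_overlapping_atoms_add_nothing(self):
        a = [
            _atom("A", 1, "UNK", "C1", "C", (0, 0, 0)),
            _atom("A", 2, "UNK", "C2", "C", (0, 0, 0)),
        ]
        # coincident spheres: every surface point of one is buried by the other
        total = itf.sasa(a, n_points=960, canonicalize=False).sum()
        assert total <= sphere_area(1.70, 1.4) * 1.01

    @pytest.mark.parametrize("d", [1.0, 2.5, 4.0, 5.5])
    def test_two_sphere_overlap_matches_spherical_caps(self, d):
        a = [
            _atom("A", 1, "UNK", "C1", "C", (0, 0, 0)),
            _atom("A", 2, "UNK", "O1", "O", (d, 0, 0)),
        ]
        got = itf.sasa(a, n_points=960, canonicalize=False)
        want = two_sphere_sasa(1.70, 1.52, d, 1.4)
        assert got[0] == pytest.approx(want[0], rel=0.02)
        assert got[1] == pytest.approx(want[1], rel=0.02)

    def test_rotation_translation_invariance(self, rng):
        """The canonical-frame construction makes sampled SASA follow the
        molecule exactly under rigid motion."""
        from scipy.spatial.transform import Rotation

        atoms = _cloud(rng, 40)
        base = itf.sasa(atoms).sum()
        R = Rotation.from_rotvec([0.3, -1.1, 2.0]).as_matrix()
        moved = [
            _atom(a.copy_id, a.res_id, a.res_name, a.atom_name, a.element,
                  R @ np.array(a.pos) + np.array([25.0, -13.0, 8.0]))
            for a in atoms
        ]
        assert itf.sasa(moved).sum() == pytest.approx(base, rel=1e-9)

    def test_point_density_convergence(self, rng):
        """Doubling the point lattice changes the total area of a compact
        domain by well under 0.5%."""
        atoms = _cloud(rng, 120, spread=5.0)
        a960 = itf.sasa(atoms, n_points=960).sum()
        a1920 = itf.sasa(atoms, n_points=1920).sum()
        assert abs(a1920 - a960) / a1920 < 0.005

    def test_unknown_element_warns_and_uses_fallback(self):
        with pytest.warns(UserWarning, match="fallback"):
            area = itf.sasa(
                [_atom("A", 1, "UNK", "SE1", "SE", (0, 0, 0))], n_points=960
            ).sum()
        assert area == pytest.approx(sphere_area(1.70, 1.4), rel=0.01)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="n_points"):
            itf.sasa([_atom("A", 1, "UNK", "C1", "C", (0, 0, 0))], n_points=50)


class TestBuriedSurfaceArea:
    def test_distant_parts_bury_nothing(self, rng):
        a = _cloud(rng, 15, copy="A")
        b = _cloud(rng, 15, copy="B", offset=(100.0, 0, 0))
        total, (ba, bb) = itf.buried_surface_area(a, b)
        assert total == pytest.approx(0.0, abs=1e-9)
        assert ba == pytest.approx(0.0, abs=1e-9)
        assert bb == pytest.approx(0.0, abs=1e-9)

    def test_contacting_parts_bury_positive_symmetric_area(self, rng):
        a = _cloud(rng, 20, copy="A", spread=4.0)
        b = _cloud(rng, 20, copy="B", spread=4.0, offset=(7.0, 0, 0))
        total, (ba, bb) = itf.buried_surface_area(a, b)
        assert total == pytest.approx(ba + bb, abs=1e-9)
        assert ba > 0 and bb > 0

    def test_shared_atom_rejected(self, rng):
        a = _cloud(rng, 5, copy="A")
        with pytest.raises(ValueError, match="shared"):
            itf.buried_surface_area(a, a)


class TestContactDetectors:
    def test_hbond_toy_pair(self):
        a = [_atom("A", 1, "GLY", "N", "N", (0, 0, 0))]
        b = [_atom("B", 2, "GLY", "O", "O", (3.2, 0, 0))]
        recs = itf.find_hbonds(a, b)
        assert len(recs) == 1
        assert recs[0].kind == "mainchain_hbond"
        assert recs[0].distance == pytest.approx(3.2)
        # beyond the cutoff: nothing
        far = [_atom("B", 2, "GLY", "O", "O", (3.8, 0, 0))]
        assert itf.find_hbonds(a, far) == []

    def test_sidechain_hbond_roles(self):
        lys = [_atom("A", 446, "LYS", "NZ", "N", (0, 0, 0))]
        ser = [_atom("B", 401, "SER", "OG", "O", (2.9, 0, 0))]
        recs = itf.find_hbonds(lys, ser)
        assert len(recs) == 1 and recs[0].kind == "hbond"
        # two backbone carbonyls cannot bond each other
        o1 = [_atom("A", 1, "GLY", "O", "O", (0, 0, 0))]
        o2 = [_atom("B", 2, "GLY", "O", "O", (3.0, 0, 0))]
        assert itf.find_hbonds(o1, o2) == []

    def test_salt_bridge_toy_pair(self):
        asp = [_atom("A", 439, "ASP", "OD1", "O", (0, 0, 0))]
        lys = [_atom("B", 393, "LYS", "NZ", "N", (3.0, 0, 0))]
        recs = itf.find_salt_bridges(asp, lys)
        assert len(recs) == 1
        assert recs[0].kind == "salt_bridge"
        # a backbone O near the same NZ is not a salt bridge
        bbo = [_atom("A", 440, "GLY", "O", "O", (0, 0, 0))]
        assert itf.find_salt_bridges(bbo, lys) == []

    def test_hydrophobic_aggregates_per_residue_pair(self):
        leu = [
            _atom("A", 395, "LEU", "CD1", "C", (0, 0, 0)),
            _atom("A", 395, "LEU", "CD2", "C", (1.0, 0, 0)),
        ]
        val = [_atom("B", 445, "VAL", "CG1", "C", (4.0, 0, 0))]
        recs = itf.find_hydrophobic(leu, val)
        assert len(recs) == 1  # one record per residue pair
        assert recs[0].distance == pytest.approx(3.0)
        # main-chain carbons are excluded
        bb = [_atom("A", 395, "LEU", "CA", "C", (0, 0, 0))]
        assert itf.find_hydrophobic(bb, val) == []

    def test_water_mediated_single_and_double_bridge(self):
        a = [_atom("A", 1, "GLY", "O", "O", (0, 0, 0))]
        b = [_atom("B", 2, "GLY", "O", "O", (6.0, 0, 0))]
        w1 = _atom("W", 1, "HOH", "O", "O", (3.0, 0, 0))
        recs = itf.find_water_mediated(a, b, [w1])
        assert len(recs) == 1 and recs[0].kind == "water_mediated"
        # a two-water chain is only found at depth 2
        far_b = [_atom("B", 2, "GLY", "O", "O", (9.0, 0, 0))]
        w2 = _atom("W", 2, "HOH", "O", "O", (6.0, 0, 0))
        assert itf.find_water_mediated(a, far_b, [w1, w2], depth=1) == []
        deep = itf.find_water_mediated(a, far_b, [w1, w2], depth=2)
        assert len(deep) == 1 and len(deep[0].waters) == 2

    @pytest.mark.parametrize(
        "finder,d_max",
        [
            (itf.find_hbonds, 3.5),
            (itf.find_salt_bridges, 4.0),
            (itf.find_hydrophobic, 4.5),
        ],
    )
    def test_detectors_match_exhaustive_scan(self, rng, finder, d_max):
        """KD-tree detectors find exactly the pairs a double loop finds on
        <=20-atom toys."""
        names = [("ASP", "OD1", "O"), ("LYS", "NZ", "N"), ("GLY", "N", "N"),
                 ("GLY", "O", "O"), ("LEU", "CD1", "C"), ("SER", "OG", "O")]
        for trial in range(5):
            a, b = [], []
            for i in range(10):
                rn, an, el = names[int(rng.integers(len(names)))]
                a.append(_atom("A", i + 1, rn, an, el, rng.uniform(0, 10, 3)))
                rn, an, el = names[int(rng.integers(len(names)))]
                b.append(_atom("B", i + 1, rn, an, el, rng.uniform(0, 10, 3)))
            got = {
                (r.atom_a.res_id, r.atom_a.atom_name, r.atom_b.res_id, r.atom_b.atom_name)
                for r in finder(a, b)
            }
            # every reported pair is within cutoff and present in the scan
            scan = {
                (a[i].res_id, a[i].atom_name, b[j].res_id, b[j].atom_name)
                for i, j, _d in brute_force_pairs(a, b, d_max)
            }
            assert got <= scan
            # and no qualifying pair is missed: rerun the finder role logic
            # against the exhaustive pair list
            missed = scan - {
                (r.atom_a.res_id, r.atom_a.atom_name, r.atom_b.res_id, r.atom_b.atom_name)
                for r in finder(a, b, d_max)
            }
            for ra, na, rb, nb in missed:
                xa = next(x for x in a if x.res_id == ra and x.atom_name == na)
                xb = next(x for x in b if x.res_id == rb and x.atom_name == nb)
                single = finder([xa], [xb], d_max)
                assert single == [], "pair found in isolation but missed in bulk"


class TestFingerprint:
    def test_distant_pair_empty_report(self, rng):
        a = _cloud(rng, 10, copy="A")
        b = _cloud(rng, 10, copy="B", offset=(120.0, 0, 0))
        rep = itf.interface_fingerprint(a, b)
        assert rep.bsa_total == pytest.approx(0.0, abs=1e-9)
        assert rep.contacts == []

    def test_planted_inventory_recovered(self):
        """A hand-built pair with one salt bridge, one H-bond and one
        hydrophobic contact yields exactly that inventory."""
        regions = {"beta4": (4, 6), "loop12": (7, 9)}
        a = [
            _atom("A", 5, "LYS", "NZ", "N", (0, 0, 0)),
            _atom("A", 5, "LYS", "N", "N", (0, 3.0, 0)),
            _atom("A", 6, "LEU", "CD1", "C", (0, -4.0, 0)),
        ]
        b = [
            _atom("B", 8, "ASP", "OD1", "O", (3.0, 0, 0)),
            _atom("B", 8, "ASP", "O", "O", (0, 6.2, 0)),
            _atom("B", 7, "LEU", "CD1", "C", (0, -4.0, 4.0)),
        ]
        rep = itf.interface_fingerprint(a, b, regions, regions)
        kinds = sorted(c.kind for c in rep.contacts)
        # NZ...OD1 registers both as an H-bond (N/O donor-acceptor) and as a
        # salt bridge; N...O backbone pair at 3.2 A; CD1...CD1 at 4.0 A
        assert kinds == ["hbond", "hydrophobic", "mainchain_hbond", "salt_bridge"]
        sb = rep.by_kind("salt_bridge")[0]
        assert sb.site == "typeII"  # beta4 vs loop12
        assert rep.bsa_total > 0
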