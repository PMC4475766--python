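"""Interaction detectors: geometric windows, strict/crude semantics,
oracle equivalence, invariances."""

import numpy as np
import pytest

from oddkit.interactions import (GeometricCriteria, detect_all,
                                 detect_halogen_bonds, detect_hbonds,
                                 detect_hydrophobic, detect_metal_interactions,
                                 detect_pi_cation, detect_pi_stacking,
                                 detect_salt_bridges, interaction_profile,
                                 KINDS, PROFILE_NAMES)
from oddkit.perception import perceive_features
from oddkit.synthetic import (make_hbond_complex, make_planted_complex,
                              random_interaction_spec, random_rotation)

from .conftest import featurize_pair
from .oracles import oracle_all, records_as_set

CRIT = GeometricCriteria()


def _planted(seed, n=None):
    rng = np.random.default_rng(seed)
    spec = random_interaction_spec(rng, n or int(rng.integers(1, 6)))
    return make_planted_complex(spec, seed=seed)


class TestHbond:
    def test_collinear_pair_is_strict(self):
        p, l, _ = make_hbond_complex(2.9, 180.0)
        recs = detect_hbonds(*featurize_pair(p, l))
        assert len(recs) == 1 and recs[0].strict
        assert recs[0].distance == pytest.approx(2.9)

    def test_bent_pair_is_crude_only(self):
        p, l, _ = make_hbond_complex(2.9, 90.0)
        recs = detect_hbonds(*featurize_pair(p, l))
        assert len(recs) == 1 and not recs[0].strict

    def test_beyond_cutoff_gives_nothing(self):
        p, l, _ = make_hbond_complex(5.0, 180.0)
        assert detect_hbonds(*featurize_pair(p, l)) == []

    def test_implicit_h_donor_uses_heavy_atom_fallback(self):
        """A donor with implicit (geometry-free) hydrogens is judged by the
        X-D...A angles of its heavy neighbors."""
        from oddkit.molio import Atom, AtomSite, Bond, Molecule, ProteinStructure
        prot = ProteinStructure(atoms=[Atom("O", np.zeros(3))],
                                sites=[AtomSite(atom_name="O1", residue_name="UNK")])
        # donor O with implicit H, heavy neighbor C pointing away from A
        lig = Molecule(atoms=[Atom("O", np.array([3.0, 0, 0]), implicit_h=1),
                              Atom("C", np.array([4.4, 0, 0]))],
                       bonds=[Bond(0, 1)])
        recs = detect_hbonds(*featurize_pair(prot, lig))
        assert len(recs) == 1 and recs[0].strict  # X-D...A = 180 >= 90
        # heavy neighbor between donor and acceptor: angle 0 < 90 -> crude
        lig2 = Molecule(atoms=[Atom("O", np.array([3.0, 0, 0]), implicit_h=1),
                               Atom("C", np.array([1.6, 0, 0]))],
                        bonds=[Bond(0, 1)])
        recs2 = detect_hbonds(*featurize_pair(prot, lig2))
        assert len(recs2) == 1 and not recs2[0].strict


class TestDistanceOnlyDetectors:
    @pytest.mark.parametrize("dist,expected", [(3.5, 1), (4.5, 0)])
    def test_salt_bridge_window(self, dist, expected):
        from oddkit.synthetic import _frag_salt_bridge
        from oddkit.molio import Molecule, ProteinStructure
        pa, ps, _, la, lb = _frag_salt_bridge(dist)
        prot = ProteinStructure(atoms=pa, sites=ps)
        lig = Molecule(atoms=la, bonds=lb)
        recs = detect_salt_bridges(*featurize_pair(prot, lig))
        assert len(recs) == expected
        assert all(r.strict for r in recs)  # no angle term

    @pytest.mark.parametrize("dist,expected", [(3.8, 1), (4.2, 0)])
    def test_hydrophobic_window(self, dist, expected):
        from oddkit.synthetic import _frag_hydrophobic
        from oddkit.molio import Molecule, ProteinStructure
        pa, ps, _, la, lb = _frag_hydrophobic(dist)
        prot = ProteinStructure(atoms=pa, sites=ps)
        lig = Molecule(atoms=la, bonds=lb)
        assert len(detect_hydrophobic(*featurize_pair(prot, lig))) == expected

    @pytest.mark.parametrize("dist,expected", [(2.1, 1), (3.4, 0)])
    def test_metal_coordination_window(self, dist, expected):
        from oddkit.synthetic import _frag_metal_coordination
        from oddkit.molio import Molecule, ProteinStructure
        pa, ps, _, la, lb = _frag_metal_coordination(dist)
        prot = ProteinStructure(atoms=pa, sites=ps, metals=[0])
        lig = Molecule(atoms=la, bonds=lb)
        recs = detect_metal_interactions(*featurize_pair(prot, lig))
        assert len(recs) == expected


class TestHalogen:
    def test_collinear_sigma_hole_strict(self):
        p, l, _ = make_planted_complex([("halogen_bond", (3.3, 180.0))], seed=0,
                                       n_decoys=0)
        recs = detect_halogen_bonds(*featurize_pair(p, l))
        assert len(recs) == 1 and recs[0].strict

    def test_bent_geometry_crude(self):
        p, l, _ = make_planted_complex([("halogen_bond", (3.5, 120.0))], seed=0,
                                       n_decoys=0)
        recs = detect_halogen_bonds(*featurize_pair(p, l))
        assert len(recs) == 1 and not recs[0].strict
        assert recs[0].angles["CXA"] == pytest.approx(120.0, abs=1e-6)


class TestPiStacking:
    def test_parallel_rings_face_to_face_strict(self):
        p, l, _ = make_planted_complex([("pi_stack_f2f", (4.5, 0.0))], seed=0,
                                       n_decoys=0)
        recs = detect_pi_stacking(*featurize_pair(p, l))
        assert [r.kind for r in recs] == ["pi_stack_f2f"]
        assert recs[0].strict

    def test_perpendicular_rings_edge_to_face_strict(self):
        p, l, _ = make_planted_complex([("pi_stack_e2f", (5.2, 90.0))], seed=0,
                                       n_decoys=0)
        recs = detect_pi_stacking(*featurize_pair(p, l))
        assert [r.kind for r in recs] == ["pi_stack_e2f"]
        assert recs[0].strict

    def test_intermediate_tilt_is_crude(self):
        p, l, _ = make_planted_complex([("pi_stack_f2f", (5.4, 40.0))], seed=0,
                                       n_decoys=0)
        recs = detect_pi_stacking(*featurize_pair(p, l))
        assert len(recs) == 1 and not recs[0].strict


class TestPiCationAndMetal:
    def test_axial_cation_strict(self):
        p, l, _ = make_planted_complex([("pi_cation", (4.0, 0.0))], seed=0,
                                       n_decoys=0)
        recs = detect_pi_cation(*featurize_pair(p, l))
        assert len(recs) == 1 and recs[0].strict

    def test_in_plane_cation_crude(self):
        p, l, _ = make_planted_complex([("pi_cation", (4.5, 90.0))], seed=0,
                                       n_decoys=0)
        recs = detect_pi_cation(*featurize_pair(p, l))
        assert len(recs) == 1 and not recs[0].strict

    def test_axial_metal_over_ring_strict(self):
        p, l, _ = make_planted_complex([("pi_metal", (3.5, 0.0))], seed=0,
                                       n_decoys=0)
        recs = detect_metal_interactions(*featurize_pair(p, l))
        assert [r.kind for r in recs] == ["pi_metal"]
        assert recs[0].strict


class TestOracleEquivalence:
    def test_record_sets_match_brute_force(self):
        """Every detector equals the independent all-pairs reference on
        random planted complexes (exact record-set equality)."""
        for seed in range(40):
            p, l, _ = _planted(seed)
            pf, lf = featurize_pair(p, l)
            got = records_as_set(detect_all(pf, lf, CRIT))
            want = oracle_all(pf, lf, CRIT)
            assert got == want, f"seed {seed}"

    def test_manifest_agreement(self):
        for seed in range(25):
            p, l, manifest = _planted(seed)
            pf, lf = featurize_pair(p, l)
            profile = interaction_profile(detect_all(pf, lf, CRIT))
            counts = profile.as_dict()
            for kind, (crude, strict) in manifest.expected_counts().items():
                assert counts[f"{kind}_crude"] == crude
                assert counts[f"{kind}_strict"] == strict


class TestProperties:
    def test_rigid_motion_invariance(self, rng):
        p, l, _ = _planted(3)
        pf, lf = featurize_pair(p, l)
        base = detect_all(pf, lf, CRIT)
        for _ in range(5):
            rot = random_rotation(rng)
            t = rng.uniform(-30, 30, 3)
            pf2, lf2 = featurize_pair(p.transformed(rot, t), l.transformed(rot, t))
            moved = detect_all(pf2, lf2, CRIT)
            assert records_as_set(moved) == records_as_set(base)
            for a, b in zip(base, moved):
                assert abs(a.distance - b.distance) < 1e-9

    def test_strict_implies_crude_by_construction(self):
        """A strict record also satisfies the crude (distance) criterion."""
        for seed in range(10):
            p, l, _ = _planted(seed)
            pf, lf = featurize_pair(p, l)
            for r in detect_all(pf, lf, CRIT):
                cutoff = {
                    "hbond": CRIT.hbond_dist, "salt_bridge": CRIT.salt_bridge_dist,
                    "hydrophobic": CRIT.hydrophobic_dist,
                    "halogen_bond": CRIT.halogen_dist,
                    "pi_stack_f2f": CRIT.pi_stack_dist,
                    "pi_stack_e2f": CRIT.pi_stack_dist,
                    "pi_cation": CRIT.pi_cation_dist,
                    "pi_metal": CRIT.pi_metal_dist,
                    "metal_coordination": CRIT.metal_coord_dist,
                }[r.kind]
                assert 0 < r.distance <= cutoff

    def test_enlarging_cutoffs_never_removes_records(self):
        for seed in range(10):
            p, l, _ = _planted(seed)
            pf, lf = featurize_pair(p, l)
            base = records_as_set(detect_all(pf, lf, CRIT))
            wider = CRIT.override(
                hbond_dist=CRIT.hbond_dist + 1, salt_bridge_dist=5.0,
                hydrophobic_dist=5.0, halogen_dist=5.0, pi_stack_dist=6.5,
                pi_cation_dist=6.5, metal_coord_dist=4.0, pi_metal_dist=6.0)
            grown = records_as_set(detect_all(pf, lf, wider))
            # compare ignoring the strict flag: widening a distance cutoff
            # may add records but never removes one
            assert {t[:3] for t in base} <= {t[:3] for t in grown}

    def test_detection_deterministic_and_sorted(self):
        p, l, _ = _planted(5)
        pf, lf = featurize_pair(p, l)
        a = detect_all(pf, lf, CRIT)
        b = detect_all(pf, lf, CRIT)
        assert [vars(r) for r in a] == [vars(r) for r in b]
        keys = [r.sort_key() for r in a]
        assert keys == sorted(keys)


class TestProfile:
    def test_empty_records_zero_vector(self):
        v = interaction_profile([])
        assert list(v.names) == list(PROFILE_NAMES)
        assert not v.values.any()

    def test_two_strict_hbonds(self):
        p, l, _ = make_planted_complex(
            [("hbond", (2.9, 180.0)), ("hbond", (2.5, 150.0))], seed=0)
        pf, lf = featurize_pair(p, l)
        counts = interaction_profile(detect_all(pf, lf)).as_dict()
        assert counts["hbond_crude"] == 2
        assert counts["hbond_strict"] == 2

    def test_strict_never_exceeds_crude(self):
        for seed in range(10):
            p, l, _ = _planted(seed)
            pf, lf = featurize_pair(p, l)
            counts = interaction_profile(detect_all(pf, lf)).as_dict()
            for kind in KINDS:
                assert counts[f"{kind}_strict"] <= counts[f"{kind}_crude"]


class TestCriteriaValidation:
    def test_negative_cutoff_rejected(self):
        with pytest.raises(ValueError):
            GeometricCriteria(hbond_dist=-1.0)

    def test_angle_window_bounds(self):
        with pytest.raises(ValueError):
            GeometricCriteria(pi_f2f_max=200.0)

    def test_override_returns_new_object(self):
        crit = GeometricCriteria()
        crit2 = crit.override(hbond_dist=3.2)
        assert crit.hbond_dist == 3.5 and crit2.hbond_dist == 3.2
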