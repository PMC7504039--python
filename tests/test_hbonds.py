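"""Geometric hydrogen-bond detection, His–Glu pairing and pose triage."""
import math

import numpy as np
import pytest

from complementa.hbonds import (
    BACKBONE_ACCEPTORS,
    BACKBONE_DONOR,
    HBondCriteria,
    SIDECHAIN_ACCEPTORS,
    SIDECHAIN_DONORS,
    classify_orientation,
    detect_hbonds,
    filter_models,
    his_glu_pairs,
)
from complementa.structio import Pose, SiteSelection, SiteNotFoundError
from complementa.synth import SITE_EVHH, SITE_HAEE, gen_pose_ensemble
from conftest import make_atom

SITE_A1 = SiteSelection("A", 1, 1)
SITE_B1 = SiteSelection("B", 1, 1)


def dha_angle(h, d, a):
    """Plain-trig D–H···A angle at the hydrogen."""
    v1 = np.asarray(d, float) - h
    v2 = np.asarray(a, float) - h
    return math.degrees(math.acos(
        np.dot(v1, v2) / np.linalg.norm(v1) / np.linalg.norm(v2)))


def glu_his_pair_pose(distance, hydrogen_xyz=None):
    """Glu side chain (chain A) facing a His side chain (chain B).

    The donor is His NE2 at (0, distance, 0), the acceptor Glu OE1 at the
    origin; an explicit hydrogen can be placed at ``hydrogen_xyz``.
    """
    oe1 = make_atom("OE1", (0, 0, 0), 11, "A", "GLU", element="O", serial=1)
    cd = make_atom("CD", (0, 0, -1.3), 11, "A", "GLU", element="C", serial=2)
    ne2 = make_atom("NE2", (0, distance, 0), 35, "B", "HIS", element="N", serial=3)
    ce1 = make_atom("CE1", (0, distance + 1.35, 0), 35, "B", "HIS", element="C", serial=4)
    atoms = [oe1, cd, ne2, ce1]
    if hydrogen_xyz is not None:
        atoms.append(make_atom("HE2", hydrogen_xyz, 35, "B", "HIS",
                               element="H", serial=5))
    return Pose(model_id=1, atoms=atoms)


def oracle_hbonds(pose, site_a, site_b, criteria):
    """Independent exhaustive enumeration over all donor/acceptor pairs."""
    def site_atoms(site):
        return [a for a in pose.atoms if a.chain_id == site.chain_id
                and site.first <= a.residue_seq <= site.last]

    def donors(atoms):
        out = []
        for a in atoms:
            table = dict([BACKBONE_DONOR]) | SIDECHAIN_DONORS.get(a.residue_name, {})
            if a.name in table:
                ante = next((x for x in atoms if x.residue_seq == a.residue_seq
                             and x.chain_id == a.chain_id and x.name == table[a.name]), None)
                hs = [x for x in atoms if x.element == "H"
                      and x.residue_seq == a.residue_seq and x.chain_id == a.chain_id
                      and np.linalg.norm(x.xyz - a.xyz) <= 1.25]
                out.append((a, ante, hs))
        return out

    def acceptors(atoms):
        return [a for a in atoms
                if a.name in set(BACKBONE_ACCEPTORS)
                | set(SIDECHAIN_ACCEPTORS.get(a.residue_name, ()))]

    def angle(c, p1, p2):
        v1, v2 = p1 - c, p2 - c
        return math.degrees(math.acos(
            np.clip(np.dot(v1, v2) / np.linalg.norm(v1) / np.linalg.norm(v2), -1, 1)))

    found = set()
    ga, gb = site_atoms(site_a), site_atoms(site_b)
    for dside, aside in ((ga, gb), (gb, ga)):
        for d, ante, hs in donors(dside):
            for acc in acceptors(aside):
                dist = np.linalg.norm(d.xyz - acc.xyz)
                if dist > criteria.max_da_distance or dist == 0:
                    continue
                if hs:
                    if max(angle(h.xyz, d.xyz, acc.xyz) for h in hs) < criteria.min_dha_angle:
                        continue
                elif ante is not None:
                    if angle(d.xyz, ante.xyz, acc.xyz) < criteria.min_heavy_angle:
                        continue
                found.add((d.chain_id, d.residue_seq, d.name,
                           acc.chain_id, acc.residue_seq, acc.name))
    return found


def bond_keys(bonds):
    return {(b.donor.chain_id, b.donor.residue_seq, b.donor.atom_name,
             b.acceptor.chain_id, b.acceptor.residue_seq, b.acceptor.atom_name)
            for b in bonds}


class TestDetect:
    def test_planted_glu_his_bond_with_hydrogen(self):
        h = (0.2, 2.0, 0.0)  # near the D→A segment, wide D–H···A angle
        pose = glu_his_pair_pose(2.9, hydrogen_xyz=h)
        bonds = detect_hbonds(pose, SiteSelection("A", 11, 11), SiteSelection("B", 35, 35))
        assert len(bonds) == 1
        b = bonds[0]
        assert (b.donor.atom_name, b.acceptor.atom_name) == ("NE2", "OE1")
        assert b.distance == pytest.approx(2.9)
        assert b.angle == pytest.approx(dha_angle(h, (0, 2.9, 0), (0, 0, 0)), abs=1e-6)
        assert b.angle > 150.0
        assert b.donor_is_sidechain and b.acceptor_is_sidechain

    def test_beyond_distance_cutoff_rejected(self):
        pose = glu_his_pair_pose(4.2)
        assert detect_hbonds(pose, SiteSelection("A", 11, 11),
                             SiteSelection("B", 35, 35)) == []

    def test_poor_dha_angle_rejected(self):
        h = (1.0, 2.9, 0.0)  # hydrogen perpendicular to the D→A axis: ~71°
        assert dha_angle(h, (0, 2.9, 0), (0, 0, 0)) < 120
        pose = glu_his_pair_pose(2.9, hydrogen_xyz=h)
        assert detect_hbonds(pose, SiteSelection("A", 11, 11),
                             SiteSelection("B", 35, 35)) == []

    def test_heavy_atom_proxy_without_hydrogens(self):
        pose = glu_his_pair_pose(3.2)  # antecedent CE1 opposite the acceptor: 180°
        bonds = detect_hbonds(pose, SiteSelection("A", 11, 11),
                              SiteSelection("B", 35, 35))
        assert len(bonds) == 1 and bonds[0].angle is None

    def test_symmetric_in_site_order(self):
        pose = glu_his_pair_pose(2.9)
        sa, sb = SiteSelection("A", 11, 11), SiteSelection("B", 35, 35)
        assert bond_keys(detect_hbonds(pose, sa, sb)) == bond_keys(detect_hbonds(pose, sb, sa))

    def test_monotone_in_criteria(self):
        pose = glu_his_pair_pose(3.3)
        sa, sb = SiteSelection("A", 11, 11), SiteSelection("B", 35, 35)
        tight = HBondCriteria(max_da_distance=3.0)
        loose = HBondCriteria(max_da_distance=3.5)
        assert bond_keys(detect_hbonds(pose, sa, sb, tight)) <= bond_keys(
            detect_hbonds(pose, sa, sb, loose))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle_on_random_models(self, seed):
        """Random donor/acceptor-rich residues thrown into a 8 Å box."""
        rng = np.random.default_rng(seed)
        atoms = []
        serial = 1
        resnames = ["GLU", "HIS", "SER", "ASP", "GLN", "LYS"]
        templates = {
            "GLU": [("CD", "C"), ("OE1", "O"), ("OE2", "O")],
            "HIS": [("CG", "C"), ("ND1", "N"), ("CE1", "C"), ("NE2", "N")],
            "SER": [("CB", "C"), ("OG", "O")],
            "ASP": [("CG", "C"), ("OD1", "O"), ("OD2", "O")],
            "GLN": [("CD", "C"), ("OE1", "O"), ("NE2", "N")],
            "LYS": [("CE", "C"), ("NZ", "N")],
        }
        for chain, base_res in (("A", 1), ("B", 1)):
            for i in range(3):
                resname = resnames[rng.integers(len(resnames))]
                for name, element in [("N", "N"), ("CA", "C"), ("O", "O")] + templates[resname]:
                    atoms.append(make_atom(name, rng.uniform(0, 8, 3), base_res + i,
                                           chain, resname, element, serial))
                    serial += 1
        pose = Pose(1, atoms)
        sa, sb = SiteSelection("A", 1, 3), SiteSelection("B", 1, 3)
        criteria = HBondCriteria()
        assert bond_keys(detect_hbonds(pose, sa, sb, criteria)) == oracle_hbonds(
            pose, sa, sb, criteria)

    def test_unresolvable_site_propagates(self, two_chain_pose):
        with pytest.raises(SiteNotFoundError):
            detect_hbonds(two_chain_pose, SiteSelection("A", 99, 99), SITE_B1)


class TestHisGluPairs:
    def test_combination_labels(self):
        ens, _ = gen_pose_ensemble(["pass"], seed=1)
        bonds = detect_hbonds(ens.poses[0], SITE_EVHH, SITE_HAEE)
        labels = [label for _, _, label in his_glu_pairs(bonds)]
        assert labels == ["Glu11-His35", "His13-Glu38", "His14-Glu38"]

    def test_empty_input(self):
        assert his_glu_pairs([]) == []

    def test_residue_level_dedup(self):
        pose = glu_his_pair_pose(2.9)
        # add a second atomic bond between the same residue pair
        pose.atoms.append(make_atom("OE2", (1.2, 0, 0), 11, "A", "GLU", "O", 6))
        bonds = detect_hbonds(pose, SiteSelection("A", 11, 11), SiteSelection("B", 35, 35))
        assert len(bonds) >= 2
        assert [label for _, _, label in his_glu_pairs(bonds)] == ["Glu11-His35"]

    def test_non_his_glu_bonds_ignored(self):
        ens, _ = gen_pose_ensemble(["backbone_only"], seed=1)
        bonds = detect_hbonds(ens.poses[0], SITE_EVHH, SITE_HAEE)
        # bonds exist, but only the GLU38–HIS13 backbone pair is His↔Glu at residue level
        assert len(bonds) == 3
        assert [label for _, _, label in his_glu_pairs(bonds)] == ["His13-Glu38"]


class TestOrientation:
    def _segment_pose(self, v):
        """Two 2-residue sites: A along +x, B along direction v."""
        v = np.asarray(v, float)
        atoms = [
            make_atom("CA", (0, 0, 0), 1, "A", serial=1),
            make_atom("CA", (3.8, 0, 0), 2, "A", serial=2),
            make_atom("CA", (0, 10, 0), 1, "B", serial=3),
            make_atom("CA", (0, 10, 0) + 3.8 * v, 2, "B", serial=4),
        ]
        return Pose(1, atoms)

    @pytest.mark.parametrize("v,expected", [
        ((1, 0, 0), "parallel"),
        ((-1, 0, 0), "antiparallel"),
        ((0, 0, 1), "crosswise"),
        ((0, 1, 0), "crosswise"),
    ])
    def test_basic_directions(self, v, expected):
        pose = self._segment_pose(v)
        assert classify_orientation(pose, SiteSelection("A", 1, 2),
                                    SiteSelection("B", 1, 2)) == expected

    def test_invariant_under_rigid_motion(self):
        from scipy.spatial.transform import Rotation

        pose = self._segment_pose((1, 0.2, 0.1))
        sa, sb = SiteSelection("A", 1, 2), SiteSelection("B", 1, 2)
        before = classify_orientation(pose, sa, sb)
        rot = Rotation.from_euler("xyz", [0.7, -1.2, 2.4])
        shift = np.array([5.0, -3.0, 11.0])
        moved = Pose(1, [a.moved_to(rot.apply(a.xyz) + shift) for a in pose.atoms])
        assert classify_orientation(moved, sa, sb) == before

    def test_missing_ca_raises(self, two_chain_pose):
        with pytest.raises(SiteNotFoundError):
            classify_orientation(two_chain_pose, SiteSelection("A", 1, 1),
                                 SiteSelection("B", 1, 1))


class TestFilter:
    def test_pose_kinds_verdicts(self):
        kinds = ["pass", "two_bonds", "one_bond", "backbone_only",
                 "shared_atom", "detached"]
        ens, truth = gen_pose_ensemble(kinds, seed=3)
        reports, passing = filter_models(ens, SITE_EVHH, SITE_HAEE)
        assert [r.passed for r in reports] == [True] + [False] * 5
        assert len(passing) == 1
        by_kind = {t["kind"]: r for t, r in zip(truth.data["poses"], reports)}
        assert by_kind["pass"].n_distinct_sidechain_atoms == 6
        assert by_kind["shared_atom"].n_bonds == 3
        assert by_kind["shared_atom"].n_distinct_sidechain_atoms == 1
        assert by_kind["backbone_only"].n_distinct_sidechain_atoms == 0

    def test_planted_pass_count(self):
        kinds = ["pass", "detached", "pass", "two_bonds", "pass", "pass",
                 "backbone_only", "detached", "shared_atom", "one_bond"]
        ens, truth = gen_pose_ensemble(kinds, seed=4)
        reports, passing = filter_models(ens, SITE_EVHH, SITE_HAEE)
        assert len(passing) == truth.data["n_expected_pass"] == 4
        assert [r.pose_id for r in reports if r.passed] == [1, 3, 5, 6]

    def test_one_side_counting_mode(self):
        ens, _ = gen_pose_ensemble(["pass"], seed=5)
        # the passing pose has 3 side-chain atoms on each interface side
        both, _ = filter_models(ens, SITE_EVHH, SITE_HAEE, count_side="both")
        one_a, _ = filter_models(ens, SITE_EVHH, SITE_HAEE, count_side="siteA")
        one_b, _ = filter_models(ens, SITE_EVHH, SITE_HAEE, count_side="siteB")
        assert both[0].n_distinct_sidechain_atoms == 6
        assert one_a[0].n_distinct_sidechain_atoms == 3
        assert one_b[0].n_distinct_sidechain_atoms == 3

    def test_degenerate_threshold_passes_nothing(self):
        ens, _ = gen_pose_ensemble(["pass", "pass"], seed=6)
        reports, passing = filter_models(ens, SITE_EVHH, SITE_HAEE, min_bonds=99)
        assert passing == [] and all(not r.passed for r in reports)

    def test_orientation_labels_in_reports(self):
        ens, _ = gen_pose_ensemble(["pass", "pass"], seed=7,
                                   orientations=["parallel", "antiparallel"])
        reports, _ = filter_models(ens, SITE_EVHH, SITE_HAEE)
        assert [r.orientation for r in reports] == ["parallel", "antiparallel"]
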