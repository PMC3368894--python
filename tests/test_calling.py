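"""Confidence calibration, patch clustering and residue conversion."""

import numpy as np
import pytest

from pdmsite.calling import (ConfidenceTable, actual_residue_sites,
                             build_confidence_table, call_patches,
                             residues_from_patches, to_confidence, Patch)
from pdmsite.structure import AtomSite, Structure
from conftest import random_rotation


class TestConfidenceTable:
    def test_bin_fraction(self):
        act = np.full(10, 0.55)
        lab = np.array([True] * 3 + [False] * 7)
        t = build_confidence_table(act, lab)
        assert t.confidence[5] == pytest.approx(0.3)
        assert t.counts[5] == 10

    def test_all_positive_gives_unit_confidence(self):
        rng = np.random.default_rng(0)
        act = rng.uniform(0, 1, 100)
        t = build_confidence_table(act, np.ones(100, bool))
        populated = t.counts > 0
        np.testing.assert_allclose(t.confidence[populated], 1.0)

    def test_conservation_identity(self):
        """sum over bins of confidence*count equals the number of positive
        labels, exactly, on the populated bins."""
        rng = np.random.default_rng(1)
        act = rng.uniform(0, 1, 500)
        lab = rng.random(500) < 0.3
        t = build_confidence_table(act, lab)
        populated = t.counts > 0
        total = (t.confidence[populated] * t.counts[populated]).sum()
        assert total == pytest.approx(lab.sum(), abs=1e-9)

    def test_empty_bins_interpolated(self):
        act = np.array([0.05] * 10 + [0.95] * 10)
        lab = np.array([False] * 10 + [True] * 10)
        t = build_confidence_table(act, lab)
        assert t.confidence[0] == 0.0
        assert t.confidence[9] == 1.0
        # middle bins rise monotonically between the two populated bins
        assert np.all(np.diff(t.confidence) >= 0)
        assert 0.4 < t.confidence[4] < 0.6

    def test_no_data_is_error(self):
        with pytest.raises(ValueError):
            build_confidence_table(np.array([]), np.array([], dtype=bool))


class TestLookup:
    def make_table(self, conf):
        return ConfidenceTable(confidence=np.asarray(conf, float),
                               counts=np.ones(10, int), positives=np.zeros(10, int))

    def test_bin_lookup(self):
        t = self.make_table([0.1] * 5 + [0.7] + [0.1] * 4)
        assert to_confidence(0.55, t) == pytest.approx(0.7)

    def test_activity_one_maps_to_last_bin(self):
        t = self.make_table(np.linspace(0, 0.9, 10))
        assert to_confidence(1.0, t) == pytest.approx(0.9)

    def test_out_of_range_is_error(self):
        t = self.make_table(np.zeros(10))
        with pytest.raises(ValueError):
            to_confidence(1.2, t)

    def test_monotone_tables_give_monotone_confidences(self):
        rng = np.random.default_rng(2)
        conf = np.sort(rng.uniform(0, 1, 10))
        t = self.make_table(conf)
        act = np.sort(rng.uniform(0, 1, 50))
        out = to_confidence(act, t)
        assert np.all(np.diff(out) >= 0)


def brute_force_patches(coords, conf, seed_thr=0.6, grow=11.0, member_thr=0.2,
                        merge=10.0):
    """Independent oracle: explicit pairwise single-linkage over seeds, then
    membership by any-seed distance."""
    import itertools

    seeds = [i for i in range(len(conf)) if conf[i] > seed_thr]
    groups = [{s} for s in seeds]
    changed = True
    while changed:
        changed = False
        for a, b in itertools.combinations(range(len(groups)), 2):
            if any(np.linalg.norm(coords[i] - coords[j]) <= merge
                   for i in groups[a] for j in groups[b]):
                groups[a] |= groups[b]
                del groups[b]
                changed = True
                break
    out = []
    for g in groups:
        members = {i for i in range(len(conf)) if conf[i] > member_thr
                   and any(np.linalg.norm(coords[i] - coords[s]) <= grow for s in g)}
        out.append((frozenset(g), frozenset(members)))
    return set(out)


class TestPatches:
    def test_no_confident_atom_no_patch(self):
        coords = np.random.default_rng(0).uniform(0, 20, (10, 3))
        assert call_patches(coords, np.full(10, 0.5)) == []

    def test_two_seeds_within_merge_distance_form_one_patch(self):
        coords = np.array([[0, 0, 0], [9.0, 0, 0], [30.0, 0, 0]])
        conf = np.array([0.9, 0.8, 0.1])
        patches = call_patches(coords, conf)
        assert len(patches) == 1
        assert patches[0].seed_idx == [0, 1]

    def test_two_seeds_beyond_merge_distance_stay_separate(self):
        coords = np.array([[0, 0, 0], [10.5, 0, 0]])
        conf = np.array([0.9, 0.8])
        assert len(call_patches(coords, conf)) == 2

    def test_matches_brute_force_oracle_on_random_toys(self):
        rng = np.random.default_rng(4)
        for trial in range(5):
            coords = rng.uniform(0, 40, size=(50, 3))
            conf = rng.uniform(0, 1, 50)
            got = {(frozenset(p.seed_idx), frozenset(p.member_idx))
                   for p in call_patches(coords, conf)}
            want = brute_force_patches(coords, conf)
            assert got == want, f"trial {trial}"

    def test_order_and_rigid_motion_invariance(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 30, size=(40, 3))
        conf = rng.uniform(0, 1, 40)
        base = {(frozenset(p.seed_idx), frozenset(p.member_idx))
                for p in call_patches(coords, conf)}
        rot = random_rotation(rng)
        moved = coords @ rot.T + rng.uniform(-5, 5, 3)
        assert {(frozenset(p.seed_idx), frozenset(p.member_idx))
                for p in call_patches(moved, conf)} == base

    def test_raising_seed_threshold_shrinks_membership(self):
        rng = np.random.default_rng(6)
        coords = rng.uniform(0, 30, size=(60, 3))
        conf = rng.uniform(0, 1, 60)
        lo = set().union(*[p.member_idx for p in call_patches(coords, conf, seed_threshold=0.6)] or [set()])
        hi = set().union(*[p.member_idx for p in call_patches(coords, conf, seed_threshold=0.8)] or [set()])
        assert hi <= lo


def residue_structure(n_surface=10, n_buried=2):
    atoms = []
    for i in range(n_surface):
        atoms.append(AtomSite("A", "LEU", 1, f"S{i}", np.array([i, 0.0, 0.0]),
                              type_id=8, radius=1.87, sasa_u=5.0, dsasa=0.0))
    for i in range(n_buried):
        atoms.append(AtomSite("A", "LEU", 1, f"B{i}", np.array([i, 5.0, 0.0]),
                              type_id=8, radius=1.87, sasa_u=0.0))
    return Structure(atoms)


class TestResidueConversion:
    @pytest.mark.parametrize("n_members,expected", [(4, True), (3, False)])
    def test_thirty_percent_rule_is_strict(self, n_members, expected):
        st = residue_structure()
        patch = Patch(seed_idx=[0], member_idx=list(range(n_members)))
        calls = residues_from_patches([patch], st, list(range(len(st))))
        assert calls[("A", 1)][0] is expected

    def test_fully_buried_residue_excluded(self):
        atoms = [AtomSite("A", "LEU", 7, "CB", np.zeros(3), type_id=8,
                          radius=1.87, sasa_u=0.0)]
        st = Structure(atoms)
        assert residues_from_patches([], st, []) == {}
        assert actual_residue_sites(st) == {}

    def test_actual_sites_same_rule_on_dsasa(self):
        st = residue_structure()
        for a in st.atoms[:4]:
            a.dsasa = 0.5
        calls = actual_residue_sites(st)
        assert calls[("A", 1)] == (True, pytest.approx(0.4))
        st2 = residue_structure()
        for a in st2.atoms[:3]:
            a.dsasa = 1.0
        assert actual_residue_sites(st2)[("A", 1)][0] is False

    def test_missing_dsasa_is_error(self):
        st = residue_structure()
        st.atoms[0].dsasa = None
        with pytest.raises(ValueError, match="dSASA"):
            actual_residue_sites(st)

    def test_conversion_idempotent(self):
        st = residue_structure()
        patch = Patch(seed_idx=[0], member_idx=list(range(5)))
        once = residues_from_patches([patch], st, list(range(len(st))))
        again = residues_from_patches([patch], st, list(range(len(st))))
        assert once == again
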