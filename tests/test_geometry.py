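"""Dihedral-angle distance, exemplars, radii, and structural neighbors."""

import numpy as np
import pytest

from cdrcanon import (
    angle_term,
    compute_exemplar,
    exemplar_distance_profile,
    exemplar_separation,
    loop_distance,
    structural_neighbors,
)

from conftest import dihedral_record, random_dihedrals
from _oracles import loop_distance_naive, medoid_naive


class TestAngleTerm:
    def test_identical_angles_zero(self):
        assert angle_term(50.0, 50.0) == pytest.approx(0.0)

    def test_opposite_angles_max(self):
        assert angle_term(0.0, 180.0) == pytest.approx(4.0)

    def test_periodicity_360(self):
        assert angle_term(10.0, -350.0) == pytest.approx(0.0, abs=1e-12)

    def test_range_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            v = angle_term(rng.uniform(-180, 180), rng.uniform(-180, 180))
            assert 0.0 <= v <= 4.0


class TestLoopDistance:
    def test_identical_dihedrals_zero(self):
        rng = np.random.default_rng(1)
        d = random_dihedrals(rng, 6)
        a = dihedral_record("a", d)
        b = dihedral_record("b", d)
        assert loop_distance(a, b) == pytest.approx(0.0)

    def test_single_residue_phi_flip(self):
        a = dihedral_record("a", [(0.0, 50.0)])
        b = dihedral_record("b", [(180.0, 50.0)])
        assert loop_distance(a, b) == pytest.approx(4.0)

    def test_100_random_pairs_match_naive_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            L = int(rng.integers(1, 18))
            da, db = random_dihedrals(rng, L), random_dihedrals(rng, L)
            a, b = dihedral_record("a", da), dihedral_record("b", db)
            assert loop_distance(a, b) == pytest.approx(
                loop_distance_naive(da, db), abs=1e-9)
            assert loop_distance(a, b) == pytest.approx(loop_distance(b, a))
            assert 0.0 <= loop_distance(a, b) <= 8 * L

    def test_length_mismatch_rejected(self):
        a = dihedral_record("a", [(0.0, 0.0)])
        b = dihedral_record("b", [(0.0, 0.0), (1.0, 1.0)])
        with pytest.raises(ValueError):
            loop_distance(a, b)

    def test_missing_dihedrals_rejected(self):
        from conftest import make_record
        a = dihedral_record("a", [(0.0, 0.0)] * 8)
        b = make_record(rid="b")
        with pytest.raises(ValueError):
            loop_distance(a, b)


class TestExemplar:
    def test_single_member_cluster(self):
        a = dihedral_record("only", [(10.0, 20.0)] * 3)
        geo = compute_exemplar([a])
        assert geo.exemplar_id == "only"
        assert geo.radius == 0.0
        assert geo.member_distances == {"only": 0.0}

    def test_collinear_members_middle_is_medoid(self):
        base = [(0.0, 0.0)] * 4
        def shift(phi):
            return [(phi, 0.0)] + base[1:]
        members = [dihedral_record("left", shift(-10.0)),
                   dihedral_record("mid", shift(0.0)),
                   dihedral_record("right", shift(10.0))]
        geo = compute_exemplar(members)
        assert geo.exemplar_id == "mid"
        oracle = medoid_naive([m.dihedrals for m in
                               sorted(members, key=lambda r: r.record_id)])
        assert geo.exemplar_id == sorted(m.record_id for m in members)[oracle]

    def test_medoid_matches_exhaustive_oracle_random_cluster(self):
        rng = np.random.default_rng(3)
        members = [dihedral_record(f"m{i:02d}", random_dihedrals(rng, 5))
                   for i in range(12)]
        geo = compute_exemplar(members)
        oracle_idx = medoid_naive([m.dihedrals for m in members])
        assert geo.exemplar_id == members[oracle_idx].record_id
        assert geo.radius == pytest.approx(
            max(geo.member_distances.values()))
        assert geo.member_distances[geo.exemplar_id] == 0.0

    def test_invariant_under_member_reordering(self):
        rng = np.random.default_rng(4)
        members = [dihedral_record(f"m{i}", random_dihedrals(rng, 4))
                   for i in range(8)]
        geo1 = compute_exemplar(members)
        geo2 = compute_exemplar(list(reversed(members)))
        assert geo1.exemplar_id == geo2.exemplar_id
        assert geo1.radius == pytest.approx(geo2.radius)

    def test_external_exemplar_override(self):
        rng = np.random.default_rng(5)
        members = [dihedral_record(f"m{i}", random_dihedrals(rng, 4))
                   for i in range(5)]
        geo = compute_exemplar(members, exemplar_id="m3")
        assert geo.exemplar_id == "m3"
        assert geo.member_distances["m3"] == 0.0


class TestStructuralNeighbors:
    def _cluster(self, rng, n=20, length=5, sd=15.0):
        center = np.array(random_dihedrals(rng, length))
        members = []
        for i in range(n):
            noise = rng.normal(0, sd, size=center.shape)
            d = [(float(a), float(b)) for a, b in
                 np.clip(center + noise, -179.9, 180.0)]
            members.append(dihedral_record(f"m{i:02d}", d))
        return members

    def test_identical_members_always_neighbors(self):
        d = [(10.0, 20.0)] * 4
        members = [dihedral_record(f"m{i}", d) for i in range(4)]
        far = dihedral_record("far", [(170.0, -90.0)] * 4)
        geo = compute_exemplar(members + [far])
        count = structural_neighbors(members[0], geo, members + [far])
        assert count >= 3

    def test_zero_fraction_gives_zero(self):
        rng = np.random.default_rng(6)
        members = self._cluster(rng)
        geo = compute_exemplar(members)
        assert structural_neighbors(members[0], geo, members,
                                    fraction=0.0) == 0

    def test_counts_match_exhaustive_pairwise_check(self):
        rng = np.random.default_rng(7)
        members = self._cluster(rng, n=20)
        geo = compute_exemplar(members)
        threshold = geo.radius / 15.0
        for q in members[:5]:
            expected = sum(
                1 for m in members
                if m.record_id != q.record_id
                and loop_distance_naive(q.dihedrals, m.dihedrals) < threshold
            )
            assert structural_neighbors(q, geo, members) == expected

    def test_zero_radius_multimember_warns_and_returns_zero(self):
        d = [(0.0, 0.0)] * 3
        members = [dihedral_record(f"m{i}", d) for i in range(3)]
        geo = compute_exemplar(members)
        assert geo.radius == 0.0
        assert structural_neighbors(members[0], geo, members) == 0


class TestProfilesAndSeparation:
    def test_all_correct_predictions_empty_incorrect_stratum(self):
        rng = np.random.default_rng(8)
        members = [dihedral_record(f"m{i}", random_dihedrals(rng, 4))
                   for i in range(6)]
        geo = compute_exemplar(members)
        preds = {m.record_id: m.cluster_label for m in members}
        profile = exemplar_distance_profile(
            members, {members[0].cluster_label: geo}, preds)
        assert profile["correct"].all()
        assert profile.loc[
            profile.record_id == geo.exemplar_id, "exemplar_distance"
        ].iloc[0] == 0.0

    def test_distance_blind_errors_enriched_in_far_lobe(self):
        # two-lobe cluster: a tight lobe at the exemplar and a far lobe;
        # if predictions fail exactly on the far lobe, the incorrect
        # stratum must have the larger mean exemplar distance
        near = [(0.0, 0.0)] * 4
        far = [(120.0, 120.0)] * 4
        members = ([dihedral_record(f"n{i}", near) for i in range(10)]
                   + [dihedral_record(f"f{i}", far) for i in range(5)])
        geo = compute_exemplar(members)
        label = members[0].cluster_label
        preds = {m.record_id: (label if m.record_id.startswith("n")
                               else "other") for m in members}
        profile = exemplar_distance_profile(members, {label: geo}, preds)
        wrong = profile[~profile.correct]["exemplar_distance"].mean()
        right = profile[profile.correct]["exemplar_distance"].mean()
        assert wrong > right

    def test_separation_is_exemplar_distance(self):
        rng = np.random.default_rng(9)
        a = [dihedral_record(f"a{i}", random_dihedrals(rng, 4),
                             cluster="L2-4-1") for i in range(4)]
        b = [dihedral_record(f"b{i}", random_dihedrals(rng, 4),
                             cluster="L2-4-2") for i in range(4)]
        ga, gb = compute_exemplar(a), compute_exemplar(b)
        sep = exemplar_separation(ga, gb)
        assert sep == pytest.approx(
            loop_distance(ga.exemplar_record, gb.exemplar_record))
        assert exemplar_separation(ga, ga) == pytest.approx(0.0)
        assert exemplar_separation(gb, ga) == pytest.approx(sep)
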