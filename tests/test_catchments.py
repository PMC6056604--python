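"""Flow-weight construction, plurality HSAs and catchment descriptives."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import hsanet as hn


def adm(rows):
    return pd.DataFrame(rows, columns=["person_id", "area_id", "hospital_id"])


class TestMergeEpisodes:
    def test_transfer_collapses_to_first_hospital(self):
        df = pd.DataFrame({
            "person_id": ["p1", "p1"],
            "area_id": ["A", "A"],
            "hospital_id": ["H1", "H2"],
            "episode_id": ["e1", "e1"],
        })
        out = hn.merge_episodes(df)
        assert len(out) == 1
        assert out.loc[0, "hospital_id"] == "H1"
        out_last = hn.merge_episodes(df, attribute="last")
        assert out_last.loc[0, "hospital_id"] == "H2"

    def test_distinct_episodes_unchanged(self):
        df = pd.DataFrame({
            "person_id": ["p1", "p2"],
            "area_id": ["A", "A"],
            "hospital_id": ["H1", "H2"],
            "episode_id": ["e1", "e2"],
        })
        out = hn.merge_episodes(df)
        assert len(out) == 2
        assert sorted(out["hospital_id"]) == ["H1", "H2"]

    def test_five_rows_two_pairs_one_singleton(self):
        # hand count: episodes {e1: 2 rows, e2: 2 rows, e3: 1 row} -> 3 records
        df = pd.DataFrame({
            "person_id": ["p1"] * 5,
            "area_id": ["A"] * 5,
            "hospital_id": ["H1", "H2", "H3", "H1", "H2"],
            "episode_id": ["e1", "e1", "e2", "e2", "e3"],
        })
        out = hn.merge_episodes(df)
        assert len(out) == 3
        assert set(zip(out["episode_id"], out["hospital_id"])) == {
            ("e1", "H1"), ("e2", "H3"), ("e3", "H2"),
        }

    def test_preventable_flag_is_ored_over_episode(self):
        df = pd.DataFrame({
            "person_id": ["p1", "p1"],
            "area_id": ["A", "A"],
            "hospital_id": ["H1", "H2"],
            "preventable": [0, 1],
            "episode_id": ["e1", "e1"],
        })
        assert hn.merge_episodes(df).loc[0, "preventable"] == 1

    def test_missing_column_named_in_error(self):
        with pytest.raises(ValueError, match="hospital_id"):
            hn.merge_episodes(pd.DataFrame({"person_id": ["p"], "area_id": ["A"]}))

    def test_no_episode_column_is_identity(self):
        df = adm([("p1", "A", "H1"), ("p2", "A", "H2")])
        pd.testing.assert_frame_equal(hn.merge_episodes(df), df)


class TestAreaWeights:
    def test_proportional_counts(self):
        df = adm([("p", "A", "H1")] * 3 + [("p", "A", "H2")])
        profiles, _ = hn.compute_area_weights(df)
        assert profiles["A"].weights == {"H1": 0.75, "H2": 0.25}

    def test_single_hospital_area(self):
        profiles, _ = hn.compute_area_weights(adm([("p", "B", "H1")] * 4))
        assert profiles["B"].weights == {"H1": 1.0}

    def test_three_hospital_split(self):
        df = adm([("p", "C", "H1")] * 3 + [("p", "C", "H2")] * 2
                 + [("p", "C", "H3")])
        profiles, _ = hn.compute_area_weights(df)
        w = profiles["C"].weights
        assert w["H1"] == pytest.approx(0.5)
        assert w["H2"] == pytest.approx(1 / 3)
        assert w["H3"] == pytest.approx(1 / 6)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="no admissions"):
            hn.compute_area_weights(adm([]))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(
        st.tuples(st.sampled_from("ABCD"), st.sampled_from(["H1", "H2", "H3"])),
        min_size=1, max_size=40,
    ))
    def test_weights_sum_to_one_and_assignment_order_invariant(self, pairs):
        df = adm([(f"p{i}", a, h) for i, (a, h) in enumerate(pairs)])
        profiles, _ = hn.compute_area_weights(df)
        for p in profiles.values():
            assert abs(sum(p.weights.values()) - 1.0) < 1e-9
            assert all(w > 0 for w in p.weights.values())
        shuffled = df.sample(frac=1, random_state=0)
        profiles2, _ = hn.compute_area_weights(shuffled)
        a1 = hn.assign_hsa(profiles).assignment
        a2 = hn.assign_hsa(profiles2).assignment
        assert a1 == a2


class TestAssignHsa:
    def test_argmax_assignment(self):
        prof = hn.AreaFlowProfile("A", {"H1": 0.75, "H2": 0.25})
        assert hn.assign_hsa({"A": prof}).assignment["A"] == "H1"

    def test_tie_broken_lexicographically(self):
        prof = hn.AreaFlowProfile("A", {"H2": 0.5, "H1": 0.5})
        assert hn.assign_hsa({"A": prof}).assignment["A"] == "H1"

    def test_never_plurality_hospital_has_empty_hsa(self):
        # 5 areas, 3 hospitals; H3 holds at most 40% anywhere -> empty HSA
        profiles = {
            "A1": hn.AreaFlowProfile("A1", {"H1": 0.6, "H3": 0.4}),
            "A2": hn.AreaFlowProfile("A2", {"H1": 0.7, "H2": 0.3}),
            "A3": hn.AreaFlowProfile("A3", {"H2": 0.6, "H3": 0.4}),
            "A4": hn.AreaFlowProfile("A4", {"H1": 1.0}),
            "A5": hn.AreaFlowProfile("A5", {"H2": 0.5, "H1": 0.2, "H3": 0.3}),
        }
        part = hn.assign_hsa(profiles)
        assert part.hsas["H3"] == frozenset()
        assert len(part.nonempty_hsas) == 2
        assert part.hsas["H1"] == frozenset({"A1", "A2", "A4"})
        assert part.hsas["H2"] == frozenset({"A3", "A5"})

    def test_hsas_exactly_invert_assignment(self):
        profiles = {
            a: hn.AreaFlowProfile(a, {"H1": 0.5 + d, "H2": 0.5 - d})
            for a, d in [("A1", 0.1), ("A2", -0.1), ("A3", 0.25)]
        }
        part = hn.assign_hsa(profiles)
        rebuilt = {a: h for h, areas in part.hsas.items() for a in areas}
        assert rebuilt == dict(part.assignment)


class TestMarketShareIndex:
    def test_ratio_by_definition(self):
        profiles, _ = hn.compute_area_weights(adm(
            [("p", "A", "H1")] * 8 + [("p", "B", "H1")] * 2
            + [("p", "B", "H2")] * 3
        ))
        part = hn.assign_hsa(profiles)  # A -> H1, B -> H2
        msi = hn.market_share_index(part, adm(
            [("p", "A", "H1")] * 8 + [("p", "B", "H1")] * 2
            + [("p", "B", "H2")] * 3
        ))
        assert msi["H1"] == pytest.approx(0.8)  # 8 of 10 from inside HSA
        assert msi["H2"] == pytest.approx(1.0)

    def test_empty_hsa_scores_zero(self):
        profiles = {
            "A": hn.AreaFlowProfile("A", {"H1": 0.6, "H2": 0.4}),
        }
        part = hn.assign_hsa(profiles)
        msi = hn.market_share_index(
            part, adm([("p", "A", "H1")] * 3 + [("p", "A", "H2")] * 2)
        )
        assert msi["H2"] == 0.0
        assert 0.0 <= min(msi.values()) and max(msi.values()) <= 1.0

    def test_all_internal_is_one(self):
        profiles, _ = hn.compute_area_weights(adm([("p", "A", "H1")] * 5))
        part = hn.assign_hsa(profiles)
        assert hn.market_share_index(part, adm([("p", "A", "H1")] * 5)) == \
            {"H1": 1.0}


class TestPersonWeights:
    profiles = {
        "A": hn.AreaFlowProfile("A", {"H1": 0.75, "H2": 0.25}),
        "B": hn.AreaFlowProfile("B", {"H2": 1.0}),
    }

    def persons(self):
        return pd.DataFrame({
            "person_id": ["p1", "p2", "p3", "p4"],
            "area_id": ["A", "A", "B", "B"],
        })

    def test_rows_inherit_area_profile_and_sum_to_one(self):
        pw = hn.person_weight_matrix(self.profiles, self.persons())
        dense = pw.matrix.toarray()
        np.testing.assert_allclose(dense.sum(axis=1), 1.0, atol=1e-9)
        i1 = pw.hospital_ids.index("H1")
        np.testing.assert_allclose(dense[0], dense[1])  # same area, same row
        assert dense[0][i1] == pytest.approx(0.75)

    def test_column_sums_are_weighted_catchment_sizes(self):
        # hand sum: H1 = 2 * 0.75 = 1.5; H2 = 2 * 0.25 + 2 * 1.0 = 2.5
        pw = hn.person_weight_matrix(self.profiles, self.persons())
        sizes = pw.weighted_catchment_sizes
        assert sizes["H1"] == pytest.approx(1.5)
        assert sizes["H2"] == pytest.approx(2.5)
        assert sizes.sum() == pytest.approx(len(pw.person_ids))

    def test_unknown_area_person_reported_not_dropped_silently(self):
        persons = pd.DataFrame({
            "person_id": ["p1", "px"], "area_id": ["A", "ZZ"],
        })
        pw = hn.person_weight_matrix(self.profiles, persons)
        assert pw.matrix.shape[0] == 1
        assert list(pw.exclusions["person_id"]) == ["px"]
        assert "no admissions" in pw.exclusions["reason"].iloc[0]


class TestWeightedCovariate:
    def test_weighted_mean(self):
        assert hn.weighted_hospital_covariate(
            np.array([0.6, 0.4]), pd.Series([90.0, 100.0], index=["H1", "H2"])
        ) == pytest.approx(94.0)

    def test_degenerate_weight_is_single_membership(self):
        assert hn.weighted_hospital_covariate(
            np.array([1.0, 0.0]), pd.Series([90.0, 100.0], index=["H1", "H2"])
        ) == pytest.approx(90.0)

    def test_uniform_weights_give_arithmetic_mean(self):
        vals = pd.Series([80.0, 90.0, 100.0, 110.0],
                         index=["H1", "H2", "H3", "H4"])
        assert hn.weighted_hospital_covariate(
            np.full(4, 0.25), vals) == pytest.approx(95.0)

    def test_missing_covariate_names_hospital(self):
        profiles = {"A": hn.AreaFlowProfile("A", {"H1": 0.5, "H2": 0.5})}
        pw = hn.person_weight_matrix(
            profiles, pd.DataFrame({"person_id": ["p"], "area_id": ["A"]})
        )
        with pytest.raises(ValueError, match="H2"):
            hn.weighted_hospital_covariate(pw, {"H1": 90.0})


class TestCatchmentSummary:
    def test_single_area_single_hospital(self):
        admissions = adm([("p1", "A", "H1")] * 3)
        profiles, _ = hn.compute_area_weights(admissions)
        part = hn.assign_hsa(profiles)
        persons = pd.DataFrame({"person_id": ["p1", "p2"],
                                "area_id": ["A", "A"]})
        s = hn.catchment_summary(profiles, part, persons, admissions)
        assert s.areas.loc["A", "share_top1"] == pytest.approx(1.0)
        for t in (5, 10, 20, 50):
            assert s.hospitals.loc["H1", f"areas_weight_gt_{t}pct"] == 1
        assert s.hospitals.loc["H1", "market_share_index"] == pytest.approx(1.0)

    def test_toy_three_area_system_matches_hand_table(self):
        admissions = adm(
            [("p", "A", "H1")] * 3 + [("p", "A", "H2")]          # A: .75/.25
            + [("p", "B", "H2")] * 4 + [("p", "B", "H1")]        # B: .8 H2
            + [("p", "C", "H1")] * 1 + [("p", "C", "H2")] * 1    # C: tie
        )
        persons = pd.DataFrame({
            "person_id": [f"p{i}" for i in range(6)],
            "area_id": ["A", "A", "B", "B", "C", "C"],
        })
        profiles, _ = hn.compute_area_weights(admissions)
        part = hn.assign_hsa(profiles)
        s = hn.catchment_summary(profiles, part, persons, admissions)
        # hand: top-1 shares .75, .8, .5 -> mean .6833
        assert s.stats["areas"]["share_top1"]["mean"] == \
            pytest.approx((0.75 + 0.8 + 0.5) / 3)
        # weighted catchments: H1 = 2*.75 + 2*.2 + 2*.5 = 2.9; H2 = 3.1
        assert s.hospitals.loc["H1", "weighted_catchment"] == pytest.approx(2.9)
        assert s.hospitals.loc["H2", "weighted_catchment"] == pytest.approx(3.1)
        assert s.hospitals["weighted_catchment"].sum() == pytest.approx(6.0)
        # C ties -> H1 by lexicographic rule; HSAs: H1 {A, C}, H2 {B}
        assert s.areas.loc["C", "assigned_hospital"] == "H1"
        assert s.stats["hsas"]["n_nonempty"] == 2

    def test_single_membership_catchment_equals_hsa_population(self):
        # every area uses exactly one hospital -> weighted size == HSA head count
        admissions = adm([("p", "A", "H1")] * 2 + [("p", "B", "H2")] * 3)
        persons = pd.DataFrame({
            "person_id": [f"p{i}" for i in range(5)],
            "area_id": ["A", "A", "B", "B", "B"],
        })
        profiles, _ = hn.compute_area_weights(admissions)
        part = hn.assign_hsa(profiles)
        s = hn.catchment_summary(profiles, part, persons, admissions)
        for h in ("H1", "H2"):
            assert s.hospitals.loc[h, "weighted_catchment"] == \
                pytest.approx(s.hospitals.loc[h, "hsa_population"])


class TestProfileValidation:
    @pytest.mark.parametrize("weights", [
        {}, {"H1": 0.5, "H2": 0.4}, {"H1": 1.2, "H2": -0.2},
    ])
    def test_invalid_profiles_rejected(self, weights):
        with pytest.raises(ValueError):
            hn.AreaFlowProfile("A", weights)
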