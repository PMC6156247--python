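"""Screening-cascade statistics: best pose, CBAV, LBPV, filters, ΔΔG°."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from multistat_screen.dock_model import (
    CompoundRecord,
    ConfigurationError,
    PocketDefinition,
    StabilityRecord,
)
from multistat_screen.screen_triage import (
    DockScoreSummary,
    PocketClass,
    TriageConfig,
    best_pose,
    cbav,
    cbav_filter,
    classify_pocket_occupancy,
    ddg0_impairment,
    lbpv,
    rank_top_k,
    run_triage,
    similarity_filter,
)
from multistat_screen.synthetic_data import PoseSimConfig, simulate_pose_table

from conftest import TABLE2_BS, make_pose, pose_set_with_classes


class TestBestPose:
    def test_highest_bs_wins(self):
        poses = [make_pose(rank=i + 1, bs=b) for i, b in enumerate([7.1, 8.09, 6.0])]
        assert best_pose(poses).bs == 8.09

    def test_single_pose_identity(self):
        p = make_pose(bs=5.0)
        assert best_pose([p]) is p

    def test_bs_tie_broken_by_less_negative_crash(self):
        a = make_pose(rank=1, bs=5.0, crash=-2.0)
        b = make_pose(rank=2, bs=5.0, crash=-1.0)
        assert best_pose([a, b]) is b

    def test_full_tie_broken_by_rank(self):
        a = make_pose(rank=2, bs=5.0, crash=-1.0)
        b = make_pose(rank=1, bs=5.0, crash=-1.0)
        assert best_pose([a, b]) is b

    def test_empty_and_mixed_sets_rejected(self):
        with pytest.raises(ValueError):
            best_pose([])
        with pytest.raises(ValueError, match="mixed"):
            best_pose([make_pose(cid="A"), make_pose(cid="B")])


class TestRankTopK:
    @pytest.fixture
    def summaries(self):
        return [DockScoreSummary(cid, best_bs={"STAT1": bs})
                for cid, bs in TABLE2_BS.items()]

    def test_primary_screen_top_compound(self, summaries):
        assert rank_top_k(summaries, "STAT1", 1)[0].compound_id == "J01"

    def test_primary_screen_top_three(self, summaries):
        top3 = [s.compound_id for s in rank_top_k(summaries, "STAT1", 3)]
        assert top3 == ["J01", "E01", "C01"]

    def test_k_exceeding_n_returns_all(self, summaries):
        assert len(rank_top_k(summaries, "STAT1", 100)) == len(summaries)

    def test_tie_stable_by_compound_id(self):
        summaries = [DockScoreSummary(c, best_bs={"T": 5.0}) for c in "BAC"]
        assert [s.compound_id for s in rank_top_k(summaries, "T", 3)] == ["A", "B", "C"]


class TestSimilarityFilter:
    def _cpd(self, cid, sim, mw=350.0):
        return CompoundRecord(cid, cid, mw, "CDL", {"C01": (sim, 2.0)})

    def test_table_level_similarity_kept(self):
        kept = similarity_filter([self._cpd("C01L_F03", 0.767)], ["C01"], 0.5, 300.0)
        assert [c.compound_id for c in kept] == ["C01L_F03"]

    def test_below_similarity_dropped(self):
        assert similarity_filter([self._cpd("X", 0.49)], ["C01"], 0.5) == []

    def test_molecular_weight_rule(self):
        assert similarity_filter([self._cpd("X", 0.6, mw=299.0)], ["C01"], 0.5, 300.0) == []
        kept = similarity_filter([self._cpd("X", 0.6, mw=300.0)], ["C01"], 0.5, 300.0)
        assert len(kept) == 1  # inclusive boundary

    def test_max_over_references(self):
        c = CompoundRecord("X", "x", 350.0, "CDL",
                           {"C01": (0.2, 1.0), "E01": (0.6, 1.0)})
        assert similarity_filter([c], ["C01", "E01"], 0.5) == [c]

    def test_compound_without_similarity_excluded(self):
        c = CompoundRecord("X", "x", 350.0, "CDL")
        assert similarity_filter([c], ["C01"], 0.5) == []

    def test_idempotent(self):
        cs = [self._cpd("A", 0.767), self._cpd("B", 0.3)]
        once = similarity_filter(cs, ["C01"], 0.5)
        assert similarity_filter(once, ["C01"], 0.5) == once


class TestCbav:
    def test_equal_scores_give_zero(self):
        assert cbav(8.23, 8.23) == 0.0

    def test_reference_preference(self):
        assert cbav(8.23, 4.87) == pytest.approx(3.36)
        assert cbav(4.0, 5.5) == pytest.approx(-1.5)

    @given(a=st.floats(-50, 50), b=st.floats(-50, 50))
    @settings(max_examples=100, derandomize=True)
    def test_antisymmetry(self, a, b):
        assert cbav(a, b) + cbav(b, a) == pytest.approx(0.0, abs=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            cbav(math.nan, 1.0)
        with pytest.raises(ValueError):
            cbav(1.0, math.inf)


class TestCbavFilter:
    def _summary(self, cid, cbav_map):
        s = DockScoreSummary(cid, best_bs={"STAT1": 8.0, "STAT2": 1.0, "STAT3": 1.0})
        s.cbav = {("STAT1", t): v for t, v in cbav_map.items()}
        return s

    def test_all_nonnegative_kept(self):
        s = self._summary("C01L_F03", {"STAT2": 3.36, "STAT3": 0.22})
        assert cbav_filter([s], "STAT1", 0.0) == [s]

    def test_any_negative_dropped(self):
        s = self._summary("E01", {"STAT2": -1.65, "STAT3": -0.73})
        assert cbav_filter([s], "STAT1", 0.0) == []

    def test_zero_boundary_inclusive(self):
        s = self._summary("X", {"STAT2": 0.0, "STAT3": 0.0})
        assert cbav_filter([s], "STAT1", 0.0) == [s]

    def test_missing_entry_excluded(self):
        s = self._summary("X", {"STAT2": 1.0})  # STAT3 entry absent
        assert cbav_filter([s], "STAT1", 0.0) == []

    def test_idempotent(self):
        sums = [self._summary("A", {"STAT2": 1.0, "STAT3": 0.5}),
                self._summary("B", {"STAT2": -0.1, "STAT3": 2.0})]
        once = cbav_filter(sums, "STAT1", 0.0)
        assert cbav_filter(once, "STAT1", 0.0) == once


class TestPocketOccupancy:
    PKTS = [PocketDefinition("pY0", (0.0, 0.0, 0.0), 5.0),
            PocketDefinition("pYX", (20.0, 0.0, 0.0), 5.0)]

    def test_flags_read_directly(self):
        assert classify_pocket_occupancy(make_pose(flags=(True, True))) is PocketClass.BOTH
        assert classify_pocket_occupancy(make_pose(flags=(False, False))) is PocketClass.NEITHER

    def test_atom_at_centroid_occupies(self):
        pose = make_pose(coords=np.array([[0.0, 0.0, 0.0]]))
        assert classify_pocket_occupancy(pose, self.PKTS) is PocketClass.PY0_ONLY

    def test_atoms_just_outside_both_radii(self):
        eps = 1e-6
        pose = make_pose(coords=np.array([[5.0 + eps, 0.0, 0.0],
                                          [20.0, 5.0 + eps, 0.0]]))
        assert classify_pocket_occupancy(pose, self.PKTS) is PocketClass.NEITHER

    def test_boundary_distance_counts_as_inside(self):
        pose = make_pose(coords=np.array([[5.0, 0.0, 0.0]]))
        assert classify_pocket_occupancy(pose, self.PKTS) is PocketClass.PY0_ONLY

    def test_coords_without_pockets_is_config_error(self):
        pose = make_pose(coords=np.zeros((1, 3)))
        with pytest.raises(ConfigurationError):
            classify_pocket_occupancy(pose, None)


class TestLbpv:
    def test_dual_pocket_fractions(self):
        assert lbpv(pose_set_with_classes(n_both=19, n_py0=1), "BOTH") == 0.95
        assert lbpv(pose_set_with_classes(n_both=5, n_neither=15), "BOTH") == 0.25
        assert lbpv(pose_set_with_classes(n_py0=20), "BOTH") == 0.0

    def test_single_pocket_aggregates(self):
        poses = pose_set_with_classes(n_both=2, n_py0=6, n_pyx=11, n_neither=1)
        assert lbpv(poses, PocketClass.PY0_ONLY) == 0.3
        assert lbpv(poses, PocketClass.PYX_ONLY) == 0.55
        assert lbpv(poses, "PY0_ANY") == pytest.approx(0.4)
        assert lbpv(poses, "PYX_ANY") == pytest.approx(0.65)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            lbpv([], "BOTH")

    @given(st.tuples(st.integers(0, 8), st.integers(0, 8),
                     st.integers(0, 8), st.integers(0, 8)).filter(lambda t: sum(t) > 0))
    @settings(max_examples=60, derandomize=True)
    def test_inclusion_exclusion_identity(self, counts):
        nb, n0, nx, nn = counts
        poses = pose_set_with_classes(n_both=nb, n_py0=n0, n_pyx=nx, n_neither=nn)
        total = (lbpv(poses, "PY0_ANY") + lbpv(poses, "PYX_ANY")
                 - lbpv(poses, "BOTH") + lbpv(poses, PocketClass.NEITHER))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            flags = [(bool(rng.integers(2)), bool(rng.integers(2)))
                     for _ in range(int(rng.integers(1, 21)))]
            poses = [make_pose(rank=i + 1, flags=f) for i, f in enumerate(flags)]
            brute = sum(1 for f in flags if f == (True, True)) / len(flags)
            assert lbpv(poses, "BOTH") == pytest.approx(brute)


class TestDdg0:
    def _pair(self, wt_dg, mut_dg):
        return (StabilityRecord("STAT1", "wt", "STATTIC", wt_dg),
                StabilityRecord("STAT1", "R602A", "STATTIC", mut_dg))

    @pytest.mark.parametrize("wt,mut,ddg,impaired", [
        (-8.0, -5.0, 3.0, True),
        (-8.0, -8.0, 0.0, False),
        (-5.0, -8.0, -3.0, False),
    ])
    def test_sign_rule(self, wt, mut, ddg, impaired):
        got_ddg, got_imp = ddg0_impairment(*self._pair(wt, mut))
        assert got_ddg == pytest.approx(ddg)
        assert got_imp is impaired

    def test_mismatched_pair_rejected(self):
        wt = StabilityRecord("STAT1", "wt", "STATTIC", -8.0)
        mut = StabilityRecord("STAT3", "R609A", "STATTIC", -5.0)
        with pytest.raises(ValueError, match="mismatched"):
            ddg0_impairment(wt, mut)
        with pytest.raises(ValueError):
            ddg0_impairment(mut, mut)


class TestRunTriage:
    def test_planted_survivors_recovered_exactly(self):
        poses, compounds, truth = simulate_pose_table(PoseSimConfig(seed=11))
        report = run_triage(poses, compounds,
                            TriageConfig(reference_compounds=["C01", "E01", "F01"]))
        assert sorted(report.final_survivors) == sorted(truth.winners)
        assert [s.n_in for s in report.stages][0] == 50

    def test_single_compound_passing_everything(self):
        poses = pose_set_with_classes(n_both=20, cid="A", tid="STAT1")
        poses += [make_pose(cid="A", tid="STAT2", rank=i + 1, bs=7.0 - 0.1 * i)
                  for i in range(20)]
        compounds = [CompoundRecord("A", "a", 350.0, "CDL", {"C01": (0.9, 1.0)})]
        report = run_triage(poses, compounds,
                            TriageConfig(reference_compounds=["C01"]))
        assert report.final_survivors == ["A"]

    def test_all_negative_cbav_empties_final_stage(self):
        poses = pose_set_with_classes(n_both=20, cid="A", tid="STAT1")
        poses += [make_pose(cid="A", tid="STAT2", rank=i + 1, bs=12.0 - 0.1 * i)
                  for i in range(20)]
        compounds = [CompoundRecord("A", "a", 350.0, "CDL", {"C01": (0.9, 1.0)})]
        report = run_triage(poses, compounds,
                            TriageConfig(reference_compounds=["C01"]))
        assert report.final_survivors == []
        names = [s.name for s in report.stages]
        assert names[-1] == "lbpv_dual_pocket"  # report completes downstream

    def test_report_json_serializes(self, tmp_path):
        poses, compounds, _ = simulate_pose_table(PoseSimConfig(seed=1, n_compounds=8))
        report = run_triage(poses, compounds,
                            TriageConfig(reference_compounds=["C01"], top_k=5))
        text = report.to_json(tmp_path / "r.json")
        assert (tmp_path / "r.json").read_text() == text
        assert '"stages"' in text
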