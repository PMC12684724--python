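"""Isotopologue-group detection: member matching, Welch test, scan logic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import isocontext as ic
from isocontext.errors import ConfigurationError

C13 = ic.TracerDef.from_name("13C")


def _table(rows: dict[str, tuple[float, float, list[float]]],
           samples: list[str]) -> ic.FeatureTable:
    """rows: feature_id -> (mz, rt, intensities per sample)."""
    df = pd.DataFrame({fid: [mz, rt] + list(vals)
                       for fid, (mz, rt, vals) in rows.items()},
                      index=["mz", "rt"] + samples).T
    df.index.name = "feature_id"
    return ic.FeatureTable(df)


class TestCandidateMembers:
    PARAMS = ic.DetectionParams(ppm_tol=5.0, rt_window=10.0, n_max=3)

    def test_close_isotopologue_matched(self):
        # hand oracle: |182.0740 - 182.07406| / 182.074 = 0.31 ppm
        feats = _table({"B": (181.0707, 120.0, [1.0]),
                        "M1": (182.0740, 121.0, [1.0])}, ["S1"])
        members = ic.candidate_members(feats, "B", C13, self.PARAMS)
        assert members == [(0, "B", 181.0707), (1, "M1", 182.0740)]

    def test_far_candidate_rejected(self):
        # 182.0780 is ~22 ppm above the n=1 target: outside any window here
        feats = _table({"B": (181.0707, 120.0, [1.0]),
                        "X": (182.0780, 121.0, [1.0])}, ["S1"])
        members = ic.candidate_members(feats, "B", C13, self.PARAMS)
        assert members == [(0, "B", 181.0707)]

    def test_closest_mz_wins_on_ambiguity(self):
        target = 181.0707 + C13.delta_mass
        feats = _table({"B": (181.0707, 120.0, [1.0]),
                        "NEAR": (target + 1e-4, 121.0, [1.0]),
                        "FAR": (target + 5e-4, 121.0, [1.0])}, ["S1"])
        members = ic.candidate_members(feats, "B", C13, self.PARAMS)
        assert [fid for _, fid, _ in members] == ["B", "NEAR"]

    def test_rt_window_enforced(self):
        feats = _table({"B": (181.0707, 120.0, [1.0]),
                        "M1": (181.0707 + C13.delta_mass, 140.0, [1.0])},
                       ["S1"])
        members = ic.candidate_members(feats, "B", C13, self.PARAMS)
        assert len(members) == 1


class TestRelativeIntensities:
    def test_normalization(self, small_feature_table):
        members = [(0, "F1", 181.0707), (1, "F1_M1", 182.0740)]
        rel = ic.per_sample_relative_intensities(members, small_feature_table,
                                                 ["U1"])
        assert rel["U1"] == pytest.approx([0.99, 0.01])

    def test_all_absent_sample_dropped(self):
        feats = _table({"A": (100.0, 10.0, [np.nan, 5.0]),
                        "B": (101.0, 10.0, [np.nan, 5.0])}, ["S1", "S2"])
        rel = ic.per_sample_relative_intensities(
            [(0, "A", 100.0), (1, "B", 101.0)], feats, ["S1", "S2"])
        assert set(rel) == {"S2"}

    def test_single_member_group(self):
        feats = _table({"A": (100.0, 10.0, [42.0])}, ["S1"])
        rel = ic.per_sample_relative_intensities([(0, "A", 100.0)], feats,
                                                 ["S1"])
        assert rel["S1"] == pytest.approx([1.0])

    def test_interior_gap_is_zero_not_shift(self):
        feats = _table({"A": (100.0, 10.0, [80.0]),
                        "C": (102.0, 10.0, [20.0])}, ["S1"])
        rel = ic.per_sample_relative_intensities(
            [(0, "A", 100.0), (2, "C", 102.0)], feats, ["S1"])
        assert rel["S1"] == pytest.approx([0.8, 0.0, 0.2])


class TestWelch:
    def test_degenerate_equal(self):
        t, _, p = ic.welch_t_test([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert (t, p) == (0.0, 1.0)

    def test_identical_samples(self):
        t, _, p = ic.welch_t_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert t == 0.0 and p == 1.0

    def test_hand_computed_example(self):
        # textbook Welch: means 0.85/0.15, s^2 = 0.005 each, n = 2
        t, df, p = ic.welch_t_test([0.8, 0.9], [0.1, 0.2])
        assert t == pytest.approx(9.899, rel=1e-3)
        assert df == pytest.approx(2.0, rel=1e-3)
        assert p == pytest.approx(0.01005, rel=1e-3)

    def test_degenerate_unequal_means(self):
        t, _, p = ic.welch_t_test([1.0, 1.0], [0.0, 0.0])
        assert np.isinf(t) and p == 0.0

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            a = rng.normal(0.0, 1.0, rng.integers(2, 8))
            b = rng.normal(0.3, 2.0, rng.integers(2, 8))
            t, df, p = ic.welch_t_test(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_too_few_observations(self):
        with pytest.raises(ConfigurationError):
            ic.welch_t_test([1.0], [1.0, 2.0])


class TestBenjaminiHochberg:
    def test_hand_example(self):
        # p(i)*m/i then step-down monotonization: (.03, .03, .03)
        assert ic.adjust_pvalues_bh([0.01, 0.02, 0.03]) == \
            pytest.approx([0.03, 0.03, 0.03])

    def test_single_value(self):
        assert ic.adjust_pvalues_bh([1.0]) == [1.0]

    def test_positions_preserved(self):
        p = [0.04, 0.001, 0.9]
        adj = ic.adjust_pvalues_bh(p)
        assert np.argsort(adj).tolist() == np.argsort(p).tolist()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, 40)
        ours = ic.adjust_pvalues_bh(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert ours == pytest.approx(ref, rel=1e-12)


class TestDetectGroups:
    def _simulate_pair(self, m1_lab, m1_unl, seed, cv=0.05):
        rng = np.random.default_rng(seed)
        base = 1e6
        rows = {}
        sigma = np.sqrt(np.log1p(cv ** 2))
        noise = lambda n: rng.lognormal(-sigma ** 2 / 2, sigma, n)
        lab0 = base * (1 - m1_lab) * noise(3)
        lab1 = base * m1_lab * noise(3)
        unl0 = base * (1 - m1_unl) * noise(3)
        unl1 = base * max(m1_unl, 1e-9) * noise(3)
        rows["B"] = (181.0707, 120.0, list(lab0) + list(unl0))
        rows["M1"] = (181.0707 + C13.delta_mass, 120.0,
                      list(lab1) + list(unl1))
        feats = _table(rows, ["L1", "L2", "L3", "U1", "U2", "U3"])
        sheet = ic.SampleSheet(pd.DataFrame({
            "sample_id": ["L1", "L2", "L3", "U1", "U2", "U3"],
            "experiment": "e", "condition": "c",
            "tracer_state": ["labeled"] * 3 + ["unlabeled"] * 3,
            "replicate": [1, 2, 3] * 2}))
        return feats, sheet

    def test_enriched_group_detected(self):
        feats, sheet = self._simulate_pair(0.4, 0.01, seed=5)
        groups = ic.detect_groups(feats, sheet, C13, ic.DetectionParams(),
                                  "c")
        assert len(groups) == 1
        assert groups[0].p_values[1] <= 0.05
        # direct Welch on the generated relative intensities agrees
        rel_l = ic.per_sample_relative_intensities(groups[0].members, feats,
                                                   ["L1", "L2", "L3"])
        rel_u = ic.per_sample_relative_intensities(groups[0].members, feats,
                                                   ["U1", "U2", "U3"])
        _, _, p = ic.welch_t_test([v[1] for v in rel_l.values()],
                                  [v[1] for v in rel_u.values()])
        assert p <= 0.05

    def test_null_rarely_detected(self):
        # labeled == unlabeled distribution: detection is a false positive
        hits = 0
        for seed in range(100):
            feats, sheet = self._simulate_pair(0.05, 0.05, seed=200 + seed)
            groups = ic.detect_groups(feats, sheet, C13,
                                      ic.DetectionParams(), "c")
            hits += bool(groups)
        assert hits <= 5  # >= 95% of seeds yield nothing

    def test_noise_floor_blocks_base(self):
        feats, sheet = self._simulate_pair(0.4, 0.01, seed=5)
        params = ic.DetectionParams(noise_floor=1e9)
        assert ic.detect_groups(feats, sheet, C13, params, "c") == []

    def test_missing_replicates_is_configuration_error(self):
        feats, sheet = self._simulate_pair(0.4, 0.01, seed=5)
        sheet = ic.SampleSheet(sheet.data[sheet.data["sample_id"] != "U3"]
                               .reset_index(drop=True))
        params = ic.DetectionParams(min_replicates=3)
        with pytest.raises(ConfigurationError, match="c"):
            ic.detect_groups(feats, sheet, C13, params, "c")

    def test_rescaling_one_sample_invariant(self):
        feats, sheet = self._simulate_pair(0.4, 0.01, seed=5)
        scaled = ic.FeatureTable(feats.data.copy())
        scaled.data["L2"] = scaled.data["L2"] * 10.0
        g1 = ic.detect_groups(feats, sheet, C13, ic.DetectionParams(), "c")
        g2 = ic.detect_groups(scaled, sheet, C13, ic.DetectionParams(), "c")
        assert [g.member_ids for g in g1] == [g.member_ids for g in g2]
        assert [g.p_values for g in g1] == [g.p_values for g in g2]


class TestBenchmarkInvariants:
    def test_no_feature_in_two_groups(self, benchmark_run):
        seen = set()
        for g in benchmark_run["groups"]:
            for fid in g.member_ids:
                assert fid not in seen
                seen.add(fid)

    def test_member_ladder_spacing_within_window(self, benchmark_run):
        params = ic.DetectionParams()
        for g in benchmark_run["groups"]:
            prev_n, prev_mz = g.members[0][0], g.members[0][2]
            for n, _, mz in g.members[1:]:
                target = prev_mz + (n - prev_n) * C13.delta_mass
                tol = params.pair_tol_factor * params.ppm_tol * target * 1e-6
                assert abs(mz - target) <= tol
                prev_n, prev_mz = n, mz

    def test_groups_frame_round_trip(self, benchmark_run):
        from isocontext.isotope_detection import groups_from_frame, \
            groups_to_frame

        frame = groups_to_frame(benchmark_run["groups"])
        back = groups_from_frame(frame)
        orig = sorted(benchmark_run["groups"], key=lambda g: g.group_id)
        assert len(back) == len(orig)
        for a, b in zip(back, orig):
            assert a.members == b.members
            assert a.p_values == pytest.approx(b.p_values)
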