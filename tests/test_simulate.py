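"""Generative model: rate function, session structure, Poisson calibration, I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bilat import (
    DirectionGrid,
    GroundTruthDistributions,
    PhaseDurations,
    SessionFormatError,
    SimConfig,
    rate_function,
    read_session,
    simulate_session,
    write_session,
)
from bilat.simulate import _go_rate_vector


class TestRateFunction:
    def test_prepare_and_rest_return_baseline(self, make_gt):
        gt = make_gt(baseline=12.0)
        for phase in ("prepare", "rest"):
            assert rate_function(gt, "bimanual", phase) == 12.0

    def test_zero_modulation_returns_baseline(self, make_gt):
        gt = make_gt(baseline=7.5, md_ipsi=0.0, md_contra=0.0)
        assert rate_function(gt, "contra", "go", contra_dir_deg=123.0) == 7.5
        assert rate_function(gt, "bimanual", "go", 45.0, 270.0) == pytest.approx(7.5)

    def test_unimanual_go_at_pd_adds_full_amplitude(self, make_gt):
        gt = make_gt(baseline=10.0, md_contra=5.0, pd_contra=90.0)
        assert rate_function(gt, "contra", "go", contra_dir_deg=90.0) == pytest.approx(15.0)

    def test_bimanual_symmetric_cancellation(self, make_gt):
        gt = make_gt(
            baseline=10.0, md_ipsi=4.0, md_contra=4.0, pd_ipsi=0.0, pd_contra=90.0,
            gain_ipsi=1.0, gain_contra=1.0,
        )
        # contra at its PD, ipsi anti-preferred: contributions cancel exactly
        r = rate_function(gt, "bimanual", "go", ipsi_dir_deg=180.0, contra_dir_deg=90.0)
        assert r == pytest.approx(10.0)

    def test_rates_clip_at_zero(self, make_gt):
        gt = make_gt(baseline=1.0, md_contra=5.0, pd_contra=0.0)
        assert rate_function(gt, "contra", "go", contra_dir_deg=180.0) == 0.0

    def test_missing_or_extra_direction_rejected(self, make_gt):
        gt = make_gt()
        with pytest.raises(ValueError):
            rate_function(gt, "ipsi", "go")
        with pytest.raises(ValueError):
            rate_function(gt, "ipsi", "go", ipsi_dir_deg=0.0, contra_dir_deg=0.0)
        with pytest.raises(ValueError):
            rate_function(gt, "bimanual", "go", ipsi_dir_deg=0.0)
        with pytest.raises(ValueError):
            rate_function(gt, "swim", "go", ipsi_dir_deg=0.0)
        with pytest.raises(ValueError):
            rate_function(gt, "ipsi", "warmup", ipsi_dir_deg=0.0)

    @settings(max_examples=50, derandomize=True)
    @given(
        theta_i=st.floats(0, 359.9), theta_c=st.floats(0, 359.9),
        md=st.floats(0, 30), base=st.floats(0, 20),
    )
    def test_rate_is_nonnegative(self, theta_i, theta_c, md, base):
        from bilat import NeuronGroundTruth

        gt = NeuronGroundTruth(
            unit_id="u0", baseline_hz=base,
            md_uni_ipsi_hz=md, md_uni_contra_hz=md,
            pd_uni_ipsi_deg=10.0, pd_uni_contra_deg=200.0,
            md_bi_ipsi_hz=md, md_bi_contra_hz=md,
            pd_bi_ipsi_deg=10.0, pd_bi_contra_deg=200.0,
            bimanual_gain_ipsi=1.0, bimanual_gain_contra=1.0,
        )
        assert rate_function(gt, "bimanual", "go", theta_i, theta_c) >= 0.0

    def test_vectorized_rates_match_scalar_model(self, make_gt):
        gts = [make_gt(unit_id=f"u{i}", pd_ipsi=30.0 * i, pd_contra=40.0 * i,
                       md_ipsi=1.0 + i, baseline=5.0 + i) for i in range(5)]
        for task, di, dc in (("ipsi", 45.0, None), ("contra", None, 135.0), ("bimanual", 45.0, 225.0)):
            vec = _go_rate_vector(gts, task, di, dc)
            for u, gt in enumerate(gts):
                assert vec[u] == pytest.approx(rate_function(gt, task, "go", di, dc))


class TestSimulateSession:
    def test_block_and_trial_counts(self, tiny_session):
        _, trials, _ = tiny_session
        counts = trials.groupby("block_type").size()
        # 8 directions (or 16 bimanual configurations) x n_reps=2
        assert counts["ipsi"] == 16
        assert counts["contra"] == 16
        assert counts["bimanual"] == 32
        assert trials["block_id"].nunique() == 3
        # every configuration appears exactly n_reps times
        bi = trials[trials["block_type"] == "bimanual"]
        assert bi.groupby(["ipsi_dir_deg", "contra_dir_deg"]).size().eq(2).all()

    def test_default_session_trial_total(self):
        cfg = SimConfig(n_units=1, rng_seed=0)
        _, trials, _ = simulate_session(cfg)
        # 8 reps x (8 + 8 + 16) target configurations
        assert len(trials) == 256

    def test_unimanual_trials_leave_other_arm_empty(self, tiny_session):
        _, trials, _ = tiny_session
        assert trials.loc[trials.block_type == "ipsi", "contra_dir_deg"].isna().all()
        assert trials.loc[trials.block_type == "contra", "ipsi_dir_deg"].isna().all()
        assert trials.loc[trials.block_type == "bimanual", ["ipsi_dir_deg", "contra_dir_deg"]].notna().all().all()

    def test_same_seed_is_bit_identical(self):
        cfg = SimConfig(n_units=4, n_reps_per_config=1, rng_seed=5)
        s1, t1, g1 = simulate_session(cfg)
        s2, t2, g2 = simulate_session(cfg)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(t1, t2)
        assert g1 == g2

    def test_spikes_sorted_within_unit(self, tiny_session):
        spikes, _, _ = tiny_session
        for _, grp in spikes.groupby("unit_id"):
            assert (np.diff(grp["time_s"].to_numpy()) >= 0).all()

    def test_empty_task_list_rejected(self):
        with pytest.raises(ValueError):
            simulate_session(SimConfig(n_units=1), tasks=[])

    def test_go_phase_spike_counts_match_poisson_mean(self):
        # baseline 20 Hz, zero modulation, 2 s Go: counts ~ Poisson(40)
        dists = GroundTruthDistributions(baseline_hz_range=(20.0, 20.0), md_hz_range=(0.0, 0.0))
        cfg = SimConfig(n_units=1, n_reps_per_config=8, distributions=dists, rng_seed=21)
        spikes, trials, _ = simulate_session(cfg, tasks=["ipsi"])
        t = spikes["time_s"].to_numpy()
        counts = [
            ((t >= r.go_onset_s) & (t < r.rest_onset_s)).sum()
            for r in trials.itertuples()
        ]
        n = len(counts)
        assert n == 64
        sem = np.sqrt(40.0 / n)  # Poisson variance = mean
        assert abs(np.mean(counts) - 40.0) < 3 * sem


class TestPhaseAndGridValidation:
    def test_bad_phase_durations_rejected(self):
        with pytest.raises(ValueError):
            PhaseDurations(prepare_s=(1.5, 1.0))
        with pytest.raises(ValueError):
            PhaseDurations(go_s=0.0)

    def test_bad_grids_rejected(self):
        with pytest.raises(ValueError):
            DirectionGrid(bimanual_dirs_deg=(30.0, 135.0, 225.0, 315.0))  # not a subset
        with pytest.raises(ValueError):
            DirectionGrid(unimanual_dirs_deg=(0.0,) * 8)

    def test_unknown_noise_model_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(noise_model="gamma")


class TestSessionIO:
    def test_round_trip_identity(self, tiny_session, tmp_path):
        spikes, trials, gts = tiny_session
        write_session(spikes, trials, tmp_path / "s", ground_truth=gts)
        spikes2, trials2 = read_session(tmp_path / "s")
        pd.testing.assert_frame_equal(spikes, spikes2)
        pd.testing.assert_frame_equal(trials, trials2)

    def test_empty_spike_table_is_valid(self, tiny_session, tmp_path):
        _, trials, _ = tiny_session
        empty = pd.DataFrame({"unit_id": pd.Series(dtype=str), "time_s": pd.Series(dtype=float)})
        write_session(empty, trials, tmp_path / "s")
        spikes2, _ = read_session(tmp_path / "s")
        assert len(spikes2) == 0

    def test_missing_column_is_parse_error(self, tiny_session, tmp_path):
        spikes, trials, _ = tiny_session
        write_session(spikes, trials.drop(columns=["go_onset_s"]), tmp_path / "s")
        with pytest.raises(SessionFormatError, match="go_onset_s"):
            read_session(tmp_path / "s")

    def test_missing_onset_names_offending_row(self, tiny_session, tmp_path):
        spikes, trials, _ = tiny_session
        bad = trials.copy()
        bad.loc[3, "go_onset_s"] = np.nan
        write_session(spikes, bad, tmp_path / "s")
        with pytest.raises(SessionFormatError, match="row 3"):
            read_session(tmp_path / "s")

    def test_unknown_block_tag_rejected(self, tiny_session, tmp_path):
        spikes, trials, _ = tiny_session
        bad = trials.copy()
        bad.loc[0, "block_type"] = "tripedal"
        write_session(spikes, bad, tmp_path / "s")
        with pytest.raises(SessionFormatError, match="tripedal"):
            read_session(tmp_path / "s")

    def test_unsorted_spikes_rejected(self, tiny_session, tmp_path):
        spikes, trials, _ = tiny_session
        bad = spikes.copy()
        bad.iloc[0, bad.columns.get_loc("time_s")] = 1e9
        write_session(bad, trials, tmp_path / "s")
        with pytest.raises(SessionFormatError, match="time order"):
            read_session(tmp_path / "s")
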