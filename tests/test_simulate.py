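import numpy as np
import pandas as pd
import pytest

from cbci.errors import ParameterError
from cbci.io import CONFIDENCE_GRID, write_trials
from cbci.preprocess import condition_epochs
from cbci.simulate import (
    SimConfig,
    simulate_behaviour,
    simulate_dataset,
    simulate_epochs,
    simulate_frames,
)
from cbci.stats import erp_compare

SMALL = dict(n_participants=4, n_blocks=2, trials_per_block=21,
             fs_raw=64, n_channels=6)


def small_config(**kw):
    return SimConfig(**{**SMALL, **kw})


class TestSimConfig:
    def test_defaults_match_study_layout(self):
        cfg = SimConfig()
        assert cfg.n_blocks * cfg.trials_per_block == 504
        assert cfg.response_deadline_s == 2.5
        assert cfg.conf_deadline_s == 2.0
        assert cfg.frame_rate_hz == 4.0
        assert cfg.fs_raw == 2048.0
        assert cfg.n_channels == 64

    @pytest.mark.parametrize(
        "kw",
        [
            dict(n_participants=0),
            dict(accuracy_range=(0.3, 0.9)),
            dict(fraction_empty=1.0),
            dict(fs_raw=100.0),
            dict(n_channels=3),
            dict(acc_rt_correlation=-2.0),
            dict(rt_lognorm_params=((0.8, 1.2), 0.35)),  # median >= deadline
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ParameterError):
            small_config(**kw)


class TestBehaviour:
    def test_degenerate_accuracy_all_correct(self):
        beh = simulate_behaviour(small_config(accuracy_range=(1.0, 1.0), seed=5))
        for recs in beh.trials.values():
            for r in recs:
                if r.answered:
                    assert r.decision == r.true_label

    def test_determinism_same_seed(self):
        cfg = small_config(seed=7)
        a, b = simulate_behaviour(cfg), simulate_behaviour(cfg)
        assert a.trials == b.trials
        pd.testing.assert_frame_equal(a.schedule, b.schedule)

    def test_different_seed_differs(self):
        a = simulate_behaviour(small_config(seed=1))
        b = simulate_behaviour(small_config(seed=2))
        assert a.trials != b.trials

    def test_empirical_accuracy_within_binomial_tolerance(self):
        cfg = SimConfig(fs_raw=64, n_channels=6, seed=11)  # 336 decision trials
        beh = simulate_behaviour(cfg)
        for _, prow in beh.participants.iterrows():
            recs = [r for r in beh.trials[prow.participant_id] if r.true_label != 0]
            emp = np.mean([r.correctness == "correct" for r in recs])
            n = len(recs)
            tol = 3 * np.sqrt(prow.accuracy * (1 - prow.accuracy) / n)
            assert abs(emp - prow.accuracy) <= tol

    def test_rt_truncated_at_deadline(self):
        beh = simulate_behaviour(small_config(seed=3))
        onset = beh.schedule.set_index("trial_id").onset_s
        for recs in beh.trials.values():
            for r in recs:
                if r.answered:
                    rt = r.response_timestamp_s - onset[r.trial_id]
                    assert 0 < rt < 2.5

    def test_confidence_on_grid_and_higher_when_correct(self):
        beh = simulate_behaviour(small_config(seed=3, n_blocks=8))
        conf_c, conf_i = [], []
        for recs in beh.trials.values():
            for r in recs:
                if r.answered:
                    assert r.reported_confidence in CONFIDENCE_GRID
                    (conf_c if r.correctness == "correct" else conf_i).append(
                        r.reported_confidence
                    )
        assert np.mean(conf_c) > np.mean(conf_i)

    def test_confidence_timestamp_after_response(self):
        beh = simulate_behaviour(small_config(seed=3))
        for recs in beh.trials.values():
            for r in recs:
                if r.answered:
                    assert r.confidence_timestamp_s > r.response_timestamp_s
                    assert (
                        r.confidence_timestamp_s - r.response_timestamp_s <= 2.0
                    )

    def test_accuracy_rt_coupling_sign(self):
        cfg = SimConfig(n_participants=10, fs_raw=64, n_channels=6,
                        acc_rt_correlation=-0.9, seed=21)
        beh = simulate_behaviour(cfg)
        onset = beh.schedule.set_index("trial_id").onset_s
        mean_rts = []
        for pid in beh.participants.participant_id:
            rts = [r.response_timestamp_s - onset[r.trial_id]
                   for r in beh.trials[pid] if r.answered]
            mean_rts.append(np.mean(rts))
        r = np.corrcoef(beh.participants.accuracy, mean_rts)[0, 1]
        assert r < 0

    def test_disappearance_rule_labels_timeouts_incorrect(self):
        cfg = small_config(seed=9, fraction_empty=0.0,
                           disappearance_range_s=(0.2, 0.6), frame_rate_hz=10.0)
        beh = simulate_behaviour(cfg)
        n_timeouts = 0
        for recs in beh.trials.values():
            for r in recs:
                if not r.answered and r.true_label != 0:
                    assert r.correctness == "incorrect"
                    n_timeouts += 1
        assert n_timeouts > 0

    def test_empty_trials_have_no_decision(self):
        beh = simulate_behaviour(small_config(seed=4))
        n_empty = 0
        for recs in beh.trials.values():
            for r in recs:
                if r.true_label == 0:
                    assert not r.answered and r.correctness is None
                    n_empty += 1
        assert n_empty > 0


class TestOnsetRtConsistency:
    def test_exact_identity(self):
        ds = simulate_dataset(small_config(seed=6))
        onset = ds.schedule.set_index("trial_id").onset_s
        for pid, recs in ds.trials.items():
            for r in recs:
                if r.answered:
                    rt = ds.true_rt(pid, r.trial_id)
                    assert r.response_timestamp_s == onset[r.trial_id] + rt

    def test_onsets_only_on_nonempty_trials(self):
        ds = simulate_dataset(small_config(seed=6))
        sched = ds.schedule
        assert sched.loc[sched.true_label == 0, "onset_s"].isna().all()
        assert sched.loc[sched.true_label != 0, "onset_s"].notna().all()


class TestEpochs:
    def test_shape_matches_config(self):
        cfg = small_config(seed=2)
        beh = simulate_behaviour(cfg)
        eps = simulate_epochs(beh.trials, cfg)
        for pid, es in eps.items():
            n_answered = sum(r.answered for r in beh.trials[pid])
            assert es.data.shape == (n_answered, 6, int(round(1.9 * 64)))
            assert es.fs == 64.0

    def test_no_epoch_for_empty_or_missing(self):
        cfg = small_config(seed=2, disappearance_range_s=(0.2, 0.7))
        beh = simulate_behaviour(cfg)
        eps = simulate_epochs(beh.trials, cfg)
        for pid, es in eps.items():
            answered_ids = {r.trial_id for r in beh.trials[pid] if r.answered}
            assert set(es.trial_ids) == answered_ids

    def test_null_effect_mask_below_alpha(self):
        cfg = SimConfig(n_participants=8, n_blocks=4, trials_per_block=30,
                        fraction_empty=0.0, fs_raw=64, n_channels=6,
                        erp_effect=0.0, seed=13)
        ds = simulate_dataset(cfg)
        conditioned = {p: condition_epochs(e) for p, e in ds.epochs.items()}
        res = erp_compare(conditioned, channel="FCz", alpha=0.05)
        assert res.significance_mask.mean() < 0.15

    def test_injected_effect_detected_in_window(self):
        cfg = SimConfig(n_participants=10, n_blocks=5, trials_per_block=40,
                        fraction_empty=0.0, fs_raw=64, n_channels=6,
                        erp_effect=40.0, noise_sd=10.0, seed=13)
        ds = simulate_dataset(cfg)
        conditioned = {p: condition_epochs(e) for p, e in ds.epochs.items()}
        res = erp_compare(conditioned, channel="FCz", alpha=0.05)
        inside = (res.times_ms > -470) & (res.times_ms < -30)
        outside = res.times_ms < -700
        assert res.significance_mask[inside].mean() > 0.85
        assert res.significance_mask[outside].mean() < 0.3


class TestFrames:
    def test_exp1_spacing_250ms(self):
        cfg = small_config(frame_rate_hz=4.0, seed=8)
        frames = simulate_frames(simulate_behaviour(cfg).schedule, cfg)
        for fs in frames.values():
            np.testing.assert_allclose(np.diff(fs.timestamps), 0.25)

    def test_exp2_spacing_100ms(self):
        cfg = small_config(frame_rate_hz=10.0, seed=8)
        frames = simulate_frames(simulate_behaviour(cfg).schedule, cfg)
        for fs in frames.values():
            np.testing.assert_allclose(np.diff(fs.timestamps), 0.1, atol=1e-9)

    def test_noiseless_single_step(self):
        cfg = small_config(frame_jitter_sd=0.0, seed=8)
        beh = simulate_behaviour(cfg)
        frames = simulate_frames(beh.schedule, cfg)
        sched = beh.schedule.set_index("trial_id")
        for tid, fs in frames.items():
            ch = fs.changes()
            if sched.loc[tid, "true_label"] == 0:
                assert np.all(ch == 0.0)
            else:
                above = np.flatnonzero(ch > 1.0)
                assert len(above) == 1
                assert fs.timestamps[above[0] + 1] == pytest.approx(
                    sched.loc[tid, "onset_s"]
                )

    def test_missed_trials_have_small_step(self):
        cfg = small_config(frame_jitter_sd=0.0, fraction_missed=0.5, seed=8)
        beh = simulate_behaviour(cfg)
        frames = simulate_frames(beh.schedule, cfg)
        sched = beh.schedule.set_index("trial_id")
        missed = [t for t in frames if sched.loc[t, "true_label"] != 0
                  and sched.loc[t, "missed"]]
        assert missed
        for tid in missed:
            assert frames[tid].changes().max() < 1.0


class TestDatasetDeterminism:
    def test_serialized_byte_identical(self, tmp_path):
        cfg = small_config(seed=17)
        paths = []
        for run in range(2):
            ds = simulate_dataset(cfg)
            p = tmp_path / f"trials_{run}.csv"
            write_trials([r for recs in ds.trials.values() for r in recs], p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_epoch_and_frame_determinism(self):
        cfg = small_config(seed=17)
        a, b = simulate_dataset(cfg), simulate_dataset(cfg)
        for pid in a.epochs:
            np.testing.assert_array_equal(a.epochs[pid].data, b.epochs[pid].data)
        for tid in a.frames:
            np.testing.assert_array_equal(a.frames[tid].mean_rgb, b.frames[tid].mean_rgb)

    def test_seed_override(self):
        cfg = small_config(seed=17)
        ds = simulate_dataset(cfg, seed=99)
        assert ds.config.seed == 99
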