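"""Paradigm schedule bookkeeping and signal-model guarantees."""

import dataclasses

import numpy as np
import pytest
from scipy.signal import welch

import lmbci
from lmbci.errors import ConfigError
from lmbci.simulate import CONDITIONS, LMI_TYPE, REST_TYPE


def band_power(x, fs, lo, hi):
    f, p = welch(x, fs=fs, nperseg=min(256, x.shape[-1]), axis=-1)
    m = (f >= lo) & (f <= hi)
    return np.trapezoid(p[..., m], f[m], axis=-1).mean()


class TestTrialSchedule:
    def test_paper_parameters_give_192_trials(self):
        schedule = lmbci.build_trial_schedule(lmbci.SimConfig())
        assert len(schedule) == 192
        assert schedule.counts() == {c: 48 for c in CONDITIONS}

    def test_single_run_composition(self):
        cfg = lmbci.SimConfig(n_runs=1)
        schedule = lmbci.build_trial_schedule(cfg)
        assert len(schedule) == 16
        counts = schedule.counts()
        assert sum(counts[c] for c in REST_TYPE) == 8
        assert sum(counts[c] for c in LMI_TYPE) == 8

    def test_per_run_composition_and_spacing(self):
        cfg = lmbci.SimConfig(n_runs=3)
        schedule = lmbci.build_trial_schedule(cfg)
        for run in range(3):
            conds = [t.condition for t in schedule.trials if t.run_index == run]
            assert sum(c in REST_TYPE for c in conds) == 8
            assert sum(c in LMI_TYPE for c in conds) == 8
        onsets = np.array([t.cue_onset_time for t in schedule.trials])
        assert np.all(np.diff(onsets) >= cfg.trial_s - 1e-12)

    def test_schedule_determinism(self):
        cfg = lmbci.SimConfig(rng_seed=42)
        a = lmbci.build_trial_schedule(cfg)
        b = lmbci.build_trial_schedule(cfg)
        assert [t.condition for t in a.trials] == [t.condition for t in b.trials]
        c = lmbci.build_trial_schedule(dataclasses.replace(cfg, rng_seed=43))
        assert [t.condition for t in a.trials] != [t.condition for t in c.trials]
        assert a.counts() == c.counts()

    @pytest.mark.parametrize("bad", [
        {"n_runs": 0},
        {"trials_per_condition_per_run": {c: 0 for c in CONDITIONS}},
        {"montage": ("Cz",) * 16},
        {"fs": 50.0},
        {"erd_depth": {"rest": {}, "V-rest": {}, "no-LMI": {"Cz": 1.0}, "KI-LMI": {}}},
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigError):
            lmbci.build_trial_schedule(lmbci.SimConfig(**bad))


class TestSynthesis:
    def test_byte_identical_under_fixed_seed(self, tiny_cfg):
        a = lmbci.synthesize_session(tiny_cfg)
        b = lmbci.synthesize_session(tiny_cfg)
        assert a.data.tobytes() == b.data.tobytes()

    def test_power_conservation_without_erd(self):
        # no modulation anywhere: task and baseline band power agree < 5 %
        depth = {c: {} for c in CONDITIONS}
        cfg = lmbci.SimConfig(n_runs=8, fs=160.0, rng_seed=21, erd_depth=depth)
        epochs = lmbci.extract_epochs(lmbci.synthesize_session(cfg))
        cz = cfg.montage.index("Cz")
        pb = band_power(epochs.baseline[:, cz, :], 160.0, 8, 30)
        pt = band_power(epochs.task[:, cz, :], 160.0, 8, 30)
        assert epochs.n_trials >= 100
        assert abs(pt / pb - 1) < 0.05

    def test_task_power_monotone_in_depth(self):
        powers = []
        for d in (0.0, 0.15, 0.3, 0.45):
            depth = {c: {} for c in CONDITIONS}
            depth["no-LMI"] = {"Cz": d}
            cfg = lmbci.SimConfig(n_runs=4, fs=160.0, rng_seed=8, erd_depth=depth)
            epochs = lmbci.extract_epochs(lmbci.synthesize_session(cfg))
            idx = epochs.condition_indices("no-LMI")
            cz = cfg.montage.index("Cz")
            powers.append(band_power(epochs.task[idx][:, cz, :], 160.0, 8, 30))
        assert all(a > b for a, b in zip(powers, powers[1:]))

    def test_injected_depth_matches_welch_ratio(self):
        # ~200 modulated trials per session; ratio averaged over three
        # sessions since a single session's band-power ratio has ~5 % SD
        ratios = []
        for seed in (2, 3, 9):
            depth = {c: {} for c in CONDITIONS}
            depth["no-LMI"] = {"Cz": 0.3}
            cfg = lmbci.SimConfig(
                n_runs=16, fs=160.0, rng_seed=seed, erd_depth=depth,
                trials_per_condition_per_run={
                    "rest": 1, "V-rest": 1, "KI-LMI": 1, "no-LMI": 13,
                },
            )
            epochs = lmbci.extract_epochs(lmbci.synthesize_session(cfg))
            idx = epochs.condition_indices("no-LMI")
            assert len(idx) >= 200
            cz = cfg.montage.index("Cz")
            pb = band_power(epochs.baseline[idx][:, cz, :], 160.0, 8, 13)
            pt = band_power(epochs.task[idx][:, cz, :], 160.0, 8, 13)
            ratios.append(pt / pb)
        assert np.mean(ratios) == pytest.approx(0.7, abs=0.05)


class TestArtifacts:
    def test_rate_zero_is_identity(self, tiny_cfg):
        session = lmbci.synthesize_session(tiny_cfg)
        out = lmbci.inject_artifacts(session, 0.0, 300.0, rng_seed=1)
        assert np.array_equal(out.data, session.data)
        assert out.artifact_trials == []

    def test_rate_one_flags_every_trial_downstream(self, tiny_cfg):
        session = lmbci.synthesize_session(tiny_cfg)
        out = lmbci.inject_artifacts(session, 1.0, 300.0, rng_seed=1)
        assert sorted(out.artifact_trials) == list(range(len(session.schedule)))
        epochs = lmbci.reject_artifacts(lmbci.extract_epochs(out), 200.0)
        assert epochs.artifact_flags.all()
        # input session untouched
        assert not np.array_equal(out.data, session.data)

    def test_affected_count_binomial_and_reproducible(self, default_session):
        _, session = default_session
        counts = [
            len(lmbci.inject_artifacts(session, 0.5, 300.0, rng_seed=s).artifact_trials)
            for s in range(50)
        ]
        again = lmbci.inject_artifacts(session, 0.5, 300.0, rng_seed=0)
        assert len(again.artifact_trials) == counts[0]
        # mean of 50 draws from Binomial(192, .5): SE ~ 1; allow 4 SE
        assert abs(np.mean(counts) - 96) < 4.0

    def test_invalid_rate_rejected(self, tiny_cfg):
        session = lmbci.synthesize_session(tiny_cfg)
        with pytest.raises(ConfigError):
            lmbci.inject_artifacts(session, 1.5, 300.0, rng_seed=0)
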