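"""ERD arithmetic: instantaneous power, time courses, summaries."""

import numpy as np
import pytest

import lmbci
from lmbci.erd import (
    PowerSeries,
    compute_erd,
    emin_and_arrival,
    erd_mean,
    erd_timecourse,
    instantaneous_power,
    relative_power_db,
)
from lmbci.errors import ConfigError, DegenerateInputError

FS = 160.0


def sinusoid(freq, amp, n, fs=FS, phase=0.0):
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestInstantaneousPower:
    def test_in_band_sinusoid_recovers_half_amplitude_squared(self):
        x = sinusoid(10.0, 2.0, 1600)[None, None, :]
        ps = instantaneous_power(x, FS, (8, 13))
        mid = ps.power[0, 0, 400:1200]
        assert mid.mean() == pytest.approx(2.0, rel=0.02)  # A^2/2 = 2

    def test_out_of_band_tone_rejected(self):
        x = sinusoid(50.0, 2.0, 1600)[None, None, :]
        ps = instantaneous_power(x, FS, (8, 13))
        assert ps.power[0, 0, 400:1200].mean() < 2e-3

    def test_longer_window_same_mean_lower_variance(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((1, 1, 80000))
        short = instantaneous_power(x, FS, (8, 30), window_s=0.25)
        long = instantaneous_power(x, FS, (8, 30), window_s=0.5)
        ps_s = short.power[0, 0, short.valid]
        ps_l = long.power[0, 0, long.valid]
        assert ps_l.mean() == pytest.approx(ps_s.mean(), rel=0.02)
        assert ps_l.var() < ps_s.var()

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ConfigError):
            instantaneous_power(np.zeros((1, 1, 160)), FS, (8, 90))


def make_series(power, fs=FS):
    power = np.asarray(power, dtype=float)
    return PowerSeries(power=power, fs=fs, band=(8, 13), window_s=0.25,
                       valid=slice(0, power.shape[-1]))


class TestTimecourse:
    def test_equal_power_gives_zero_erd(self):
        p = make_series(np.full((5, 2, 100), 3.0))
        base = make_series(np.full((5, 2, 40), 3.0))
        erd_t, pb = erd_timecourse(p, base)
        np.testing.assert_allclose(erd_t, 0.0)
        np.testing.assert_allclose(pb, 3.0)

    def test_half_power_gives_minus_fifty(self):
        p = make_series(np.full((5, 2, 100), 1.5))
        base = make_series(np.full((5, 2, 40), 3.0))
        erd_t, _ = erd_timecourse(p, base)
        np.testing.assert_allclose(erd_t, -50.0)

    def test_zero_baseline_is_degenerate(self):
        p = make_series(np.ones((5, 2, 100)))
        base = make_series(np.zeros((5, 2, 40)))
        with pytest.raises(DegenerateInputError):
            erd_timecourse(p, base)

    def test_mean_erd_trivial_cases(self):
        base = make_series(np.full((4, 1, 40), 2.0))
        assert erd_mean(make_series(np.full((4, 1, 90), 2.0)), base)[0] == pytest.approx(0.0)
        assert erd_mean(make_series(np.full((4, 1, 90), 1.4)), base)[0] == pytest.approx(-30.0)

    def test_plateau_matches_welch_oracle_on_same_data(self):
        # injected 30 % alpha power drop at Cz on a ~200-trial session;
        # the ERD(t) plateau must agree with a Welch power-ratio oracle
        # computed on the same trials at matched (1 s) resolution
        from scipy.signal import welch

        depth = {c: {} for c in ("rest", "V-rest", "no-LMI", "KI-LMI")}
        depth["no-LMI"] = {"Cz": 0.3}
        cfg = lmbci.SimConfig(
            n_runs=16, fs=FS, rng_seed=6, erd_depth=depth,
            trials_per_condition_per_run={
                "rest": 1, "V-rest": 1, "KI-LMI": 1, "no-LMI": 13,
            },
        )
        epochs = lmbci.extract_epochs(lmbci.synthesize_session(cfg))
        r = compute_erd(epochs, "no-LMI", "alpha")
        cz = r.channel("Cz")
        plateau = r.erd_t[cz].mean()
        idx = epochs.condition_indices("no-LMI")
        assert len(idx) >= 200

        def wp(x):
            f, p = welch(x, fs=FS, nperseg=160, axis=-1)
            m = (f >= 8) & (f <= 13)
            return np.trapezoid(p[..., m], f[m], axis=-1).mean()

        oracle = (wp(epochs.task[idx][:, cz, :]) / wp(epochs.baseline[idx][:, cz, :])
                  - 1) * 100
        assert plateau == pytest.approx(oracle, abs=5.0)

    def test_mean_erd_consistent_with_timecourse_average(self, default_epochs):
        # interior of the grid (edge-truncated smoothing windows removed):
        # exact identity; full grid: only edge effects, ~1 pp
        r = compute_erd(default_epochs, "KI-LMI", "alpha+beta")
        half = int(0.25 * default_epochs.fs) // 2
        np.testing.assert_allclose(
            r.erd_t[:, half:-half].mean(axis=1), r.erd_mean, atol=1e-9)
        np.testing.assert_allclose(r.erd_t.mean(axis=1), r.erd_mean, atol=1.5)

    def test_erd_bounded_below_by_minus_hundred(self, default_epochs):
        for cond in ("rest", "no-LMI", "KI-LMI"):
            r = compute_erd(default_epochs, cond, "alpha+beta")
            assert r.erd_t.min() >= -100.0

    def test_trial_average_precedes_normalization(self, default_epochs):
        # normalizing each trial by its own noisy baseline then averaging
        # is a different (positively biased) estimator; guard the order
        from lmbci.erd import _window_series

        idx = default_epochs.condition_indices("no-LMI")
        base, task = _window_series(default_epochs, idx, (8.0, 30.0), 0.25)
        cz = default_epochs.montage.index("Cz")
        pooled = compute_erd(default_epochs, "no-LMI", "alpha+beta").erd_mean[cz]
        per_trial_pb = base.power[:, cz, :].mean(axis=1)
        per_trial_pt = task.power[:, cz, :].mean(axis=1)
        per_trial = ((per_trial_pt - per_trial_pb) / per_trial_pb * 100).mean()
        assert per_trial != pytest.approx(pooled, abs=1.0)
        assert per_trial > pooled  # Jensen: E[1/x] > 1/E[x]


class TestSummaries:
    def test_emin_and_arrival_on_monotone_ramp(self):
        times = np.linspace(0, 2, 201)
        trace = np.linspace(0, -40, 201)
        e_min, t_arr = emin_and_arrival(trace, times, reference=-40.0)
        assert e_min == -40.0
        assert t_arr == 2.0
        e_min, t_arr = emin_and_arrival(trace, times, reference="self-min")
        assert t_arr == 2.0

    def test_reference_never_reached_gives_sentinel(self):
        times = np.linspace(0, 2, 50)
        e_min, t_arr = emin_and_arrival(np.zeros(50), times, reference=-10.0)
        assert e_min == 0.0
        assert np.isnan(t_arr)

    def test_relative_power_db_identity_and_ratio(self, narrowband_epochs_factory):
        rng = np.random.default_rng(3)
        from lmbci.filters import bandpass_filter

        s = bandpass_filter(rng.standard_normal((10, 4, 480)), (8, 13), FS)
        task = np.concatenate([s, np.sqrt(2.0) * s])  # cond B has 2x power
        labels = np.array(["no-LMI"] * 10 + ["rest"] * 10, dtype="U8")
        epochs = narrowband_epochs_factory(task, labels=labels)
        t, db_self = relative_power_db(epochs, "rest", "rest", band="alpha")
        np.testing.assert_allclose(db_self, 0.0, atol=1e-12)
        _, db = relative_power_db(epochs, "no-LMI", "rest", band="alpha")
        np.testing.assert_allclose(db, 10 * np.log10(0.5), atol=1e-9)

    def test_db_closed_form_scale(self):
        assert 10 * np.log10(10 ** (-2.1)) == pytest.approx(-21.0)

    def test_db_against_own_baseline(self, narrowband_epochs_factory):
        from lmbci.filters import bandpass_filter

        rng = np.random.default_rng(5)
        s = bandpass_filter(rng.standard_normal((10, 2, 480)), (8, 13), FS)
        # baseline power = 2x task power -> -3.01 dB against own baseline
        epochs = narrowband_epochs_factory(
            s, baseline=np.sqrt(2.0) * s[:, :, :160],
            labels=np.array(["rest"] * 10, dtype="U8"))
        _, db = relative_power_db(epochs, "rest", None, band="alpha")
        assert np.median(db) == pytest.approx(10 * np.log10(0.5), abs=0.35)
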