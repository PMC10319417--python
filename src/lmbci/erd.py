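"""Event-related desynchronization (ERD) time courses and summaries.

The classical band-power ERD pipeline: band-pass filter every trial,
square the samples to obtain instantaneous power, average power across
trials, smooth with a 0.25 s moving window, and express task-window
power relative to the pre-task baseline:

    P_base = mean of P(t) over the baseline window
    P_task = mean of P(t) over the task window
    ERD(t) = (P(t) - P_base) / P_base * 100        [%]
    mean ERD = (P_task - P_base) / P_base * 100    [%]

Negative values are desynchronization (power drop); the scale is
bounded below by -100 % since power is nonnegative.  The trial-average
is taken BEFORE baseline normalization — normalizing each trial by its
own noisy baseline first gives a different (positively biased) result.

Also provided: the minimum of the ERD time course in the task window
(E_min), the arrival time T to reach a reference ERD level, and a
decibel relative-power time course of one condition against a reference
condition (10*log10 power ratio) for condition-contrast plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from lmbci.errors import ConfigError, DegenerateInputError
from lmbci.filters import bandpass_filter
from lmbci.preprocessing import BASELINE_WINDOW, TASK_WINDOW, EpochSet

#: Canonical analysis bands (Hz).
BANDS: dict[str, tuple[float, float]] = {
    "alpha": (8.0, 13.0),
    "beta": (14.0, 30.0),
    "alpha+beta": (8.0, 30.0),
}

#: Sentinel for an arrival time whose reference level is never reached.
NOT_REACHED = float("nan")


@dataclass
class PowerSeries:
    """Per-trial instantaneous band power on the moving-window grid.

    ``power`` has shape (n_trials, n_channels, n_samples); ``valid`` is
    the slice of samples whose smoothing window lies fully inside the
    segment (edge-truncated windows are excluded from averages).
    """

    power: np.ndarray
    fs: float
    band: tuple[float, float]
    window_s: float
    valid: slice

    def trial_average(self, mask: np.ndarray | None = None) -> np.ndarray:
        p = self.power if mask is None else self.power[mask]
        return p.mean(axis=0)


def instantaneous_power(
    data: np.ndarray,
    fs: float,
    band: tuple[float, float],
    window_s: float = 0.25,
) -> PowerSeries:
    """Band-pass, square, and smooth with a centered moving window.

    ``data`` is (n_trials, n_channels, n_samples).  The hop is one
    sample (dense grid); downsample afterwards for plotting if desired.
    """
    if band[1] >= fs / 2:
        raise ConfigError(f"band {band} exceeds Nyquist ({fs / 2} Hz)")
    filtered = bandpass_filter(np.asarray(data, dtype=float), band, fs)
    power = filtered**2
    n_win = max(int(round(window_s * fs)), 1)
    smoothed = uniform_filter1d(power, size=n_win, axis=-1, mode="nearest")
    half = n_win // 2
    n = power.shape[-1]
    valid = slice(half, n - (n_win - 1 - half))
    return PowerSeries(power=smoothed, fs=fs, band=band, window_s=window_s, valid=valid)


@dataclass
class ERDResult:
    """Trial-averaged ERD for one condition and one band."""

    band_name: str
    band: tuple[float, float]
    condition: str
    montage: tuple[str, ...]
    times: np.ndarray  # s relative to task onset, task-window grid
    erd_t: np.ndarray  # (n_channels, n_times), %
    erd_mean: np.ndarray  # (n_channels,), %
    p_base: np.ndarray  # (n_channels,), uV^2
    p_task: np.ndarray  # (n_channels,), uV^2
    n_trials: int

    def channel(self, label: str) -> int:
        return self.montage.index(label)

    def emin(self, channel: str) -> float:
        return float(self.erd_t[self.channel(channel)].min())

    def topography(self) -> list[tuple[str, float]]:
        """(channel label, mean ERD %) pairs for any standard plotting tool."""
        return list(zip(self.montage, self.erd_mean.tolist()))


def erd_timecourse(
    power: PowerSeries,
    baseline_power: PowerSeries,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """ERD(t) in % on the task grid, and P_base per channel.

    ``power`` holds the task-window series, ``baseline_power`` the
    baseline-window series of the same trials.  Trial averaging happens
    first; the baseline is the time-average of the trial-averaged
    baseline power over its valid grid.
    """
    pb = baseline_power.trial_average(mask)[:, baseline_power.valid].mean(axis=1)
    if np.any(pb <= 0):
        raise DegenerateInputError("baseline power is zero on some channel")
    pt = power.trial_average(mask)
    erd_t = (pt - pb[:, None]) / pb[:, None] * 100.0
    return erd_t, pb


def erd_mean(
    power: PowerSeries,
    baseline_power: PowerSeries,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Mean task-window ERD in % per channel (scalar summary)."""
    pb = baseline_power.trial_average(mask)[:, baseline_power.valid].mean(axis=1)
    if np.any(pb <= 0):
        raise DegenerateInputError("baseline power is zero on some channel")
    pt = power.trial_average(mask)[:, power.valid].mean(axis=1)
    return (pt - pb) / pb * 100.0


def _window_series(
    epochs: EpochSet,
    idx: np.ndarray,
    band_edges: tuple[float, float],
    window_s: float,
) -> tuple[PowerSeries, PowerSeries]:
    """Baseline- and task-window power series, filtered edge-safely.

    When the epoch set carries a margin-padded continuous segment, the
    filter and the moving window run over it and the analysis windows
    are sliced out afterwards, so IIR edge transients stay in the
    margins; otherwise falls back to filtering the cut windows.
    """
    fs = epochs.fs
    if epochs.segment is not None:
        seg = instantaneous_power(epochs.segment[idx], fs, band_edges, window_s)
        # half a smoothing window at each end of a window mixes in
        # out-of-window signal (e.g. the ERD onset ramp); exclude it
        # from window averages, as for edge-truncated windows
        half = max(int(round(window_s * fs)), 1) // 2

        def cut(window: tuple[float, float]) -> PowerSeries:
            a = int(round((window[0] - epochs.segment_tmin) * fs))
            n = int(round((window[1] - window[0]) * fs))
            return PowerSeries(power=seg.power[..., a:a + n], fs=fs,
                               band=band_edges, window_s=window_s,
                               valid=slice(half, n - half))

        return cut(BASELINE_WINDOW), cut(TASK_WINDOW)
    base = instantaneous_power(epochs.baseline[idx], fs, band_edges, window_s)
    task = instantaneous_power(epochs.task[idx], fs, band_edges, window_s)
    return base, task


def compute_erd(
    epochs: EpochSet,
    condition: str,
    band: str | tuple[float, float] = "alpha+beta",
    window_s: float = 0.25,
) -> ERDResult:
    """Full ERD analysis of one condition's clean trials."""
    if isinstance(band, str):
        band_name, band_edges = band, BANDS[band]
    else:
        band_name, band_edges = f"{band[0]:g}-{band[1]:g}Hz", tuple(band)
    idx = epochs.condition_indices(condition)
    if len(idx) == 0:
        raise DegenerateInputError(f"no clean trials for condition {condition!r}")
    base, task = _window_series(epochs, idx, band_edges, window_s)
    erd_t, pb = erd_timecourse(task, base)
    pt = task.trial_average()[:, task.valid].mean(axis=1)
    erd_bar = (pt - pb) / pb * 100.0
    n = task.power.shape[-1]
    times = TASK_WINDOW[0] + np.arange(n) / epochs.fs
    return ERDResult(
        band_name=band_name, band=band_edges, condition=condition,
        montage=epochs.montage, times=times, erd_t=erd_t, erd_mean=erd_bar,
        p_base=pb, p_task=pt, n_trials=len(idx),
    )


def emin_and_arrival(
    erd_t: np.ndarray,
    times: np.ndarray,
    reference: float | str = "self-min",
) -> tuple[float, float]:
    """Deepest ERD and the time to first reach a reference level.

    ``reference='self-min'`` uses the trace's own minimum, so the
    arrival time is the argmin time (the convention for the baseline
    condition); pass another trace's E_min to measure how quickly this
    trace descends to it.  Returns (e_min, t_arrival); the arrival time
    is the NOT_REACHED sentinel (NaN) when the level is never attained.
    """
    erd_t = np.asarray(erd_t, dtype=float)
    e_min = float(erd_t.min())
    ref = e_min if reference == "self-min" else float(reference)
    hits = np.flatnonzero(erd_t <= ref)
    t_arrival = float(times[hits[0]]) if len(hits) else NOT_REACHED
    return e_min, t_arrival


def relative_power_db(
    epochs: EpochSet,
    condition: str,
    reference_condition: str | None,
    band: str | tuple[float, float] = "alpha",
    window_s: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Decibel power of one condition against a reference.

    10*log10 of the ratio of the trial-averaged, moving-window-smoothed
    task power series — the grand-average "relative power" view of a
    condition contrast.  ``reference_condition=None`` uses the
    condition's own baseline power as the (time-constant) denominator.
    Returns (times, db) with db per channel.
    """
    band_edges = BANDS[band] if isinstance(band, str) else tuple(band)
    ia = epochs.condition_indices(condition)
    if len(ia) == 0:
        raise DegenerateInputError("condition needs at least one clean trial")
    base_a, pa = _window_series(epochs, ia, band_edges, window_s)
    num = pa.trial_average()
    if reference_condition is None:
        pb = base_a.trial_average()[:, base_a.valid].mean(axis=1)
        den = np.broadcast_to(pb[:, None], num.shape)
    else:
        ib = epochs.condition_indices(reference_condition)
        if len(ib) == 0:
            raise DegenerateInputError("reference condition has no clean trials")
        _, pref = _window_series(epochs, ib, band_edges, window_s)
        den = pref.trial_average()
    if np.any(num <= 0) or np.any(den <= 0):
        raise DegenerateInputError("nonpositive power in dB computation")
    n = num.shape[-1]
    times = TASK_WINDOW[0] + np.arange(n) / epochs.fs
    return times, 10.0 * np.log10(num / den)


def erd_to_frame(result: ERDResult):
    """Tidy (channel, band, time, erd_percent) DataFrame for CSV export."""
    import pandas as pd

    n_ch, n_t = result.erd_t.shape
    return pd.DataFrame({
        "channel": np.repeat(result.montage, n_t),
        "band": result.band_name,
        "condition": result.condition,
        "time_s": np.tile(result.times, n_ch),
        "erd_percent": result.erd_t.ravel(),
    })


def summary_to_frame(results: list[ERDResult]):
    """Per-channel mean-ERD summary across conditions/bands."""
    import pandas as pd

    rows = []
    for r in results:
        for ch, val in r.topography():
            rows.append({
                "channel": ch, "band": r.band_name, "condition": r.condition,
                "erd_mean_percent": val, "n_trials": r.n_trials,
            })
    return pd.DataFrame(rows)
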