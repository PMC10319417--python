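"""Epoching, peak-to-peak artifact rejection and trial subsampling.

Analysis windows are fixed relative to the task onset (t = 0): the
baseline is the final second of the fixation-cross period
(-2.5 .. -1.5 s), when subjects are most relaxed, and the task segment
is 0.5 .. 3.5 s — the first half second after the cue is skipped
because it is dominated by cue-related transients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from lmbci.errors import ConfigError, InsufficientTrialsError
from lmbci.simulate import CONDITIONS, RawSession

log = logging.getLogger(__name__)

BASELINE_WINDOW = (-2.5, -1.5)  # s, relative to task onset
TASK_WINDOW = (0.5, 3.5)
SEGMENT_MARGIN = 0.5  # s of context kept either side for edge-safe filtering


@dataclass
class EpochSet:
    """Baseline/task-windowed trials with labels and artifact flags.

    ``baseline`` and ``task`` are (n_trials, n_channels, n_samples)
    arrays in uV.  ``segment`` is the continuous stretch spanning both
    windows plus a margin either side; band-limited power estimates
    filter the segment and slice the analysis windows out afterwards so
    IIR edge transients never land inside a window.  ``artifact_flags``
    marks trials excluded from every downstream computation; flagged
    trials are retained in the arrays so rejection is auditable rather
    than silent.
    """

    baseline: np.ndarray
    task: np.ndarray
    labels: np.ndarray  # condition per trial (str)
    artifact_flags: np.ndarray  # bool per trial
    fs: float
    montage: tuple[str, ...]
    trial_ids: np.ndarray = field(default=None)  # session-level trial indices
    flag_reasons: dict[int, str] = field(default_factory=dict)
    segment: np.ndarray | None = None  # (n_trials, n_ch, n), margin-padded
    segment_tmin: float = BASELINE_WINDOW[0] - SEGMENT_MARGIN  # s re task onset

    def __post_init__(self):
        if self.trial_ids is None:
            self.trial_ids = np.arange(len(self.labels))

    @property
    def n_trials(self) -> int:
        return self.baseline.shape[0]

    def clean_mask(self) -> np.ndarray:
        return ~self.artifact_flags

    def condition_indices(self, condition: str, clean_only: bool = True) -> np.ndarray:
        mask = self.labels == condition
        if clean_only:
            mask &= self.clean_mask()
        return np.flatnonzero(mask)

    def select(self, indices: np.ndarray) -> "EpochSet":
        """New EpochSet restricted to the given trial positions."""
        indices = np.asarray(indices)
        return EpochSet(
            baseline=self.baseline[indices].copy(),
            task=self.task[indices].copy(),
            labels=self.labels[indices].copy(),
            artifact_flags=self.artifact_flags[indices].copy(),
            fs=self.fs,
            montage=self.montage,
            trial_ids=self.trial_ids[indices].copy(),
            flag_reasons={
                i: r for i, r in self.flag_reasons.items()
                if i in set(self.trial_ids[indices].tolist())
            },
            segment=None if self.segment is None else self.segment[indices].copy(),
            segment_tmin=self.segment_tmin,
        )


def _window_slice(t0: float, window: tuple[float, float], fs: float) -> tuple[int, int]:
    """Half-open sample range [start, stop) for a window relative to t0 (s)."""
    start = int(round((t0 + window[0]) * fs))
    stop = start + int(round((window[1] - window[0]) * fs))
    return start, stop


def extract_epochs(
    session: RawSession,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    task_window: tuple[float, float] = TASK_WINDOW,
) -> EpochSet:
    """Cut one (baseline, task) epoch pair per scheduled trial.

    Windows are half-open in samples, time-locked to the task onset.
    A trial whose windows fall outside the recording is flagged (reason
    ``out_of_bounds``) and filled with zeros rather than dropped, so the
    trial count always matches the schedule.
    """
    fs = session.fs
    sched = session.schedule
    n_trials = len(sched)
    seg_window = (baseline_window[0] - SEGMENT_MARGIN, task_window[1] + SEGMENT_MARGIN)
    nb = int(round((baseline_window[1] - baseline_window[0]) * fs))
    nt = int(round((task_window[1] - task_window[0]) * fs))
    ns = int(round((seg_window[1] - seg_window[0]) * fs))
    baseline = np.zeros((n_trials, len(session.montage), nb))
    task = np.zeros((n_trials, len(session.montage), nt))
    segment = np.zeros((n_trials, len(session.montage), ns))
    labels = np.empty(n_trials, dtype=object)
    flags = np.zeros(n_trials, dtype=bool)
    reasons: dict[int, str] = {}
    for k, trial in enumerate(sched.trials):
        t0 = sched.task_onset(trial)
        b0, b1 = _window_slice(t0, baseline_window, fs)
        s0, s1 = _window_slice(t0, task_window, fs)
        g0, g1 = _window_slice(t0, seg_window, fs)
        labels[k] = trial.condition
        if b0 < 0 or s1 > session.n_samples:
            flags[k] = True
            reasons[trial.trial_index] = "out_of_bounds"
            log.warning("trial %d windows outside recording; flagged", trial.trial_index)
            continue
        baseline[k] = session.data[:, b0:b1]
        task[k] = session.data[:, s0:s1]
        # margins may poke past the recording ends; clamp, windows stay intact
        c0, c1 = max(g0, 0), min(g1, session.n_samples)
        segment[k, :, c0 - g0:c0 - g0 + (c1 - c0)] = session.data[:, c0:c1]
    labels = np.asarray(labels.tolist(), dtype="U8")
    return EpochSet(
        baseline=baseline, task=task, labels=labels, artifact_flags=flags,
        fs=fs, montage=session.montage,
        trial_ids=np.asarray([t.trial_index for t in sched.trials]),
        flag_reasons=reasons,
        segment=segment, segment_tmin=seg_window[0],
    )


def reject_artifacts(
    epochs: EpochSet,
    p2p_threshold: float = 200.0,
    predicate=None,
) -> EpochSet:
    """Flag trials whose peak-to-peak amplitude exceeds the threshold.

    A trial is flagged when ANY electrode's peak-to-peak value in either
    the baseline or the task window is strictly greater than
    ``p2p_threshold`` (uV); a value exactly at the threshold passes.
    ``predicate(baseline, task) -> bool`` is an optional extra criterion
    evaluated per trial on the (n_channels, n_samples) windows — a hook
    for rejection rules (e.g. muscle-artifact heuristics) that have no
    closed amplitude form.  Idempotent; returns a new EpochSet.
    """
    if p2p_threshold <= 0:
        raise ConfigError("p2p threshold must be positive")
    p2p_base = epochs.baseline.max(axis=2) - epochs.baseline.min(axis=2)
    p2p_task = epochs.task.max(axis=2) - epochs.task.min(axis=2)
    p2p = np.maximum(p2p_base, p2p_task).max(axis=1)  # worst electrode per trial
    new_flags = p2p > p2p_threshold
    reasons = dict(epochs.flag_reasons)
    for k in np.flatnonzero(new_flags & ~epochs.artifact_flags):
        reasons[int(epochs.trial_ids[k])] = f"p2p {p2p[k]:.1f} uV > {p2p_threshold:g} uV"
    if predicate is not None:
        for k in range(epochs.n_trials):
            if not new_flags[k] and predicate(epochs.baseline[k], epochs.task[k]):
                new_flags[k] = True
                reasons.setdefault(int(epochs.trial_ids[k]), "custom predicate")
    n_new = int((new_flags & ~epochs.artifact_flags).sum())
    log.info("artifact rejection: %d newly flagged of %d trials", n_new, epochs.n_trials)
    return replace(
        epochs,
        baseline=epochs.baseline.copy(),
        task=epochs.task.copy(),
        labels=epochs.labels.copy(),
        artifact_flags=epochs.artifact_flags | new_flags,
        flag_reasons=reasons,
    )


def subsample_trials(
    epochs: EpochSet,
    n_per_condition: int,
    rng_seed: int,
    conditions: tuple[str, ...] = CONDITIONS,
) -> EpochSet:
    """Uniform random selection of n clean trials per condition.

    Mirrors the study's step of drawing a fixed number (40) of artifact
    free trials per task before feature extraction.  Raises
    InsufficientTrialsError naming the condition when fewer clean trials
    are available than requested.
    """
    if n_per_condition <= 0:
        raise ConfigError("n_per_condition must be positive")
    rng = np.random.default_rng(rng_seed)
    keep: list[np.ndarray] = []
    for cond in conditions:
        idx = epochs.condition_indices(cond)
        if len(idx) < n_per_condition:
            raise InsufficientTrialsError(cond, len(idx), n_per_condition)
        chosen = rng.choice(idx, size=n_per_condition, replace=False)
        keep.append(np.sort(chosen))
    order = np.sort(np.concatenate(keep))
    return epochs.select(order)
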