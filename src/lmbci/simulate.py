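"""Synthetic four-condition sensorimotor EEG sessions.

The simulator emulates a cue-based lower-limb motor-imagery experiment:
each run interleaves rest-type trials (``rest``, ``V-rest``) with
imagery-type trials (``no-LMI``, ``KI-LMI``), and every trial follows a
fixation-cross / cue / task / relax timeline.  Channels carry a 1/f
background plus narrowband alpha (8-13 Hz) and beta (14-30 Hz)
processes.  During the task window of a trial the narrowband amplitude
at configured channels is attenuated by ``sqrt(1 - depth)`` — i.e. band
power drops by the fractional ``erd_depth`` — after a linear onset ramp
of ``erd_latency`` seconds, which is the event-related
desynchronization (ERD) the downstream analysis estimates.

The signal model is deliberately minimal: it produces valid ERD
percentages, imaginary-coherence structure (via an optional lagged
shared source) and CSP-discriminable covariance contrasts, without
attempting biophysical realism (no volume conduction, no realistic
ocular/muscle artifact morphology).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from lmbci.errors import ConfigError
from lmbci.filters import bandpass_filter

CONDITIONS = ("rest", "V-rest", "no-LMI", "KI-LMI")
REST_TYPE = ("rest", "V-rest")
LMI_TYPE = ("no-LMI", "KI-LMI")

#: 10-10 sensorimotor grid: frontocentral, central and centroparietal rows.
DEFAULT_MONTAGE = (
    "FC3", "FC1", "FCz", "FC2", "FC4",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP3", "CP1", "CPz", "CP2",
)

#: Default band-power drop per condition and channel (fraction in [0, 1)).
#: Imagery conditions desynchronize the mesial sensorimotor channels, the
#: illusion-assisted condition more deeply and with contralateral spread;
#: vibration alone produces only a slight drop around Cz/CPz; rest none.
DEFAULT_ERD_DEPTH: dict[str, dict[str, float]] = {
    "rest": {},
    "V-rest": {"Cz": 0.05, "CPz": 0.05},
    "no-LMI": {"Cz": 0.30, "CPz": 0.25, "C1": 0.20, "C2": 0.20},
    "KI-LMI": {
        "Cz": 0.45, "CPz": 0.40, "C1": 0.30, "C2": 0.25,
        "C3": 0.25, "C5": 0.20, "CP3": 0.20, "FC1": 0.15, "FC3": 0.15,
    },
}

ALPHA = (8.0, 13.0)
BETA = (14.0, 30.0)


@dataclass(frozen=True)
class LaggedCoupling:
    """Optional shared narrowband source with a transmission delay.

    Injected into two channels during the task window of the listed
    conditions, one copy delayed by ``lag_s`` — this creates a genuinely
    time-lagged interaction that the imaginary part of coherency detects
    while remaining blind to instantaneous (volume-conducted) mixing.
    """

    channel_a: str = "C3"
    channel_b: str = "FC3"
    gain: float = 5.0  # source RMS amplitude in uV added to each channel
    lag_s: float = 0.025  # ~quarter period of a 10 Hz rhythm
    band: tuple[float, float] = ALPHA
    conditions: tuple[str, ...] = ("KI-LMI",)


@dataclass
class SimConfig:
    """Parameters of one synthetic session.

    Defaults reproduce the study paradigm: 12 runs of 16 trials
    (8 rest-type + 8 imagery-type, equal per-condition splits), 16
    sensorimotor channels sampled at 1200 Hz, with the trial timeline
    cross 2 s -> cue 1 s -> task 3.5 s -> relax 4 s.
    """

    n_runs: int = 12
    trials_per_condition_per_run: dict[str, int] = field(
        default_factory=lambda: {c: 4 for c in CONDITIONS}
    )
    fs: float = 1200.0
    montage: tuple[str, ...] = DEFAULT_MONTAGE
    # trial timeline (s)
    cross_s: float = 2.0
    cue_s: float = 1.0
    task_s: float = 3.5
    relax_s: float = 4.0
    # signal model
    band_amp: dict[str, float] = field(
        default_factory=lambda: {"alpha": 10.0, "beta": 5.0}
    )  # narrowband RMS amplitude, uV
    noise_exponent: float = 1.0  # 1/f^exponent background
    noise_amp: float = 5.0  # background RMS amplitude, uV
    erd_depth: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(d) for c, d in DEFAULT_ERD_DEPTH.items()}
    )
    erd_latency: dict[str, float] = field(
        default_factory=lambda: {c: 0.5 for c in CONDITIONS}
    )
    artifact_rate: float = 0.0
    artifact_amp: float = 300.0
    lagged_coupling: LaggedCoupling | None = None
    rng_seed: int = 0

    @property
    def trial_s(self) -> float:
        return self.cross_s + self.cue_s + self.task_s + self.relax_s

    def validate(self) -> None:
        if self.n_runs <= 0:
            raise ConfigError("n_runs must be positive")
        for cond, n in self.trials_per_condition_per_run.items():
            if cond not in CONDITIONS:
                raise ConfigError(f"unknown condition {cond!r}")
            if n <= 0:
                raise ConfigError(f"trials per run for {cond!r} must be positive, got {n}")
        if set(self.trials_per_condition_per_run) != set(CONDITIONS):
            raise ConfigError("trials_per_condition_per_run must cover all four conditions")
        if len(self.montage) != 16 or len(set(self.montage)) != 16:
            raise ConfigError("montage must contain exactly 16 unique labels")
        band_edges = {"alpha": ALPHA, "beta": BETA}
        top = max(band_edges[b][1] for b in self.band_amp)
        if self.fs <= 2 * top:
            raise ConfigError(f"fs={self.fs} must exceed twice the highest band edge {top}")
        for cond, per_ch in self.erd_depth.items():
            for ch, d in per_ch.items():
                if ch not in self.montage:
                    raise ConfigError(f"erd_depth channel {ch!r} not in montage")
                if not (0.0 <= d < 1.0):
                    raise ConfigError(f"erd_depth[{cond}][{ch}]={d} outside [0, 1)")
        if self.erd_depth.get("rest"):
            raise ConfigError("rest condition must have zero erd_depth everywhere")
        if not (0.0 <= self.artifact_rate <= 1.0):
            raise ConfigError("artifact_rate must lie in [0, 1]")


@dataclass(frozen=True)
class Trial:
    run_index: int
    trial_index: int  # within session, 0-based
    condition: str
    cue_onset_time: float  # seconds into session


@dataclass
class TrialSchedule:
    """Ordered trial list with absolute cue-onset times."""

    trials: list[Trial]
    cross_s: float = 2.0
    cue_s: float = 1.0
    task_s: float = 3.5
    relax_s: float = 4.0

    def __len__(self) -> int:
        return len(self.trials)

    def task_onset(self, trial: Trial) -> float:
        """Task origin (t = 0 of the trial's analysis timeline), s into session."""
        return trial.cue_onset_time + self.cue_s

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {c: 0 for c in CONDITIONS}
        for t in self.trials:
            out[t.condition] += 1
        return out

    @property
    def duration(self) -> float:
        last = self.trials[-1]
        return self.task_onset(last) + self.task_s + self.relax_s


@dataclass
class RawSession:
    """Continuous multichannel recording in uV plus its trial schedule."""

    data: np.ndarray  # (n_channels, n_samples), uV
    fs: float
    montage: tuple[str, ...]
    schedule: TrialSchedule
    seed_used: int
    artifact_trials: list[int] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "RawSession":
        return RawSession(
            data=self.data.copy(),
            fs=self.fs,
            montage=self.montage,
            schedule=self.schedule,
            seed_used=self.seed_used,
            artifact_trials=list(self.artifact_trials),
        )


def build_trial_schedule(cfg: SimConfig) -> TrialSchedule:
    """Randomized trial order per run, fixed cue cadence.

    Within every run the rest-type and imagery-type trial counts are
    honoured exactly and the order of all trials in the run is a uniform
    random permutation (reproducible under ``cfg.rng_seed``).  Trials
    are laid back-to-back: consecutive cue onsets are separated by the
    full trial timeline, satisfying the minimum-spacing requirement.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    trials: list[Trial] = []
    t = cfg.cross_s  # first cue comes after the first fixation cross
    idx = 0
    for run in range(cfg.n_runs):
        conds: list[str] = []
        for cond in CONDITIONS:
            conds.extend([cond] * cfg.trials_per_condition_per_run[cond])
        order = rng.permutation(len(conds))
        for j in order:
            trials.append(Trial(run, idx, conds[j], cue_onset_time=t))
            t += cfg.trial_s
            idx += 1
    return TrialSchedule(
        trials, cross_s=cfg.cross_s, cue_s=cfg.cue_s,
        task_s=cfg.task_s, relax_s=cfg.relax_s,
    )


def _one_over_f_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise with a 1/f^exponent amplitude spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    x = np.fft.irfft(spec * scale, n=n)
    return x / x.std()


def _narrowband(n: int, band: tuple[float, float], fs: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited Gaussian process."""
    x = bandpass_filter(rng.standard_normal(n), band, fs)
    return x / x.std()


def _erd_envelope(
    n: int, fs: float, schedule: TrialSchedule,
    depth_by_cond: dict[str, float], latency_by_cond: dict[str, float],
) -> np.ndarray:
    """Amplitude gain over time for one channel and one band.

    1 outside task windows; within the task window of a trial whose
    condition has depth d, ramps linearly from 1 to sqrt(1 - d) over the
    condition's latency and holds until the end of the task.
    """
    env = np.ones(n)
    for trial in schedule.trials:
        d = depth_by_cond.get(trial.condition, 0.0)
        if d <= 0.0:
            continue
        lat = latency_by_cond.get(trial.condition, 0.5)
        t0 = schedule.task_onset(trial)
        i0 = int(round(t0 * fs))
        i1 = min(int(round((t0 + schedule.task_s) * fs)), n)
        if i0 >= n:
            continue
        g = np.sqrt(1.0 - d)
        n_ramp = max(int(round(lat * fs)), 1)
        ramp_end = min(i0 + n_ramp, i1)
        env[i0:ramp_end] = np.linspace(1.0, g, ramp_end - i0, endpoint=False)
        env[ramp_end:i1] = g
    return env


def _task_mask(n: int, fs: float, schedule: TrialSchedule,
               conditions: tuple[str, ...]) -> np.ndarray:
    mask = np.zeros(n)
    for trial in schedule.trials:
        if trial.condition not in conditions:
            continue
        i0 = int(round(schedule.task_onset(trial) * fs))
        i1 = min(int(round((schedule.task_onset(trial) + schedule.task_s) * fs)), n)
        mask[i0:i1] = 1.0
    return mask


def synthesize_session(cfg: SimConfig, schedule: TrialSchedule | None = None) -> RawSession:
    """Render the continuous EEG for a schedule.

    Each channel is an independent realization of
    ``noise_amp * (1/f noise) + sum_band band_amp * envelope(t) * narrowband``.
    Determinism: a fixed ``cfg.rng_seed`` yields byte-identical sessions.
    """
    cfg.validate()
    if schedule is None:
        schedule = build_trial_schedule(cfg)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.rng_seed, 1)))
    fs = cfg.fs
    n = int(np.ceil(schedule.duration * fs))
    band_edges = {"alpha": ALPHA, "beta": BETA}
    data = np.empty((len(cfg.montage), n))
    for ci, ch in enumerate(cfg.montage):
        x = cfg.noise_amp * _one_over_f_noise(n, cfg.noise_exponent, rng)
        for bname, amp in cfg.band_amp.items():
            depth_by_cond = {
                cond: per_ch.get(ch, 0.0) for cond, per_ch in cfg.erd_depth.items()
            }
            env = _erd_envelope(n, fs, schedule, depth_by_cond, cfg.erd_latency)
            x = x + amp * env * _narrowband(n, band_edges[bname], fs, rng)
        data[ci] = x

    cpl = cfg.lagged_coupling
    if cpl is not None:
        ia = cfg.montage.index(cpl.channel_a)
        ib = cfg.montage.index(cpl.channel_b)
        src = _narrowband(n, cpl.band, fs, rng)
        lag = int(round(cpl.lag_s * fs))
        mask = _task_mask(n, fs, schedule, cpl.conditions)
        data[ia] += cpl.gain * src * mask
        data[ib] += cpl.gain * np.roll(src, lag) * mask

    session = RawSession(
        data=data, fs=fs, montage=tuple(cfg.montage),
        schedule=schedule, seed_used=cfg.rng_seed,
    )
    if cfg.artifact_rate > 0.0:
        session = inject_artifacts(
            session, cfg.artifact_rate, cfg.artifact_amp,
            rng_seed=cfg.rng_seed + 10_007,
        )
    return session


def inject_artifacts(
    session: RawSession, rate: float, amplitude: float, rng_seed: int
) -> RawSession:
    """Add blink-like transients to a Bernoulli(rate) subset of trials.

    Each affected trial receives a 0.3 s half-sine pulse of the given
    peak amplitude (uV) on the frontal-most (FC-row) channels at a
    random moment inside the task window.  Affected session-level trial
    indices are recorded on the returned copy; the input is unchanged.
    """
    if not (0.0 <= rate <= 1.0):
        raise ConfigError(f"artifact rate {rate} outside [0, 1]")
    if amplitude <= 0:
        raise ConfigError("artifact amplitude must be positive")
    out = session.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(rng_seed)
    fs = session.fs
    width = int(round(0.3 * fs))
    pulse = amplitude * np.sin(np.linspace(0.0, np.pi, width))
    frontal = [i for i, ch in enumerate(session.montage) if ch.startswith("FC")] or [0, 1]
    sched = session.schedule
    for trial in sched.trials:
        if rng.random() >= rate:
            continue
        t0 = sched.task_onset(trial)
        start_lo = int(round(t0 * fs))
        start_hi = int(round((t0 + sched.task_s) * fs)) - width
        start = int(rng.integers(start_lo, max(start_hi, start_lo + 1)))
        stop = min(start + width, out.n_samples)
        for ci in frontal:
            out.data[ci, start:stop] += pulse[: stop - start]
        out.artifact_trials.append(trial.trial_index)
    return out


def config_to_dict(cfg: SimConfig) -> dict:
    """JSON-serializable form of a SimConfig (round-trips via config_from_dict)."""
    d = dataclasses.asdict(cfg)
    d["montage"] = list(cfg.montage)
    if cfg.lagged_coupling is not None:
        d["lagged_coupling"] = dataclasses.asdict(cfg.lagged_coupling)
        d["lagged_coupling"]["band"] = list(cfg.lagged_coupling.band)
        d["lagged_coupling"]["conditions"] = list(cfg.lagged_coupling.conditions)
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    d["montage"] = tuple(d["montage"])
    if d.get("lagged_coupling"):
        c = dict(d["lagged_coupling"])
        c["band"] = tuple(c["band"])
        c["conditions"] = tuple(c["conditions"])
        d["lagged_coupling"] = LaggedCoupling(**c)
    return SimConfig(**d)
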