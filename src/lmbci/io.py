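"""Session and epoch container I/O.

Sessions are stored as EDF (16-bit European Data Format, one 1-second
data record per second, physical units uV) plus a JSON sidecar holding
the trial schedule, the simulation configuration and the seed.  The EDF
writer is a minimal self-contained implementation of the format's fixed
256 + 256*ns byte ASCII header and int16 little-endian data records;
reading goes through :func:`mne.io.read_raw_edf`.

Epoch sets round-trip through a versioned NumPy ``.npz`` container
(``lmbci-epochs-v1``) with a JSON metadata entry.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from lmbci.errors import ConfigError
from lmbci.preprocessing import EpochSet
from lmbci.simulate import (
    RawSession,
    SimConfig,
    Trial,
    TrialSchedule,
    config_from_dict,
    config_to_dict,
)

EPOCHS_FORMAT_VERSION = "lmbci-epochs-v1"


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(path: str | Path, session: RawSession) -> Path:
    """Write a session to EDF.

    Uses 1 s data records, so the sampling rate must be a positive
    integer.  The tail is zero-padded to a whole record.  Quantization
    to 16 bits over the session's own amplitude range keeps the
    round-trip error below range/65535 uV per sample.
    """
    path = Path(path)
    fs = session.fs
    if fs != int(fs) or fs <= 0:
        raise ConfigError(f"EDF writer requires an integer sampling rate, got {fs}")
    spr = int(fs)  # samples per record per signal
    n_ch, n_samp = session.data.shape
    n_rec = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = session.data

    phys_max = float(max(np.abs(padded).max() * 1.0001, 1.0))
    # the header stores the range at 2 decimals; scale with the same value
    phys_max = float(f"{np.ceil(phys_max * 100) / 100:.2f}"[:8])
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32768
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((padded - phys_min) * scale + dig_min).astype("<i2")

    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),  # local patient identification (synthetic)
        _pad("Startdate X X X X", 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (n_ch + 1)), 8),
        _pad("", 44),
        _pad(str(n_rec), 8),
        _pad("1", 8),  # record duration, s
        _pad(str(n_ch), 4),
    ])
    fields = [
        [_pad(ch, 16) for ch in session.montage],
        [_pad("AgAgCl electrode", 80)] * n_ch,
        [_pad("uV", 8)] * n_ch,
        [_pad(f"{phys_min:.2f}"[:8], 8)] * n_ch,
        [_pad(f"{phys_max:.2f}"[:8], 8)] * n_ch,
        [_pad(str(dig_min), 8)] * n_ch,
        [_pad(str(dig_max), 8)] * n_ch,
        [_pad("", 80)] * n_ch,
        [_pad(str(spr), 8)] * n_ch,
        [_pad("", 32)] * n_ch,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for group in fields:
            fh.write(b"".join(group))
        # data records: per record, all samples of signal 1, then signal 2, ...
        for r in range(n_rec):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())
    return path


def _schedule_to_dict(schedule: TrialSchedule) -> dict:
    return {
        "cross_s": schedule.cross_s,
        "cue_s": schedule.cue_s,
        "task_s": schedule.task_s,
        "relax_s": schedule.relax_s,
        "trials": [dataclasses.asdict(t) for t in schedule.trials],
    }


def _schedule_from_dict(d: dict) -> TrialSchedule:
    return TrialSchedule(
        trials=[Trial(**t) for t in d["trials"]],
        cross_s=d["cross_s"], cue_s=d["cue_s"],
        task_s=d["task_s"], relax_s=d["relax_s"],
    )


def write_sidecar(path: str | Path, session: RawSession,
                  cfg: SimConfig | None = None) -> Path:
    path = Path(path)
    payload = {
        "fs": session.fs,
        "montage": list(session.montage),
        "seed_used": session.seed_used,
        "n_samples": session.n_samples,
        "artifact_trials": list(session.artifact_trials),
        "schedule": _schedule_to_dict(session.schedule),
        "sim_config": config_to_dict(cfg) if cfg is not None else None,
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def save_session(edf_path: str | Path, session: RawSession,
                 cfg: SimConfig | None = None) -> tuple[Path, Path]:
    """Write session EDF and its JSON sidecar (``<stem>.json``)."""
    edf_path = Path(edf_path)
    write_edf(edf_path, session)
    sidecar = edf_path.with_suffix(".json")
    write_sidecar(sidecar, session, cfg)
    return edf_path, sidecar


def read_session(
    edf_path: str | Path,
    sidecar_path: str | Path | None = None,
    apply_acquisition_filters: bool = False,
) -> tuple[RawSession, SimConfig | None]:
    """Round-trip reader: EDF via MNE plus the JSON sidecar.

    ``apply_acquisition_filters`` optionally replicates the recording
    chain of the emulated amplifier (0-60 Hz band-pass and 48-52 Hz
    notch); off by default since synthetic sessions have no line noise.
    """
    import mne

    edf_path = Path(edf_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else edf_path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text())
    raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
    data = raw.get_data(units="uV")
    if apply_acquisition_filters:
        from scipy import signal as sps
        fs = meta["fs"]
        sos = sps.butter(4, min(60.0, fs / 2 * 0.99) / (fs / 2), btype="lowpass",
                         output="sos")
        data = sps.sosfiltfilt(sos, data, axis=-1)
        b, a = sps.iirnotch(50.0, Q=12.5, fs=fs)
        data = sps.filtfilt(b, a, data, axis=-1)
    data = data[:, : meta["n_samples"]]
    session = RawSession(
        data=data,
        fs=meta["fs"],
        montage=tuple(meta["montage"]),
        schedule=_schedule_from_dict(meta["schedule"]),
        seed_used=meta["seed_used"],
        artifact_trials=list(meta["artifact_trials"]),
    )
    cfg = config_from_dict(meta["sim_config"]) if meta.get("sim_config") else None
    return session, cfg


def save_session_csv(directory: str | Path, session: RawSession) -> Path:
    """Plain-text fallback: one CSV per channel plus the JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, ch in enumerate(session.montage):
        np.savetxt(directory / f"{ch}.csv", session.data[i], fmt="%.6f")
    write_sidecar(directory / "session.json", session)
    return directory


def read_session_csv(directory: str | Path) -> RawSession:
    directory = Path(directory)
    meta = json.loads((directory / "session.json").read_text())
    data = np.vstack([
        np.loadtxt(directory / f"{ch}.csv") for ch in meta["montage"]
    ])
    return RawSession(
        data=data, fs=meta["fs"], montage=tuple(meta["montage"]),
        schedule=_schedule_from_dict(meta["schedule"]),
        seed_used=meta["seed_used"],
        artifact_trials=list(meta["artifact_trials"]),
    )


def save_epochs(path: str | Path, epochs: EpochSet) -> Path:
    path = Path(path)
    meta = {
        "format": EPOCHS_FORMAT_VERSION,
        "fs": epochs.fs,
        "montage": list(epochs.montage),
        "flag_reasons": {str(k): v for k, v in epochs.flag_reasons.items()},
        "segment_tmin": epochs.segment_tmin,
        "has_segment": epochs.segment is not None,
    }
    arrays = dict(
        baseline=epochs.baseline,
        task=epochs.task,
        labels=epochs.labels.astype("U8"),
        artifact_flags=epochs.artifact_flags,
        trial_ids=epochs.trial_ids,
        meta=np.array(json.dumps(meta)),
    )
    if epochs.segment is not None:
        arrays["segment"] = epochs.segment
    np.savez_compressed(path, **arrays)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_epochs(path: str | Path) -> EpochSet:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        if meta.get("format") != EPOCHS_FORMAT_VERSION:
            raise ConfigError(f"unsupported epochs container: {meta.get('format')!r}")
        return EpochSet(
            baseline=z["baseline"],
            task=z["task"],
            labels=z["labels"],
            artifact_flags=z["artifact_flags"],
            fs=meta["fs"],
            montage=tuple(meta["montage"]),
            trial_ids=z["trial_ids"],
            flag_reasons={int(k): v for k, v in meta["flag_reasons"].items()},
            segment=z["segment"] if meta.get("has_segment") else None,
            segment_tmin=meta.get("segment_tmin", -3.0),
        )
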