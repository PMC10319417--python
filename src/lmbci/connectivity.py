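"""Functional connectivity via the imaginary part of coherency.

Coherency R_xy(f) = S_xy(f) / sqrt(S_xx(f) S_yy(f)) generalizes
correlation to the frequency domain; its magnitude (coherence) lies in
[0, 1].  Instantaneous mixing of a common source — the dominant
artifact of sensor-space EEG connectivity, caused by volume conduction
— produces purely real coherency, so the imaginary part

    iCOH_xy(f) = Im R_xy(f)

is only nonzero for genuinely time-lagged interactions.  Spectra are
estimated trial-as-segment: each Hann-tapered task epoch contributes
one periodogram to the cross- and auto-spectral averages (frequency
resolution ~1/3 Hz for 3 s epochs).  Band summaries average |Im R|
over in-band bins (connection strength); the signed band average is
retained for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lmbci.errors import ConfigError, DegenerateInputError
from lmbci.erd import BANDS
from lmbci.preprocessing import EpochSet


@dataclass
class ConnectivityMatrix:
    """Channel x channel band-averaged iCOH.

    ``values`` holds mean |Im R| (symmetric, zero diagonal, entries in
    [0, 1]); ``signed`` the mean of Im R (antisymmetric).
    """

    values: np.ndarray
    signed: np.ndarray
    band_name: str
    band: tuple[float, float]
    n_trials: int
    montage: tuple[str, ...]

    def edge_list(self):
        """Upper-triangle (channel_a, channel_b, icoh_abs, icoh_signed) rows."""
        import pandas as pd

        rows = []
        n = len(self.montage)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append({
                    "channel_a": self.montage[i], "channel_b": self.montage[j],
                    "band": self.band_name,
                    "icoh_abs": self.values[i, j], "icoh_signed": self.signed[i, j],
                })
        return pd.DataFrame(rows)

    def top_edges(self, k: int = 20):
        """Strongest k connections, a display convention for map plotting."""
        df = self.edge_list()
        return df.sort_values("icoh_abs", ascending=False).head(k).reset_index(drop=True)


def _cross_spectra(data: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged cross-spectral matrix.

    ``data`` is (n_trials, n_channels, n_samples); returns (freqs,
    S[ch, ch, freq]) with S averaged over Hann-tapered trial
    periodograms.
    """
    n_trials, n_ch, n = data.shape
    taper = np.hanning(n)
    spec = np.fft.rfft(data * taper, axis=-1)  # (trials, ch, freq)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    s = np.einsum("tif,tjf->ijf", spec, np.conj(spec)) / n_trials
    return freqs, s


def coherency(
    data: np.ndarray, fs: float, pair: tuple[int, int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Complex coherency spectrum, trial-averaged.

    ``data`` is (n_trials, n_channels, n_samples) with at least two
    trials — a single segment is degenerate (|R| = 1 identically).
    Returns (freqs, R) where R is (n_ch, n_ch, n_freq) or, if ``pair``
    is given, the (n_freq,) spectrum of that channel pair.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ConfigError("expected (n_trials, n_channels, n_samples) array")
    if data.shape[0] < 2:
        raise DegenerateInputError(
            "coherency needs >= 2 trials; with one segment |R| = 1 identically"
        )
    freqs, s = _cross_spectra(data, fs)
    auto = np.real(np.einsum("iif->if", s))  # (ch, freq)
    denom = np.sqrt(auto[:, None, :] * auto[None, :, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, s / denom, 0.0)
    if pair is not None:
        return freqs, r[pair[0], pair[1]]
    return freqs, r


def icoh_matrix(
    epochs: EpochSet,
    band: str | tuple[float, float],
    condition: str | None = None,
) -> ConnectivityMatrix:
    """Band-averaged |iCOH| (and signed iCOH) over all channel pairs."""
    if isinstance(band, str):
        band_name, band_edges = band, BANDS[band]
    else:
        band_name, band_edges = f"{band[0]:g}-{band[1]:g}Hz", tuple(band)
    if condition is None:
        idx = np.flatnonzero(epochs.clean_mask())
    else:
        idx = epochs.condition_indices(condition)
    if len(idx) < 2:
        raise DegenerateInputError("need >= 2 clean trials for cross-spectral averaging")
    freqs, r = coherency(epochs.task[idx], epochs.fs)
    in_band = (freqs >= band_edges[0]) & (freqs <= band_edges[1])
    if not in_band.any():
        raise ConfigError(f"band {band_edges} contains no frequency bins")
    im = np.imag(r[:, :, in_band])
    values = np.abs(im).mean(axis=2)
    signed = im.mean(axis=2)
    np.fill_diagonal(values, 0.0)
    np.fill_diagonal(signed, 0.0)
    return ConnectivityMatrix(
        values=values, signed=signed, band_name=band_name, band=band_edges,
        n_trials=len(idx), montage=epochs.montage,
    )


def grand_average(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Elementwise mean across sessions/subjects (montage and band must match)."""
    if not matrices:
        raise ConfigError("empty matrix list")
    first = matrices[0]
    for m in matrices[1:]:
        if m.montage != first.montage:
            raise ConfigError("montage mismatch in grand average")
        if m.band != first.band:
            raise ConfigError("band mismatch in grand average")
    return ConnectivityMatrix(
        values=np.mean([m.values for m in matrices], axis=0),
        signed=np.mean([m.signed for m in matrices], axis=0),
        band_name=first.band_name,
        band=first.band,
        n_trials=sum(m.n_trials for m in matrices),
        montage=first.montage,
    )
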