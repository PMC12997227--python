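"""Hanning-taper time–frequency estimation and baseline correction.

Power is estimated with a sliding fixed-length (default 1 s) Hanning-tapered
window evaluated by direct DFT at the requested frequencies.  Because the
requested frequencies sit on the grid of the zero-padded (default 8 s)
transform, the direct evaluation is identical to picking bins from the
padded FFT — padding only interpolates the spectrum.  Window positions that
extend past the epoch edges are undefined and flagged missing (NaN) rather
than zero-filled; baseline correction is the relative (fractional) change
with respect to the mean raw power in a pre-stimulus window.

Normalization follows the one-sided density convention
``power = |X|^2 * 2 / (sfreq * sum(taper^2))``; everything reported
downstream is a relative change, which is normalization-invariant.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import h5py
import numpy as np

from .epochs import EpochSet


@dataclass(frozen=True)
class WindowSpec:
    """Inclusive frequency/time selection box."""

    fmin: float
    fmax: float
    tmin: float
    tmax: float

    def __post_init__(self) -> None:
        if self.fmin > self.fmax or self.tmin > self.tmax:
            raise ValueError("window bounds must be ordered")


ANALYSIS_WINDOW = WindowSpec(3.0, 6.0, 0.250, 0.500)
BASELINE_WINDOW = WindowSpec(0.0, np.inf, -1.5, -0.5)
THETA_BASELINE_WINDOW = WindowSpec(3.0, 6.0, -1.5, -0.5)


@dataclass
class TFRMap:
    """Power over (channel-or-source) x frequency x time.

    ``power`` may carry a leading trial axis when single-trial spectra are
    retained.  Missing estimates (window past the epoch edge) are NaN.
    ``mode`` is 'raw' (power >= 0) or 'relchange' (values >= -1).
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    mode: str = "raw"
    window_length: float = 1.0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.freqs) <= 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("frequency and time axes must be strictly increasing")
        if self.power.shape[-2:] != (len(self.freqs), len(self.times)):
            raise ValueError("power trailing axes must be (freqs, times)")

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.power)

    def freq_mask(self, fmin: float, fmax: float) -> np.ndarray:
        return (self.freqs >= fmin) & (self.freqs <= fmax)

    def time_mask(self, tmin: float, tmax: float) -> np.ndarray:
        return (self.times >= tmin) & (self.times <= tmax)

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("power", data=self.power, compression="gzip")
            f.create_dataset("freqs", data=self.freqs)
            f.create_dataset("times", data=self.times)
            f.attrs["mode"] = self.mode
            f.attrs["window_length"] = self.window_length

    @classmethod
    def load(cls, path) -> "TFRMap":
        with h5py.File(path, "r") as f:
            return cls(
                power=f["power"][()],
                freqs=f["freqs"][()],
                times=f["times"][()],
                mode=str(f.attrs["mode"]),
                window_length=float(f.attrs["window_length"]),
            )


def default_freqs() -> np.ndarray:
    return np.arange(1.0, 15.0 + 1e-9, 0.5)


def default_times() -> np.ndarray:
    return np.arange(-1.5, 1.5 + 1e-9, 0.05)


def tfr_hanning(
    epochs: EpochSet,
    freqs: np.ndarray | None = None,
    times: np.ndarray | None = None,
    window_length: float = 1.0,
    pad_to: float = 8.0,
    keep_trials: bool = False,
) -> TFRMap:
    """Sliding-window Hanning-taper power spectra, averaged across trials.

    At every requested time point the window of ``window_length`` seconds
    centred there is extracted, Hanning-tapered, and Fourier-transformed at
    the requested frequencies (direct DFT; equivalent to zero-padding to
    ``pad_to`` seconds and picking bins).  Time points whose window extends
    past either epoch edge are flagged missing.
    """
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    freqs = default_freqs() if freqs is None else np.asarray(freqs, dtype=float)
    times = default_times() if times is None else np.asarray(times, dtype=float)
    if np.any(freqs > epochs.sfreq / 2.0):
        raise ValueError("requested frequency above Nyquist")
    nw = int(round(window_length * epochs.sfreq))
    if nw > epochs.n_samples:
        raise ValueError("window_length exceeds the epoch duration")
    if pad_to < epochs.n_samples / epochs.sfreq:
        raise ValueError("pad_to must be at least the epoch duration")

    taper = np.hanning(nw)
    t_idx = (np.arange(nw) / epochs.sfreq)[None, :]
    phase = 2.0 * np.pi * freqs[:, None] * t_idx
    # real/imaginary DFT rows kept separate: avoids complex upcasting copies
    dft_cos = (np.cos(phase) * taper[None, :]).T.copy()
    dft_sin = (np.sin(phase) * taper[None, :]).T.copy()
    norm = 2.0 / (epochs.sfreq * np.sum(taper**2))

    n_out = (epochs.n_trials,) if keep_trials else ()
    power = np.full(n_out + (epochs.n_channels, len(freqs), len(times)), np.nan)

    half_lo = (nw - 1) // 2
    for j, tc in enumerate(times):
        c = int(round((tc - epochs.tmin) * epochs.sfreq))
        i0 = c - half_lo
        i1 = i0 + nw
        if i0 < 0 or i1 > epochs.n_samples:
            continue
        seg = np.ascontiguousarray(epochs.data[:, :, i0:i1]).reshape(-1, nw)
        re = seg @ dft_cos
        im = seg @ dft_sin
        p = ((re**2 + im**2) * norm).reshape(
            epochs.n_trials, epochs.n_channels, len(freqs)
        )
        if keep_trials:
            power[:, :, :, j] = p
        else:
            power[:, :, j] = p.mean(axis=0)

    return TFRMap(power=power, freqs=freqs, times=times, mode="raw", window_length=window_length)


def baseline_correct(tfr: TFRMap, baseline: WindowSpec = BASELINE_WINDOW) -> TFRMap:
    """Relative (fractional) change with respect to the baseline mean.

    ``out = (P - B) / B`` with B the mean raw power over non-missing
    baseline time points, separately per channel and frequency.
    """
    if tfr.mode != "raw":
        raise ValueError("baseline correction expects a raw-power TFR")
    tmask = tfr.time_mask(baseline.tmin, baseline.tmax)
    if not tmask.any():
        raise ValueError("baseline window does not overlap the time axis")
    with np.errstate(invalid="ignore"):
        B = np.nanmean(tfr.power[..., tmask], axis=-1)
    if np.any(~np.isfinite(B)) or np.any(B <= 0):
        raise ValueError("baseline power must be finite and positive")
    rel = (tfr.power - B[..., None]) / B[..., None]
    return replace(tfr, power=rel, mode="relchange")


def average_window(tfr: TFRMap, window: WindowSpec) -> np.ndarray:
    """Mean over all (freq, time) bins inside the window (inclusive bounds).

    Missing bins are skipped; returns one value per channel/source (per
    trial and channel when the map retains trials).
    """
    fmask = tfr.freq_mask(window.fmin, window.fmax)
    tmask = tfr.time_mask(window.tmin, window.tmax)
    if not fmask.any() or not tmask.any():
        raise ValueError("window selects no bins")
    sel = tfr.power[..., fmask, :][..., tmask]
    if np.all(np.isnan(sel)):
        raise ValueError("window selects only missing bins")
    return np.nanmean(sel, axis=(-2, -1))


SCAN_BANDS = [(3.0, 4.0), (4.0, 5.0), (5.0, 6.0), (6.0, 7.0), (7.0, 8.0)]
SCAN_WINDOWS = [(0.2, 0.3), (0.3, 0.4), (0.4, 0.5), (0.5, 0.6)]


def window_scan(tfr_go: TFRMap, tfr_nogo: TFRMap) -> np.ndarray:
    """Per-channel NoGo - Go means over a 5-band x 4-window scan grid.

    Bands are 1 Hz wide from 3–4 to 7–8 Hz; windows 100 ms wide from
    200–300 to 500–600 ms; returns an array (5, 4, n_channels).
    """
    if not (
        np.array_equal(tfr_go.freqs, tfr_nogo.freqs)
        and np.array_equal(tfr_go.times, tfr_nogo.times)
    ):
        raise ValueError("TFR axes must match")
    out = np.empty((len(SCAN_BANDS), len(SCAN_WINDOWS), tfr_go.power.shape[0]))
    for i, (f0, f1) in enumerate(SCAN_BANDS):
        for j, (t0, t1) in enumerate(SCAN_WINDOWS):
            w = WindowSpec(f0, f1, t0, t1)
            out[i, j] = average_window(tfr_nogo, w) - average_window(tfr_go, w)
    return out
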