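"""Epoch-quality metrics: pre-stimulus noise, band power and the
walking/seated power ratio, P300 signal-to-noise ratio, per-trial
coefficient of variation and its epoch average, and scalar-product ERP
similarity with Fisher-domain averaging.

Conventions used throughout:

* the per-trial coefficient of variation is sample standard deviation
  (``ddof=1``) over the window divided by the window mean; a zero mean
  yields NaN, which averages exclude (and count);
* the scalar product is computed on mean-centered, unit-normalized
  waveforms, i.e. it equals the Pearson correlation coefficient; the raw
  (uncentered) cosine is available via ``center=False``;
* band power stays on the linear μV²/Hz scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import signal

from .core import BandSet, EpochSet, ERPWaveform, TARGET, default_bands

__all__ = [
    "PSNResult",
    "BandPowerResult",
    "SimilarityResult",
    "psn",
    "band_power",
    "ratio_ws",
    "average_erp",
    "snr",
    "cv_trial",
    "cv_erp",
    "scalar_similarity",
    "fisher_average",
]

log = logging.getLogger(__name__)

DEFAULT_PSN_WINDOW = (-0.3, 0.0)
DEFAULT_P300_WINDOW = (0.3, 0.5)
DEFAULT_NFFT = 256
DEFAULT_SEGLEN = 128


@dataclass
class PSNResult:
    """Root-mean-square pre-stimulus amplitude, per kept trial and channel."""

    per_trial: np.ndarray  # kept trials x channels, μV
    channel_mean: np.ndarray  # per channel, μV
    grand_mean: float  # μV
    channel_labels: list[str]


@dataclass
class BandPowerResult:
    """Linear spectral power per band (μV²/Hz)."""

    per_channel: Mapping[str, np.ndarray]  # band -> per-channel mean PSD
    channel_avg: Mapping[str, float]  # band -> channel-averaged value
    freqs: np.ndarray
    psd: np.ndarray  # channels x freqs, epoch-averaged
    bands: BandSet
    channel_labels: list[str]


@dataclass
class SimilarityResult:
    """Scalar products per channel with their Fisher-domain average."""

    per_channel: np.ndarray  # r values, NaN where undefined
    fisher_z: np.ndarray
    average: float
    channel_labels: list[str]


def psn(epochs: EpochSet,
        window: tuple[float, float] = DEFAULT_PSN_WINDOW,
        label: str | None = None) -> PSNResult:
    """RMS amplitude over the pre-stimulus window, per kept trial/channel.

    ``label`` optionally restricts the computation to one stimulus class.
    """
    mask = epochs.keep_mask.copy()
    if label is not None:
        mask &= np.array([lb == label for lb in epochs.labels])
    if not mask.any():
        raise ValueError("no kept epochs to compute PSN from")
    smask = epochs.time_mask(*window)
    if not smask.any():
        raise ValueError(f"window {window} outside the epoch time axis")
    seg = epochs.tensor[mask][:, :, smask]
    per_trial = np.sqrt(np.mean(seg ** 2, axis=2))
    channel_mean = per_trial.mean(axis=0)
    return PSNResult(per_trial, channel_mean, float(channel_mean.mean()),
                     list(epochs.channel_labels))


def band_power(epochs: EpochSet, bands: BandSet | None = None,
               nfft: int = DEFAULT_NFFT,
               seglen: int = DEFAULT_SEGLEN,
               overlap: int = 0) -> BandPowerResult:
    """Segment-averaged periodogram power per frequency band.

    Each kept epoch is split into Hamming-windowed segments of ``seglen``
    samples (zero-padded to ``nfft``), periodograms are averaged over
    segments, epochs, and finally channels; band power is the mean PSD over
    the frequency bins inside each band (inclusive bounds).
    """
    if bands is None:
        bands = default_bands()
    n_samp = epochs.tensor.shape[2]
    if n_samp < seglen:
        raise ValueError(
            f"epochs of {n_samp} samples are shorter than seglen {seglen}"
        )
    nyq = epochs.rate / 2.0
    for name, (lo, hi) in bands.items():
        if hi > nyq:
            raise ValueError(f"band {name} ({lo}-{hi} Hz) exceeds Nyquist {nyq}")
    kept = epochs.kept()
    if kept.shape[0] == 0:
        raise ValueError("no kept epochs to compute band power from")
    freqs, psd = signal.welch(
        kept, fs=epochs.rate, window="hamming", nperseg=seglen,
        noverlap=overlap, nfft=nfft, detrend=False, scaling="density",
        axis=2,
    )
    psd_ch = psd.mean(axis=0)  # channels x freqs
    per_channel, channel_avg = {}, {}
    for name, (lo, hi) in bands.items():
        sel = (freqs >= lo) & (freqs <= hi)
        vals = psd_ch[:, sel].mean(axis=1)
        per_channel[name] = vals
        channel_avg[name] = float(vals.mean())
    return BandPowerResult(per_channel, channel_avg, freqs, psd_ch, bands,
                           list(epochs.channel_labels))


def ratio_ws(walk: BandPowerResult, seat: BandPowerResult) -> dict[str, float]:
    """Per-band walking/seated power ratio on the linear scale."""
    if set(walk.channel_avg) != set(seat.channel_avg):
        raise ValueError("band sets differ between conditions")
    out = {}
    for band, seated_power in seat.channel_avg.items():
        if seated_power <= 0:
            raise ZeroDivisionError(f"seated power in band {band!r} is zero")
        out[band] = walk.channel_avg[band] / seated_power
    return out


def average_erp(epochs: EpochSet, label: str = TARGET) -> ERPWaveform:
    """Pointwise mean over kept trials of one stimulus class."""
    sel = epochs.keep_mask & np.array([lb == label for lb in epochs.labels])
    if not sel.any():
        raise ValueError(f"no kept epochs with label {label!r}")
    return ERPWaveform(
        data=epochs.tensor[sel].mean(axis=0),
        n_epochs=int(sel.sum()),
        label=label,
        epoch_times=epochs.epoch_times.copy(),
        channel_labels=list(epochs.channel_labels),
    )


def snr(erp_target: ERPWaveform, psn_result: PSNResult,
        p300_window: tuple[float, float] = DEFAULT_P300_WINDOW) -> np.ndarray:
    """Per-channel ratio of the P300 peak to the trial-averaged PSN.

    The peak is the signed maximum of the averaged target waveform within
    the window (the P300 is a positive deflection).
    """
    t = erp_target.epoch_times
    sel = (t >= p300_window[0] - 1e-9) & (t <= p300_window[1] + 1e-9)
    if not sel.any():
        raise ValueError(f"window {p300_window} outside the epoch time axis")
    if np.any(psn_result.channel_mean <= 0):
        raise ZeroDivisionError("PSN channel mean is zero")
    peaks = erp_target.data[:, sel].max(axis=1)
    return peaks / psn_result.channel_mean


def cv_trial(trial: np.ndarray, epoch_times: np.ndarray,
             window: tuple[float, float] = DEFAULT_P300_WINDOW,
             use_variance: bool = False) -> float:
    """Coefficient of variation of one trial's samples inside the window.

    Sample standard deviation (``ddof=1``) over the window divided by the
    window mean; ``use_variance`` swaps the numerator for the variance.
    Returns NaN when the mean is exactly zero.
    """
    trial = np.asarray(trial, dtype=np.float64)
    sel = (epoch_times >= window[0] - 1e-9) & (epoch_times <= window[1] + 1e-9)
    if not sel.any():
        raise ValueError(f"window {window} outside the epoch time axis")
    x = trial[sel]
    mean = float(x.mean())
    if mean == 0.0:
        return float("nan")
    spread = float(np.var(x, ddof=1)) if use_variance else float(np.std(x, ddof=1))
    return spread / mean


def cv_erp(epochs: EpochSet,
           window: tuple[float, float] = DEFAULT_P300_WINDOW,
           label: str | None = TARGET,
           use_variance: bool = False) -> tuple[np.ndarray, float, int]:
    """Mean per-trial CV over kept epochs, per channel.

    Returns (per-channel CV_ERP, overall mean, number of undefined trials
    excluded). ``label=None`` pools all kept epochs.
    """
    sel = epochs.keep_mask.copy()
    if label is not None:
        sel &= np.array([lb == label for lb in epochs.labels])
    if not sel.any():
        raise ValueError("no kept epochs to compute CV_ERP from")
    kept = epochs.tensor[sel]
    n_ch = kept.shape[1]
    per_channel = np.empty(n_ch)
    n_undefined = 0
    for c in range(n_ch):
        cvs = np.array([
            cv_trial(kept[i, c], epochs.epoch_times, window, use_variance)
            for i in range(kept.shape[0])
        ])
        defined = cvs[~np.isnan(cvs)]
        n_undefined += int(np.isnan(cvs).sum())
        if defined.size == 0:
            raise ValueError(f"all trial CVs undefined on channel {c}")
        per_channel[c] = defined.mean()
    if n_undefined:
        log.warning("excluded %d undefined trial CV(s)", n_undefined)
    return per_channel, float(per_channel.mean()), n_undefined


def scalar_similarity(erp_a: ERPWaveform, erp_b: ERPWaveform,
                      channel: str | int | None = None,
                      center: bool = True) -> np.ndarray | float:
    """Scalar product of normalized ERP waveforms, in [-1, 1].

    With ``center=True`` (default) the waveforms are mean-centered before
    unit-norm scaling, making the value the Pearson correlation over time.
    Returns a per-channel vector, or a scalar if ``channel`` is given.
    Zero-variance waveforms yield NaN.
    """
    a, b = erp_a.data, erp_b.data
    if a.shape != b.shape:
        raise ValueError(f"waveform shapes differ: {a.shape} vs {b.shape}")
    if center:
        a = a - a.mean(axis=1, keepdims=True)
        b = b - b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.einsum("ct,ct->c", a, b) / (na * nb)
    r = np.where((na == 0) | (nb == 0), np.nan, r)
    r = np.clip(r, -1.0, 1.0)
    if channel is None:
        return r
    if isinstance(channel, str):
        channel = erp_a.channel_labels.index(channel)
    return float(r[channel])


def fisher_average(r_values) -> float:
    """Average correlations in the Fisher-z domain and back-transform.

    Values at exactly +/-1 are clipped just inside the open interval with a
    warning; NaNs are excluded.
    """
    r = np.asarray(r_values, dtype=np.float64)
    r = r[~np.isnan(r)]
    if r.size == 0:
        raise ValueError("no defined correlations to average")
    if np.any(np.abs(r) >= 1.0):
        log.warning("clipping %d correlation(s) at |r| = 1 before atanh",
                    int((np.abs(r) >= 1.0).sum()))
        r = np.clip(r, -1.0 + 1e-7, 1.0 - 1e-7)
    return float(np.tanh(np.mean(np.arctanh(r))))
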