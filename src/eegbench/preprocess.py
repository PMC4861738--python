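"""Continuous-data conditioning and epoching.

Filtering is zero-phase (forward-backward) so that evoked-component latencies
are not shifted; epoch extraction is pure slicing in a half-open sample
window, with the onset sample belonging to the post-stimulus side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import EpochSet, EventList, Montage, Recording, TARGET, default_montage

__all__ = [
    "highpass",
    "notch",
    "interpolate_channels",
    "extract_epochs",
    "behavioral_reject",
    "BehavioralCounts",
]

log = logging.getLogger(__name__)

DEFAULT_HIGHPASS_HZ = 1.0
DEFAULT_NOTCH_HZ = 60.0
DEFAULT_NOTCH_WIDTH_HZ = 2.0
DEFAULT_EPOCH_WINDOW = (-0.3, 0.8)
DEFAULT_RESPONSE_WINDOW_S = 1.4


def highpass(rec: Recording, cutoff: float = DEFAULT_HIGHPASS_HZ,
             order: int = 4) -> Recording:
    """Zero-phase Butterworth high-pass; removes DC and slow drift."""
    nyq = rec.rate / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff {cutoff} Hz outside (0, {nyq}) Hz")
    sos = signal.butter(order, cutoff, btype="highpass", fs=rec.rate,
                        output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return Recording(out, rec.rate, list(rec.channel_labels), dict(rec.meta))


def notch(rec: Recording, line_freq: float = DEFAULT_NOTCH_HZ,
          width: float = DEFAULT_NOTCH_WIDTH_HZ,
          harmonics: int = 1) -> Recording:
    """Zero-phase IIR notch at the mains frequency plus ``harmonics``
    integer multiples (those below Nyquist)."""
    nyq = rec.rate / 2.0
    if not 0 < line_freq < nyq:
        raise ValueError(f"line frequency {line_freq} Hz outside (0, {nyq}) Hz")
    if width <= 0:
        raise ValueError("notch width must be positive")
    out = rec.data
    for k in range(1, harmonics + 2):
        f0 = line_freq * k
        if f0 >= nyq:
            break
        b, a = signal.iirnotch(f0, f0 / width, fs=rec.rate)
        out = signal.filtfilt(b, a, out, axis=1)
    return Recording(out, rec.rate, list(rec.channel_labels), dict(rec.meta))


def interpolation_weights(montage: Montage, bad: list[str],
                          power: float = 2.0) -> dict[str, np.ndarray]:
    """Inverse-distance weights over the good channels for each bad channel.

    Distances are Euclidean chords between unit-sphere positions. Returns,
    per bad label, a weight vector over montage.names (zero at bad entries),
    summing to 1.
    """
    names = list(montage.names)
    pos = montage.position_array()
    good = [i for i, n in enumerate(names) if n not in bad]
    weights = {}
    for b in bad:
        bi = names.index(b)
        d = np.linalg.norm(pos[good] - pos[bi], axis=1)
        w = np.zeros(len(names))
        if np.any(d == 0):
            w[[good[i] for i in np.flatnonzero(d == 0)]] = 1.0
        else:
            w[good] = 1.0 / d ** power
        weights[b] = w / w.sum()
    return weights


def interpolate_channels(rec: Recording, bad: list[str],
                         montage: Montage | None = None) -> Recording:
    """Replace bad channels by an inverse-distance-weighted average of the
    remaining good channels."""
    if montage is None:
        montage = default_montage()
    if not bad:
        return rec.copy()
    unknown = [b for b in bad if b not in montage.names]
    if unknown:
        raise KeyError(f"bad channels not in montage: {unknown}")
    missing = [b for b in bad if b not in rec.channel_labels]
    if missing:
        raise KeyError(f"bad channels not in recording: {missing}")
    n_good = len([n for n in montage.names
                  if n in rec.channel_labels and n not in bad])
    if n_good < 3:
        raise ValueError(
            f"only {n_good} good montage channels remain; need at least 3"
        )
    weights = interpolation_weights(montage, bad)
    out = rec.data.copy()
    row = {lb: i for i, lb in enumerate(rec.channel_labels)}
    for b, w in weights.items():
        acc = np.zeros(rec.n_samples)
        for name, wi in zip(montage.names, w):
            if wi > 0 and name in row:
                acc += wi * rec.data[row[name]]
        out[row[b]] = acc
    return Recording(out, rec.rate, list(rec.channel_labels), dict(rec.meta))


def extract_epochs(rec: Recording, events: EventList,
                   window: tuple[float, float] = DEFAULT_EPOCH_WINDOW) -> EpochSet:
    """Slice trials x channels x samples around each onset.

    The sample window is half-open: [onset + round(t_min*rate),
    onset + round(t_min*rate) + n), with n = round((t_max - t_min)*rate).
    Events whose window leaves the recording are dropped with a warning.
    """
    t_min, t_max = window
    if t_max <= t_min:
        raise ValueError(f"empty epoch window {window}")
    n_pre = int(round(-t_min * rec.rate))
    n_samp = int(round((t_max - t_min) * rec.rate))
    times = (np.arange(n_samp) - n_pre) / rec.rate

    trials, labels, onsets = [], [], []
    n_dropped = 0
    for onset, label in zip(events.onsets, events.labels):
        start = int(onset) - n_pre
        stop = start + n_samp
        if start < 0 or stop > rec.n_samples:
            n_dropped += 1
            continue
        trials.append(rec.data[:, start:stop])
        labels.append(label)
        onsets.append(int(onset))
    if n_dropped:
        log.warning("dropped %d event(s) too close to a recording edge",
                    n_dropped)
    tensor = (np.stack(trials) if trials
              else np.empty((0, rec.n_channels, n_samp)))
    return EpochSet(
        tensor=tensor,
        epoch_times=times,
        labels=labels,
        keep_mask=np.ones(len(trials), dtype=bool),
        rate=rec.rate,
        channel_labels=list(rec.channel_labels),
        onsets=np.asarray(onsets, dtype=np.int64),
    )


@dataclass(frozen=True)
class BehavioralCounts:
    false_positives: int
    false_negatives: int


def behavioral_reject(
    epochs: EpochSet, events: EventList,
    response_window: float = DEFAULT_RESPONSE_WINDOW_S,
) -> tuple[EpochSet, BehavioralCounts]:
    """Clear the keep-mask for behavioral errors.

    A target with no button press inside (0, response_window] seconds after
    onset is a false negative; a non-target with a press in that window is a
    false positive. Both are rejected.
    """
    if len(events) != epochs.n_trials:
        raise ValueError(
            f"{len(events)} events do not align with {epochs.n_trials} epochs"
        )
    if epochs.onsets is None:
        raise ValueError("epochs carry no onset information")
    horizon = int(round(response_window * epochs.rate))
    responses = np.sort(events.responses)
    out = epochs.copy()
    n_fp = n_fn = 0
    for i, (onset, label) in enumerate(zip(out.onsets, out.labels)):
        lo = np.searchsorted(responses, onset, side="right")
        hi = np.searchsorted(responses, onset + horizon, side="right")
        pressed = hi > lo
        if label == TARGET and not pressed:
            if out.keep_mask[i]:
                n_fn += 1
            out.keep_mask[i] = False
        elif label != TARGET and pressed:
            if out.keep_mask[i]:
                n_fp += 1
            out.keep_mask[i] = False
    return out, BehavioralCounts(false_positives=n_fp, false_negatives=n_fn)
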