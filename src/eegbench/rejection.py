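"""Amplitude-based epoch rejection.

The per-trial statistic is the peak-to-peak amplitude (max minus min) inside
a sliding window, maximized over windows and then over channels; an epoch is
rejected when ANY montage channel exceeds the threshold. Partial windows at
the epoch tail are evaluated too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EpochSet

__all__ = [
    "RejectionCurve",
    "epoch_p2p",
    "reject_threshold",
    "threshold_sweep",
    "amplitude_histogram",
    "match_rejection",
    "default_thresholds",
]

DEFAULT_WIN_MS = 200.0
DEFAULT_STEP_MS = 100.0
DEFAULT_THRESHOLD_UV = 75.0
DEFAULT_BIN_WIDTH_UV = 25.0


def default_thresholds() -> np.ndarray:
    """75 to 400 μV in 25 μV steps (14 values)."""
    return np.arange(75.0, 400.0 + 1e-9, 25.0)


@dataclass
class RejectionCurve:
    thresholds: np.ndarray  # μV
    rejection_rate: np.ndarray  # fraction in [0, 1]
    n_total: int

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=np.float64)
        self.rejection_rate = np.asarray(self.rejection_rate, dtype=np.float64)
        if len(self.thresholds) != len(self.rejection_rate):
            raise ValueError("thresholds and rates differ in length")
        if np.any(np.diff(self.rejection_rate) > 1e-12):
            raise ValueError("rejection rate must be non-increasing")

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({
            "threshold_uv": self.thresholds,
            "rejection_rate": self.rejection_rate,
            "n": self.n_total,
        }).to_csv(path, index=False)


def epoch_p2p(epochs: EpochSet, win_ms: float = DEFAULT_WIN_MS,
              step_ms: float = DEFAULT_STEP_MS) -> np.ndarray:
    """Per-trial sliding-window peak-to-peak amplitude in μV.

    Returns one value per trial (kept or not): the maximum over channels of
    the maximum over windows of (max - min) within the window.
    """
    n_samp = epochs.tensor.shape[2]
    win = int(round(win_ms * epochs.rate / 1000.0))
    step = int(round(step_ms * epochs.rate / 1000.0))
    if step <= 0:
        raise ValueError("step must be positive")
    if win <= 0 or win > n_samp:
        raise ValueError(
            f"window of {win} samples invalid for epochs of {n_samp} samples"
        )
    out = np.zeros(epochs.n_trials)
    starts = range(0, n_samp, step)
    for i in range(epochs.n_trials):
        trial = epochs.tensor[i]  # channels x samples
        best = 0.0
        for s in starts:
            seg = trial[:, s:s + win]
            best = max(best, float(np.max(seg.max(axis=1) - seg.min(axis=1))))
        out[i] = best
    return out


def reject_threshold(epochs: EpochSet, thr: float = DEFAULT_THRESHOLD_UV,
                     win_ms: float = DEFAULT_WIN_MS,
                     step_ms: float = DEFAULT_STEP_MS) -> tuple[EpochSet, float]:
    """Clear the keep-mask where the sliding-window p2p exceeds ``thr``.

    Only trials that were still kept on entry are eligible; the returned
    rate is rejected / eligible (0 when nothing was eligible).
    """
    if thr <= 0:
        raise ValueError("threshold must be positive")
    p2p = epoch_p2p(epochs, win_ms, step_ms)
    out = epochs.copy()
    eligible = out.keep_mask.copy()
    reject = eligible & (p2p > thr)
    out.keep_mask[reject] = False
    n_elig = int(eligible.sum())
    rate = float(reject.sum()) / n_elig if n_elig else 0.0
    return out, rate


def threshold_sweep(epochs: EpochSet,
                    thresholds: np.ndarray | None = None,
                    win_ms: float = DEFAULT_WIN_MS,
                    step_ms: float = DEFAULT_STEP_MS) -> RejectionCurve:
    """Rejection rate among currently-kept trials at each threshold."""
    if thresholds is None:
        thresholds = default_thresholds()
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if thresholds.size == 0 or np.any(thresholds <= 0):
        raise ValueError("thresholds must be non-empty and positive")
    p2p = epoch_p2p(epochs, win_ms, step_ms)[epochs.keep_mask]
    n = p2p.size
    rates = np.array([
        float((p2p > thr).sum()) / n if n else 0.0 for thr in thresholds
    ])
    return RejectionCurve(thresholds, rates, n)


def amplitude_histogram(epochs: EpochSet,
                        bin_width: float = DEFAULT_BIN_WIDTH_UV,
                        win_ms: float = DEFAULT_WIN_MS,
                        step_ms: float = DEFAULT_STEP_MS,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of kept epochs per peak-to-peak amplitude bin.

    Bins are left-open intervals (k*w, (k+1)*w]; an exactly-zero amplitude
    is counted in the first bin. Returns (bin_edges, fractions) where
    bin_edges has one more entry than fractions.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    p2p = epoch_p2p(epochs, win_ms, step_ms)[epochs.keep_mask]
    if p2p.size == 0:
        return np.array([0.0, bin_width]), np.array([0.0])
    idx = np.maximum(np.ceil(p2p / bin_width).astype(int) - 1, 0)
    n_bins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_bins)
    edges = np.arange(n_bins + 1) * bin_width
    return edges, counts / p2p.size


def match_rejection(epochs_a: EpochSet, epochs_b: EpochSet,
                    win_ms: float = DEFAULT_WIN_MS,
                    step_ms: float = DEFAULT_STEP_MS,
                    ) -> tuple[EpochSet, EpochSet]:
    """Equalize rejected-epoch counts across two thresholded conditions.

    Additional survivors are removed from the less-rejected set in
    descending peak-to-peak order (ties: later trial index first) until both
    sets have rejected the same number of epochs.
    """
    a, b = epochs_a.copy(), epochs_b.copy()
    deficit = a.n_rejected - b.n_rejected
    if deficit == 0:
        return a, b
    donor = b if deficit > 0 else a
    n_extra = abs(deficit)
    survivors = np.flatnonzero(donor.keep_mask)
    if n_extra > survivors.size:
        raise ValueError(
            f"need to drop {n_extra} epochs but only {survivors.size} remain"
        )
    p2p = epoch_p2p(donor, win_ms, step_ms)[survivors]
    # descending p2p; ties broken by dropping the later-indexed trial first
    order = sorted(range(survivors.size),
                   key=lambda i: (-p2p[i], -survivors[i]))
    drop = survivors[[order[i] for i in range(n_extra)]]
    donor.keep_mask[drop] = False
    return a, b
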