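"""Domain types shared by every pipeline stage.

All amplitudes are microvolts, all sample indices are 0-based, and time 0 of
an epoch is the stimulus onset. Readers convert to these conventions at
ingest so downstream code never handles raw ADC units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "EventList",
    "EpochSet",
    "ERPWaveform",
    "Montage",
    "BandSet",
    "MetricTable",
    "default_montage",
    "default_bands",
    "MONTAGE_12",
    "TARGET",
    "NONTARGET",
    "read_recording",
    "write_recording",
    "write_recording_csv",
    "select_montage",
    "normalize_label",
]

TARGET = "target"
NONTARGET = "non-target"

#: The 12-channel benchmark montage, in canonical order.
MONTAGE_12 = (
    "Fpz", "F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4", "O1", "O2",
)

# Unit-sphere positions (x = right, y = anterior, z = up) computed from the
# conventional 10-20 inclination/azimuth angles. Only relative distances
# matter (interpolation weights), so approximate angles are acceptable.
_DEG = np.pi / 180.0


def _pos(incl_deg: float, azim_deg: float) -> tuple[float, float, float]:
    """Unit vector from inclination (from vertex) and azimuth (from anterior
    midline, positive toward the right ear)."""
    a, b = incl_deg * _DEG, azim_deg * _DEG
    return (
        float(np.sin(a) * np.sin(b)),
        float(np.sin(a) * np.cos(b)),
        float(np.cos(a)),
    )


_POSITIONS_12: dict[str, tuple[float, float, float]] = {
    "Fpz": _pos(72, 0),
    "F3": _pos(48, -40),
    "Fz": _pos(36, 0),
    "F4": _pos(48, 40),
    "C3": _pos(36, -90),
    "Cz": _pos(0, 0),
    "C4": _pos(36, 90),
    "P3": _pos(48, -140),
    "Pz": _pos(36, 180),
    "P4": _pos(48, 140),
    "O1": _pos(72, -162),
    "O2": _pos(72, 162),
}

_ALIASES = {
    "fpz": "Fpz",
    "fp z": "Fpz",
}


def normalize_label(label: str) -> str:
    """Map a vendor channel label onto its canonical 10-20 spelling.

    Matching is case-insensitive; labels that are not part of the benchmark
    montage are returned verbatim.
    """
    key = label.strip().lower()
    if key in _ALIASES:
        return _ALIASES[key]
    for name in MONTAGE_12:
        if key == name.lower():
            return name
    return label.strip()


@dataclass
class Recording:
    """Continuous multi-channel EEG in microvolts."""

    data: np.ndarray  # channels x samples, float64, μV
    rate: float  # Hz
    channel_labels: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("recording data must be channels x samples")
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.data.shape[0]} data rows"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def copy(self) -> "Recording":
        return Recording(
            self.data.copy(), self.rate, list(self.channel_labels),
            dict(self.meta),
        )


@dataclass
class EventList:
    """Stimulus onsets (sample indices), class labels, and button presses."""

    onsets: np.ndarray  # int sample indices, strictly increasing
    labels: list[str]  # TARGET / NONTARGET per onset
    responses: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.int64)
        self.responses = np.asarray(self.responses, dtype=np.int64)
        if len(self.labels) != len(self.onsets):
            raise ValueError("labels and onsets must have equal length")
        if len(self.onsets) > 1 and not (np.diff(self.onsets) > 0).all():
            raise ValueError("onsets must be strictly increasing")
        bad = set(self.labels) - {TARGET, NONTARGET}
        if bad:
            raise ValueError(f"unknown event labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.onsets)

    @property
    def n_targets(self) -> int:
        return sum(1 for lb in self.labels if lb == TARGET)

    def to_json(self, path: str | Path, rate: float | None = None) -> None:
        doc = {
            "onsets": self.onsets.tolist(),
            "labels": list(self.labels),
            "responses": self.responses.tolist(),
        }
        if rate is not None:
            doc["rate"] = rate
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "EventList":
        doc = json.loads(Path(path).read_text())
        return cls(
            np.asarray(doc["onsets"], dtype=np.int64),
            list(doc["labels"]),
            np.asarray(doc.get("responses", []), dtype=np.int64),
        )


@dataclass
class EpochSet:
    """Trials x channels x samples tensor with a mutable keep-mask."""

    tensor: np.ndarray  # trials x channels x samples, μV
    epoch_times: np.ndarray  # seconds relative to onset
    labels: list[str]
    keep_mask: np.ndarray  # bool per trial
    rate: float
    channel_labels: list[str]
    onsets: np.ndarray | None = None  # original onset sample of each trial

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=np.float64)
        self.epoch_times = np.asarray(self.epoch_times, dtype=np.float64)
        self.keep_mask = np.asarray(self.keep_mask, dtype=bool)
        if self.tensor.ndim != 3:
            raise ValueError("epoch tensor must be trials x channels x samples")
        n_trials, n_ch, n_samp = self.tensor.shape
        if len(self.keep_mask) != n_trials:
            raise ValueError("keep_mask length must equal trial count")
        if len(self.labels) != n_trials:
            raise ValueError("labels length must equal trial count")
        if len(self.epoch_times) != n_samp:
            raise ValueError("epoch_times length must equal sample count")
        if len(self.channel_labels) != n_ch:
            raise ValueError("channel_labels must match channel axis")

    @property
    def n_trials(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.keep_mask.sum())

    @property
    def n_rejected(self) -> int:
        return self.n_trials - self.n_kept

    def kept(self) -> np.ndarray:
        """Tensor restricted to kept trials."""
        return self.tensor[self.keep_mask]

    def kept_labels(self) -> list[str]:
        return [lb for lb, k in zip(self.labels, self.keep_mask) if k]

    def time_mask(self, t_min: float, t_max: float) -> np.ndarray:
        """Boolean sample mask for epoch_times in [t_min, t_max)."""
        eps = 0.5 / self.rate
        return (self.epoch_times >= t_min - eps) & (self.epoch_times < t_max - eps)

    def copy(self) -> "EpochSet":
        return EpochSet(
            self.tensor.copy(), self.epoch_times.copy(), list(self.labels),
            self.keep_mask.copy(), self.rate, list(self.channel_labels),
            None if self.onsets is None else self.onsets.copy(),
        )


@dataclass
class ERPWaveform:
    """Per-channel average waveform for one stimulus class."""

    data: np.ndarray  # channels x samples, μV
    n_epochs: int
    label: str
    epoch_times: np.ndarray
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.n_epochs < 1:
            raise ValueError("an ERP averages at least one epoch")
        if not np.isfinite(self.data).all():
            raise ValueError("ERP contains non-finite samples")


@dataclass(frozen=True)
class Montage:
    """Named scalp positions on the unit sphere."""

    names: tuple[str, ...]
    positions: Mapping[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        missing = [n for n in self.names if n not in self.positions]
        if missing:
            raise ValueError(f"montage names without positions: {missing}")

    def __len__(self) -> int:
        return len(self.names)

    def position_array(self) -> np.ndarray:
        return np.array([self.positions[n] for n in self.names])


def default_montage() -> Montage:
    """The 12-channel benchmark montage."""
    return Montage(names=MONTAGE_12, positions=dict(_POSITIONS_12))


@dataclass(frozen=True)
class BandSet:
    """Named, non-overlapping frequency intervals in Hz."""

    bands: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        intervals = sorted(self.bands.values())
        for lo, hi in intervals:
            if not 0 < lo < hi:
                raise ValueError(f"invalid band ({lo}, {hi})")
        for (_, hi), (lo2, _) in zip(intervals, intervals[1:]):
            if lo2 < hi:
                raise ValueError("bands overlap")

    def names(self) -> list[str]:
        return list(self.bands)

    def items(self):
        return self.bands.items()

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.bands[name]


def default_bands() -> BandSet:
    return BandSet({
        "delta": (1.0, 4.0),
        "theta": (4.0, 8.0),
        "alpha": (8.0, 13.0),
        "beta": (13.0, 30.0),
        "gamma": (30.0, 80.0),
    })


class MetricTable:
    """Long-format metric store keyed by (subject, system, condition,
    channel, metric)."""

    COLUMNS = ["subject", "system", "condition", "channel", "metric", "value"]

    def __init__(self, frame: pd.DataFrame | None = None) -> None:
        if frame is None:
            frame = pd.DataFrame(columns=self.COLUMNS)
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"metric table missing columns: {sorted(missing)}")
        self.frame = frame[self.COLUMNS].reset_index(drop=True)
        keys = self.frame[self.COLUMNS[:-1]]
        if keys.duplicated().any():
            raise ValueError("duplicate metric keys")

    def add(self, subject: str, system: str, condition: str, channel: str,
            metric: str, value: float) -> None:
        row = pd.DataFrame(
            [[subject, system, condition, channel, metric, float(value)]],
            columns=self.COLUMNS,
        )
        frame = (row if self.frame.empty
                 else pd.concat([self.frame, row], ignore_index=True))
        if frame[self.COLUMNS[:-1]].duplicated().any():
            raise ValueError(
                f"duplicate key ({subject}, {system}, {condition}, "
                f"{channel}, {metric})"
            )
        self.frame = frame

    def get(self, **key: str) -> pd.DataFrame:
        out = self.frame
        for col, val in key.items():
            if col not in self.COLUMNS:
                raise KeyError(col)
            out = out[out[col] == val]
        return out

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.frame.to_json(orient="records"))

    @classmethod
    def from_csv(cls, path: str | Path) -> "MetricTable":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# I/O


def write_recording_csv(rec: Recording, path: str | Path,
                        events: EventList | None = None) -> None:
    """Write the CSV dialect: header of channel labels, one row per sample,
    sidecar JSON (<path>.json) with rate, meta and optional events."""
    path = Path(path)
    frame = pd.DataFrame(rec.data.T, columns=rec.channel_labels)
    frame.to_csv(path, index=False)
    sidecar: dict = {"rate": rec.rate, "meta": rec.meta}
    if events is not None:
        sidecar["events"] = {
            "onsets": events.onsets.tolist(),
            "labels": list(events.labels),
            "responses": events.responses.tolist(),
        }
    Path(str(path) + ".json").write_text(json.dumps(sidecar))


def _read_csv_recording(path: Path) -> Recording:
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise ValueError(
            f"missing sampling-rate sidecar {sidecar_path.name} for {path}"
        )
    sidecar = json.loads(sidecar_path.read_text())
    if "rate" not in sidecar:
        raise ValueError(f"sidecar {sidecar_path} has no 'rate'")
    frame = pd.read_csv(path)
    if frame.shape[1] == 0:
        raise ValueError(f"{path}: no channels")
    labels = [normalize_label(c) for c in frame.columns]
    return Recording(
        frame.to_numpy(dtype=np.float64).T,
        float(sidecar["rate"]),
        labels,
        dict(sidecar.get("meta", {})),
    )


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording from BDF, EDF or the CSV dialect.

    ``format`` may be ``"bdf"``, ``"edf"`` or ``"csv"``; when omitted it is
    inferred from the file suffix. Amplitudes are converted to μV and labels
    mapped to canonical 10-20 spellings.
    """
    from . import _edf

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    format = format.lower()
    if format == "csv":
        return _read_csv_recording(path)
    if format in ("bdf", "edf"):
        data, rate, labels, meta = _edf.read(path)
        if data.shape[0] == 0:
            raise ValueError(f"{path}: no channels")
        return Recording(data, rate, [normalize_label(l) for l in labels], meta)
    raise ValueError(f"unknown recording format {format!r}")


def write_recording(rec: Recording, path: str | Path,
                    format: str | None = None,
                    events: EventList | None = None) -> None:
    """Write a recording as BDF, EDF or the CSV dialect (suffix-inferred)."""
    from . import _edf

    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    format = format.lower()
    if format == "csv":
        write_recording_csv(rec, path, events=events)
    elif format in ("bdf", "edf"):
        _edf.write(path, rec.data, rec.rate, list(rec.channel_labels),
                   kind=format, meta=rec.meta)
        if events is not None:
            events.to_json(Path(str(path) + ".events.json"), rate=rec.rate)
    else:
        raise ValueError(f"unknown recording format {format!r}")


def select_montage(rec: Recording, montage: Montage | None = None) -> Recording:
    """Restrict a recording to the montage channels, in montage order."""
    if montage is None:
        montage = default_montage()
    index = {normalize_label(lb): i for i, lb in enumerate(rec.channel_labels)}
    rows = []
    for name in montage.names:
        if name not in index:
            raise KeyError(f"channel {name!r} not present in recording")
        rows.append(index[name])
    return Recording(
        rec.data[rows].copy(), rec.rate, list(montage.names), dict(rec.meta),
    )
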