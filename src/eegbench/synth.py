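"""Synthetic auditory-oddball session generator.

Produces continuous 12-channel recordings with a P300-like evoked bump on
target trials, 1/f background noise, an alpha oscillation, an optional
gait-locked periodic artifact (fundamental plus two harmonics) and optional
blinks, together with the event schedule and simulated button presses.
Everything is deterministic under the design/model seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core import (
    EventList,
    Montage,
    NONTARGET,
    Recording,
    TARGET,
    default_montage,
)

__all__ = [
    "SessionDesign",
    "SignalModel",
    "schedule",
    "simulate",
    "make_fixture_pair",
    "default_topography",
    "default_gait_weights",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SessionDesign:
    """Oddball block structure: 4 blocks of 160 trials, 25% targets,
    400 ms stimuli with a 1420-1580 ms inter-stimulus interval."""

    n_blocks: int = 4
    trials_per_block: int = 160
    p_target: float = 0.25
    isi_range_ms: tuple[float, float] = (1420.0, 1580.0)
    stim_ms: float = 400.0
    rate: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_target < 1:
            raise ValueError("p_target must be in [0, 1)")
        if self.isi_range_ms[0] > self.isi_range_ms[1]:
            raise ValueError("isi range lower bound exceeds upper bound")
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("need at least one block of one trial")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


def default_topography() -> dict[str, float]:
    """Central-parietal P300 scalp gain (maximum at Pz)."""
    return {
        "Fpz": 0.5, "F3": 0.5, "Fz": 0.6, "F4": 0.5,
        "C3": 0.75, "Cz": 0.9, "C4": 0.75,
        "P3": 0.9, "Pz": 1.0, "P4": 0.9,
        "O1": 0.4, "O2": 0.4,
    }


def default_gait_weights() -> dict[str, float]:
    """Gait-artifact gain decaying from occiput to front."""
    return {
        "Fpz": 0.3, "F3": 0.4, "Fz": 0.4, "F4": 0.4,
        "C3": 0.6, "Cz": 0.6, "C4": 0.6,
        "P3": 0.8, "Pz": 0.8, "P4": 0.8,
        "O1": 1.0, "O2": 1.0,
    }


@dataclass(frozen=True)
class SignalModel:
    """Amplitudes and rates of the simulated signal components (μV, Hz)."""

    p300_amp: float = 8.0
    p300_latency_ms: float = 400.0
    p300_width_ms: float = 150.0  # full width at half maximum
    topography: Mapping[str, float] | None = None
    noise_sd: float = 5.0
    noise_exponent: float = 1.0
    alpha_amp: float = 2.0
    alpha_hz: float = 10.0
    gait_amp: float = 0.0
    gait_hz: float = 1.2
    gait_weights: Mapping[str, float] | None = None
    blink_rate: float = 0.0  # per minute; blink-free by default
    blink_amp: float = 80.0
    response_accuracy: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p300_amp", "noise_sd", "alpha_amp", "gait_amp",
                     "blink_rate", "blink_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.gait_hz <= 0:
            raise ValueError("gait_hz must be positive")
        if not 0 <= self.response_accuracy <= 1:
            raise ValueError("response_accuracy must be in [0, 1]")


def schedule(design: SessionDesign) -> EventList:
    """Generate the event schedule for one session.

    Targets are assigned per block by exact count (round(p_target * trials)
    of them), shuffled within the block; onsets are spaced by stimulus
    duration plus a uniform inter-stimulus interval. Deterministic under
    ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    n_t_exact = design.p_target * design.trials_per_block
    n_t = int(round(n_t_exact))
    if abs(n_t - n_t_exact) > 1e-9:
        log.warning("p_target * trials_per_block = %.3f is non-integral; "
                    "rounding to %d targets per block", n_t_exact, n_t)
    labels: list[str] = []
    for _ in range(design.n_blocks):
        block = [TARGET] * n_t + [NONTARGET] * (design.trials_per_block - n_t)
        rng.shuffle(block)
        labels.extend(block)

    lead = int(round(1.0 * design.rate))  # 1 s of pre-session signal
    gaps_s = (design.stim_ms
              + rng.uniform(*design.isi_range_ms, size=len(labels) - 1)) / 1000.0
    onsets = np.empty(len(labels), dtype=np.int64)
    onsets[0] = lead
    onsets[1:] = lead + np.cumsum(np.round(gaps_s * design.rate).astype(np.int64))
    return EventList(onsets=onsets, labels=labels)


def _pink_noise(rng: np.random.Generator, n: int, rate: float,
                sd: float, exponent: float) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _gaussian_bump(n_samples: int, center: int, amp: float,
                   sigma_samples: float) -> tuple[slice, np.ndarray]:
    half = int(np.ceil(4 * sigma_samples))
    lo = max(0, center - half)
    hi = min(n_samples, center + half + 1)
    idx = np.arange(lo, hi)
    return slice(lo, hi), amp * np.exp(-0.5 * ((idx - center) / sigma_samples) ** 2)


def simulate(design: SessionDesign, model: SignalModel,
             montage: Montage | None = None,
             events: EventList | None = None) -> tuple[Recording, EventList]:
    """Render a continuous recording plus events with button presses.

    ``events`` lets two conditions share one schedule; when omitted the
    schedule is generated from ``design.seed``.
    """
    if montage is None:
        montage = default_montage()
    if events is None:
        events = schedule(design)
    rng = np.random.default_rng(model.seed)
    rate = design.rate
    n = int(events.onsets[-1]) + int(round(1.5 * rate))
    n_ch = len(montage)
    t = np.arange(n) / rate
    data = np.zeros((n_ch, n))

    topo = dict(default_topography())
    if model.topography is not None:
        topo.update(model.topography)
    gait_w = dict(default_gait_weights())
    if model.gait_weights is not None:
        gait_w.update(model.gait_weights)

    # background: 1/f noise + alpha oscillation (random phase per channel)
    for c, name in enumerate(montage.names):
        if model.noise_sd > 0:
            data[c] += _pink_noise(rng, n, rate, model.noise_sd,
                                   model.noise_exponent)
        if model.alpha_amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            data[c] += model.alpha_amp * np.sin(
                2 * np.pi * model.alpha_hz * t + phase)

    # gait-locked artifact: fundamental + 2 harmonics, posterior-weighted
    if model.gait_amp > 0:
        for c, name in enumerate(montage.names):
            w = gait_w.get(name, 0.5)
            for h in range(3):
                phase = rng.uniform(0, 2 * np.pi)
                data[c] += (model.gait_amp * w / 2 ** h) * np.sin(
                    2 * np.pi * model.gait_hz * (h + 1) * t + phase)

    # P300: Gaussian bump on target trials, peak exactly on the sample grid
    if model.p300_amp > 0:
        sigma = (model.p300_width_ms / 1000.0 * rate) / (2 * np.sqrt(2 * np.log(2)))
        lat = int(round(model.p300_latency_ms / 1000.0 * rate))
        gains = np.array([topo.get(nm, 0.5) for nm in montage.names])
        for onset, label in zip(events.onsets, events.labels):
            if label != TARGET:
                continue
            sl, bump = _gaussian_bump(n, int(onset) + lat, model.p300_amp, sigma)
            data[:, sl] += gains[:, None] * bump[None, :]

    # blinks: stereotyped 400 ms biphasic transient, frontal-weighted
    if model.blink_rate > 0:
        n_blinks = rng.poisson(model.blink_rate * (n / rate) / 60.0)
        blink_w = {"Fpz": 1.0, "F3": 0.5, "Fz": 0.5, "F4": 0.5}
        sigma_b = 0.08 * rate
        for _ in range(n_blinks):
            center = int(rng.uniform(0, n))
            sl, bump = _gaussian_bump(n, center, model.blink_amp, sigma_b)
            sl2, bump2 = _gaussian_bump(n, center + int(0.12 * rate),
                                        -0.4 * model.blink_amp, sigma_b)
            for c, name in enumerate(montage.names):
                w = blink_w.get(name, 0.1)
                data[c, sl] += w * bump
                data[c, sl2] += w * bump2

    # button presses: hits on targets, sparse false alarms on non-targets
    presses = []
    for onset, label in zip(events.onsets, events.labels):
        if label == TARGET:
            pressed = rng.random() < model.response_accuracy
        else:
            pressed = rng.random() < (1.0 - model.response_accuracy) / 10.0
        if pressed:
            rt = 0.35 + 0.3 * rng.random()  # 350-650 ms
            presses.append(int(onset) + int(round(rt * rate)))
    out_events = EventList(
        onsets=events.onsets.copy(),
        labels=list(events.labels),
        responses=np.array(sorted(presses), dtype=np.int64),
    )
    rec = Recording(
        data, rate, list(montage.names),
        meta={"source": "eegbench-synth", "design_seed": design.seed,
              "model_seed": model.seed},
    )
    return rec, out_events


def make_fixture_pair(
    design: SessionDesign,
    model_seated: SignalModel,
    model_walking: SignalModel,
    montage: Montage | None = None,
) -> tuple[tuple[Recording, EventList], tuple[Recording, EventList]]:
    """Two sessions sharing one schedule: a seated/walking contrast.

    The conditions share the event sequence (and, when the models agree on
    the evoked parameters, the P300 template) and differ only in the
    artifact/noise parameters of their models.
    """
    events = schedule(design)
    seated = simulate(design, model_seated, montage=montage, events=events)
    walking = simulate(design, model_walking, montage=montage, events=events)
    seated[0].meta["condition"] = "seated"
    walking[0].meta["condition"] = "walking"
    return seated, walking
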