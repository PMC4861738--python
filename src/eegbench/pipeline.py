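"""Config-driven end-to-end benchmark runs.

The stage order is fixed: filtering -> montage selection -> epoching ->
behavioral rejection -> amplitude-threshold rejection (-> matched-count
rejection when two conditions are present) -> metrics. Every run writes its
full effective configuration to a JSON log so outputs are auditable and
byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as mx
from . import preprocess as pp
from . import rejection as rj
from .core import (
    EpochSet,
    EventList,
    MetricTable,
    NONTARGET,
    Recording,
    TARGET,
    default_bands,
    default_montage,
    read_recording,
    select_montage,
)

__all__ = ["DEFAULT_CONFIG", "run_benchmark", "compare_conditions", "RunResult"]

DEFAULT_CONFIG: dict = {
    "subject": "S01",
    "system": "SIM",
    "highpass_hz": 1.0,
    "notch_hz": 60.0,
    "notch_harmonics": 1,
    "epoch_window": [-0.3, 0.8],
    "response_window_s": 1.4,
    "threshold_uv": 75.0,
    "sweep": {"start": 75.0, "stop": 400.0, "step": 25.0},
    "hist_bin_uv": 25.0,
    "psn_window": [-0.3, 0.0],
    "p300_window": [0.3, 0.5],
    "p2p_win_ms": 200.0,
    "p2p_step_ms": 100.0,
}


@dataclass
class RunResult:
    table: MetricTable
    curves: dict[str, rj.RejectionCurve]
    similarity: pd.DataFrame | None
    log: dict
    epochs: dict[str, EpochSet] = field(default_factory=dict)


def _load_condition(cond: dict) -> tuple[Recording, EventList]:
    rec = read_recording(cond["recording"], cond.get("format"))
    if "events" in cond and cond["events"]:
        events = EventList.from_json(cond["events"])
    else:
        sidecar = Path(str(cond["recording"]) + ".json")
        doc = json.loads(sidecar.read_text())
        if "events" not in doc:
            raise ValueError(f"no events given and none in sidecar {sidecar}")
        ev = doc["events"]
        events = EventList(
            np.asarray(ev["onsets"], dtype=np.int64), list(ev["labels"]),
            np.asarray(ev.get("responses", []), dtype=np.int64),
        )
    return rec, events


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


def _prepare_condition(name: str, rec: Recording, events: EventList,
                       cfg: dict, log: dict) -> EpochSet:
    montage = default_montage()
    if cfg.get("highpass_hz"):
        rec = _stage(f"{name}:highpass", pp.highpass, rec, cfg["highpass_hz"])
    if cfg.get("notch_hz"):
        rec = _stage(f"{name}:notch", pp.notch, rec, cfg["notch_hz"],
                     harmonics=cfg.get("notch_harmonics", 1))
    rec = _stage(f"{name}:montage", select_montage, rec, montage)
    epochs = _stage(f"{name}:epoch", pp.extract_epochs, rec, events,
                    tuple(cfg["epoch_window"]))
    epochs, counts = _stage(f"{name}:behavioral", pp.behavioral_reject,
                            epochs, events, cfg["response_window_s"])
    log[f"{name}.false_positives"] = counts.false_positives
    log[f"{name}.false_negatives"] = counts.false_negatives
    log[f"{name}.n_trials"] = epochs.n_trials
    log[f"{name}.n_behaviorally_valid"] = epochs.n_kept
    return epochs


def _condition_metrics(table: MetricTable, subject: str, system: str,
                       name: str, epochs: EpochSet, cfg: dict) -> None:
    psn_all = mx.psn(epochs, tuple(cfg["psn_window"]))
    psn_target = mx.psn(epochs, tuple(cfg["psn_window"]), label=TARGET)
    erp_t = mx.average_erp(epochs, TARGET)
    snr = mx.snr(erp_t, psn_target, tuple(cfg["p300_window"]))
    cv_ch, cv_all, _ = mx.cv_erp(epochs, tuple(cfg["p300_window"]))
    bp = mx.band_power(epochs, default_bands())
    labels = epochs.channel_labels
    for c, ch in enumerate(labels):
        table.add(subject, system, name, ch, "PSN", psn_all.channel_mean[c])
        table.add(subject, system, name, ch, "SNR", snr[c])
        table.add(subject, system, name, ch, "CV_ERP", cv_ch[c])
        for band in bp.per_channel:
            table.add(subject, system, name, ch, f"power_{band}",
                      bp.per_channel[band][c])
    table.add(subject, system, name, "all", "PSN", psn_all.grand_mean)
    table.add(subject, system, name, "all", "SNR", float(np.mean(snr)))
    table.add(subject, system, name, "all", "CV_ERP", cv_all)
    for band, val in bp.channel_avg.items():
        table.add(subject, system, name, "all", f"power_{band}", val)


def run_benchmark(config: dict, out_dir: str | Path | None = None) -> RunResult:
    """Execute the full pipeline for one or two conditions.

    ``config`` extends :data:`DEFAULT_CONFIG` and must contain a
    ``conditions`` list of 1 or 2 entries, each with a ``recording`` path
    (events embedded in the CSV sidecar or given as an ``events`` JSON
    path). When ``out_dir`` is given, writes ``metrics.csv``,
    ``rejection_curve_<condition>.csv``, ``similarity.csv`` (two-condition
    runs) and ``run_log.json``.
    """
    cfg = {**DEFAULT_CONFIG, **config}
    conditions = cfg.get("conditions")
    if not conditions or len(conditions) > 2:
        raise ValueError("config needs a 'conditions' list of 1 or 2 entries")
    subject, system = cfg["subject"], cfg["system"]
    log: dict = {"config": {k: v for k, v in cfg.items() if k != "conditions"},
                 "conditions": [c.get("name") for c in conditions],
                 "stage_order": [
                     "highpass", "notch", "montage", "epoch", "behavioral",
                     "threshold", "match", "metrics",
                 ]}

    prepared: dict[str, EpochSet] = {}
    for cond in conditions:
        name = cond.get("name", "condition")
        rec, events = _load_condition(cond)
        prepared[name] = _prepare_condition(name, rec, events, cfg, log)

    sweep = cfg["sweep"]
    thresholds = np.arange(sweep["start"], sweep["stop"] + 1e-9, sweep["step"])
    curves = {
        name: rj.threshold_sweep(ep, thresholds, cfg["p2p_win_ms"],
                                 cfg["p2p_step_ms"])
        for name, ep in prepared.items()
    }

    thresholded: dict[str, EpochSet] = {}
    for name, ep in prepared.items():
        out, rate = rj.reject_threshold(ep, cfg["threshold_uv"],
                                        cfg["p2p_win_ms"], cfg["p2p_step_ms"])
        log[f"{name}.threshold_rejection_rate"] = rate
        thresholded[name] = out

    names = list(thresholded)
    if len(names) == 2:
        a, b = rj.match_rejection(thresholded[names[0]], thresholded[names[1]],
                                  cfg["p2p_win_ms"], cfg["p2p_step_ms"])
        thresholded = {names[0]: a, names[1]: b}
    for name, ep in thresholded.items():
        log[f"{name}.n_kept"] = ep.n_kept

    table = MetricTable()
    for name, ep in thresholded.items():
        _stage(f"{name}:metrics", _condition_metrics, table, subject, system,
               name, ep, cfg)

    similarity = None
    if len(names) == 2:
        rows = []
        for label in (TARGET, NONTARGET):
            erps = [mx.average_erp(thresholded[n], label) for n in names]
            r = mx.scalar_similarity(erps[0], erps[1])
            for c, ch in enumerate(thresholded[names[0]].channel_labels):
                rows.append({"channel": ch, "label": label, "r": r[c],
                             "fisher_z": float(np.arctanh(np.clip(
                                 r[c], -1 + 1e-7, 1 - 1e-7)))})
        similarity = pd.DataFrame(rows)
        log["similarity.fisher_average"] = mx.fisher_average(
            similarity["r"].to_numpy())
        for band, val in mx.ratio_ws(
            mx.band_power(thresholded[names[1]], default_bands()),
            mx.band_power(thresholded[names[0]], default_bands()),
        ).items():
            table.add(subject, system, f"{names[1]}/{names[0]}", "all",
                      f"ratio_ws_{band}", val)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "metrics.csv")
        for name, curve in curves.items():
            curve.to_csv(out_dir / f"rejection_curve_{name}.csv")
        if similarity is not None:
            similarity.to_csv(out_dir / "similarity.csv", index=False)
        (out_dir / "run_log.json").write_text(json.dumps(log, indent=2,
                                                         sort_keys=True))
    return RunResult(table, curves, similarity, log, thresholded)


def compare_conditions(table_a: MetricTable,
                       table_b: MetricTable) -> pd.DataFrame:
    """Absolute percent change, 100*|a - b|/a, per (channel, metric).

    Adds one channel-averaged summary row per metric (channel = "mean").
    Raises when the two tables do not share exactly the same keys.
    """
    cols = ["channel", "metric"]
    a = table_a.frame.set_index(cols)["value"]
    b = table_b.frame.set_index(cols)["value"]
    if set(a.index) != set(b.index):
        missing = set(a.index) ^ set(b.index)
        raise ValueError(f"tables disagree on keys: {sorted(missing)[:5]} ...")
    b = b.reindex(a.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * np.abs(a - b) / np.abs(a)
    out = pct.reset_index().rename(columns={"value": "pct_change"})
    out.columns = ["channel", "metric", "pct_change"]
    per_channel = out[out["channel"] != "all"]
    summary = (per_channel.groupby("metric", as_index=False)["pct_change"]
               .mean().assign(channel="mean"))
    return pd.concat([out, summary[out.columns]], ignore_index=True)
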