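"""End-to-end study driver: simulate (or ingest) → detect → analyse → report.

Runs a whole synthetic FP-surveillance study — a cohort of muscles, each with
its own event rate, recording duration and electrode array — through the
detection and interval-statistics stages, and writes the probability-of-
observation curves, per-muscle summaries and plots. Everything is
deterministic under a fixed master seed.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .containers import ArrayGeometry, EventTrain, GroundTruth
from .detect import DetectionConfig, default_config, detect
from .intervals import (POOL_ALL, CumulativeCurve, IntervalSet, TrainSummary,
                        compute_intervals, duration_for_probability,
                        pool_and_cumulate, summarize_train)
from .io import write_event_train, write_ground_truth
from .simulate import FPWaveformModel, RenewalSpec, generate_event_train, \
    synthesize_recording

__all__ = ["StudyConfig", "StudyResult", "run_pipeline", "analyze_event_trains",
           "plot_curves"]

log = logging.getLogger("fpwatch.report")

_DEFAULT_PROBS = (0.5, 0.8, 0.9, 0.95, 0.99, 1.0)


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of a synthetic surveillance study.

    The defaults emulate the clinical study design the package targets:
    29 muscles, FP rates log-uniform over 3.5–139 events/min, gamma renewal
    intervals with shape 3.5 (interval skewness ≈ 1.07), recording durations
    uniform over 215–764 s. ``duration_scale`` shrinks all durations for
    quick signal-level benchmarks; ``simulate_recordings=False`` analyses the
    ground-truth trains directly (no signal synthesis or detection).
    """

    n_muscles: int = 29
    rate_range_per_min: tuple[float, float] = (3.5, 139.0)
    distribution: str = "gamma"
    shape: float = 3.5
    duration_range_s: tuple[float, float] = (215.0, 764.0)
    duration_scale: float = 1.0
    orders: tuple[int, ...] = (1, 2, 3, 4, 5)
    grid_step_s: float = 1.0
    pooling: str = POOL_ALL
    probabilities: tuple[float, ...] = _DEFAULT_PROBS
    simulate_recordings: bool = False
    snr: float = 10.0
    sample_rate_hz: float = 2000.0
    dead_channel_range: tuple[int, int] = (2, 5)
    detection: DetectionConfig | None = None
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_muscles < 1:
            raise ValueError("n_muscles must be >= 1")
        if not 0 < self.rate_range_per_min[0] <= self.rate_range_per_min[1]:
            raise ValueError("rate range must be positive and ordered")
        if not 0 < self.duration_range_s[0] <= self.duration_range_s[1]:
            raise ValueError("duration range must be positive and ordered")
        if self.duration_scale <= 0:
            raise ValueError("duration_scale must be positive")
        if any(i < 1 for i in self.orders):
            raise ValueError("orders must be >= 1")
        if self.snr <= 0:
            raise ValueError("snr must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.detection is not None:
            d["detection"] = self.detection.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        for key in ("rate_range_per_min", "duration_range_s", "orders",
                    "probabilities", "dead_channel_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("detection") is not None:
            d["detection"] = DetectionConfig.from_dict(d["detection"])
        return cls(**d)


@dataclass(eq=False)
class StudyResult:
    """Results bundle: trains, summaries, curves and the duration table."""

    config: StudyConfig
    trains: list[EventTrain]
    truths: list[GroundTruth]
    summaries: list[TrainSummary]
    curves: dict[int, CumulativeCurve]
    duration_table: dict[int, dict[float, float]]   # order -> {p -> seconds}

    def to_json_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "summaries": [
                {
                    "muscle_id": s.muscle_id,
                    "n_events": s.n_events,
                    "rate_per_min": round(s.rate_per_min, 6),
                    "skewness": None if np.isnan(s.skewness) else round(s.skewness, 6),
                    "max_interval_per_order_s": {
                        str(i): (None if np.isnan(v) else round(v, 6))
                        for i, v in s.max_interval_per_order_s.items()},
                }
                for s in self.summaries
            ],
            "curves": {
                str(i): {
                    "durations_s": c.durations_s.tolist(),
                    "probabilities": c.probabilities.tolist(),
                    "n_intervals": c.n_intervals,
                    "pooling": c.pooling,
                    "grid_step_s": c.grid_step_s,
                }
                for i, c in self.curves.items()
            },
            "duration_for_probability_s": {
                str(i): {f"{p:g}": v for p, v in tab.items()}
                for i, tab in self.duration_table.items()
            },
        }


def analyze_event_trains(trains: Sequence[EventTrain],
                         orders: Sequence[int] = (1, 2, 3, 4, 5),
                         grid_step_s: float = 1.0,
                         pooling: str = POOL_ALL,
                         probabilities: Sequence[float] = _DEFAULT_PROBS,
                         ) -> tuple[list[TrainSummary],
                                    dict[int, CumulativeCurve],
                                    dict[int, dict[float, float]]]:
    """Interval analysis of ready-made event trains (ingest mode)."""
    if not trains:
        raise ValueError("need at least one event train")
    summaries = [summarize_train(tr, max_order=max(orders)) for tr in trains]
    curves: dict[int, CumulativeCurve] = {}
    table: dict[int, dict[float, float]] = {}
    for i in sorted(orders):
        sets = [compute_intervals(tr, i) for tr in trains]
        curves[i] = pool_and_cumulate(sets, order=i, grid_step_s=grid_step_s,
                                      pooling=pooling)
        table[i] = {p: duration_for_probability(curves[i], p)
                    for p in probabilities}
    return summaries, curves, table


def _muscle_seed(ss_child: np.random.SeedSequence) -> int:
    return int(ss_child.generate_state(1)[0] % (2 ** 31))


def run_pipeline(config: StudyConfig, outdir: str | Path | None = None) -> StudyResult:
    """Simulate the study, optionally via full signal synthesis + detection.

    With ``simulate_recordings=True`` each muscle's train is rendered into a
    multi-channel recording (grids for two of every three muscles, a linear
    array for the third, 2–5 dead channels each) and the detector's output is
    analysed; otherwise the ground-truth trains feed the analysis directly.
    """
    t0 = time.monotonic()
    ss = np.random.SeedSequence(config.master_seed)
    children = ss.spawn(config.n_muscles + 1)
    meta_rng = np.random.default_rng(children[-1])
    lo, hi = config.rate_range_per_min
    rates = 10 ** meta_rng.uniform(np.log10(lo), np.log10(hi), config.n_muscles)
    durs = meta_rng.uniform(*config.duration_range_s, config.n_muscles) \
        * config.duration_scale

    trains: list[EventTrain] = []
    truths: list[GroundTruth] = []
    for m in range(config.n_muscles):
        muscle_id = f"muscle{m:02d}"
        seed = _muscle_seed(children[m])
        spec = RenewalSpec(config.distribution, float(rates[m]),
                           shape=config.shape, seed=seed)
        truth = generate_event_train(spec, float(durs[m]))
        truths.append(truth)
        if config.simulate_recordings:
            geometry = (ArrayGeometry.grid() if m % 3 != 2
                        else ArrayGeometry.linear())
            wf = FPWaveformModel()
            n_dead = int(meta_rng.integers(config.dead_channel_range[0],
                                           config.dead_channel_range[1] + 1))
            dead = meta_rng.choice(geometry.n_channels, size=n_dead,
                                   replace=False)
            rec = synthesize_recording(
                truth, geometry, wf,
                noise_rms_uv=wf.amplitude_uv / config.snr,
                sample_rate_hz=config.sample_rate_hz,
                dead_channels=dead.tolist(), seed=seed + 1, name=muscle_id)
            try:
                train = detect(rec, config.detection or default_config(geometry))
            except ValueError as exc:
                raise RuntimeError(f"stage detect failed for {muscle_id}: {exc}") \
                    from exc
        else:
            train = truth.to_event_train(muscle_id)
        log.info("%s: N=%d, rate=%.2f/min, duration=%.1f s", muscle_id,
                 train.n, train.rate_per_min, train.recording_duration_s)
        trains.append(train)

    try:
        summaries, curves, table = analyze_event_trains(
            trains, orders=config.orders, grid_step_s=config.grid_step_s,
            pooling=config.pooling, probabilities=config.probabilities)
    except ValueError as exc:
        raise RuntimeError(f"stage analyze failed: {exc}") from exc
    result = StudyResult(config=config, trains=trains, truths=truths,
                         summaries=summaries, curves=curves,
                         duration_table=table)
    if outdir is not None:
        write_study(result, outdir)
    log.info("pipeline finished in %.1f s", time.monotonic() - t0)
    return result


def write_study(result: StudyResult, outdir: str | Path) -> Path:
    """Write results.json, per-muscle event CSVs, curve CSVs and plots."""
    out = Path(outdir)
    (out / "events").mkdir(parents=True, exist_ok=True)
    (out / "curves").mkdir(exist_ok=True)
    for train in result.trains:
        write_event_train(train, out / "events" / f"{train.muscle_id}.csv")
    for truth, train in zip(result.truths, result.trains):
        write_ground_truth(truth, out / "events" / f"{train.muscle_id}.truth.csv")
    for i, c in result.curves.items():
        lines = ["duration_s,probability"]
        lines += [f"{d:.6f},{p:.8f}" for d, p in zip(c.durations_s, c.probabilities)]
        (out / "curves" / f"order_{i}.csv").write_text("\n".join(lines) + "\n")
    (out / "results.json").write_text(
        json.dumps(result.to_json_dict(), indent=1))
    plot_curves(list(result.curves.values()), out / "curves.png")
    return out / "results.json"


def plot_curves(curves: Sequence[CumulativeCurve],
                path: str | Path | None = None,
                analytic: dict[int, tuple[np.ndarray, np.ndarray]] | None = None):
    """One panel per order plus an overlay of all orders.

    ``analytic`` optionally maps order -> (durations, cdf) reference traces
    to draw behind the empirical curves (e.g. closed-form renewal CDFs).
    """
    if not curves:
        raise ValueError("need at least one curve")
    curves = sorted(curves, key=lambda c: c.order)
    n = len(curves)
    fig, axes = plt.subplots(1, n + 1, figsize=(3.2 * (n + 1), 3.0),
                             sharey=True, squeeze=False)
    axes = axes[0]
    for ax, c in zip(axes, curves):
        ax.step(c.durations_s, c.probabilities, where="post", lw=1.2)
        if analytic and c.order in analytic:
            xs, ys = analytic[c.order]
            ax.plot(xs, ys, "--", color="0.5", lw=1.0)
        ax.set_title(f"i = {c.order}")
        ax.set_xlabel("observation duration (s)")
        ax.set_ylim(0, 1.02)
    axes[0].set_ylabel("probability of i FPs")
    for c in curves:
        axes[-1].step(c.durations_s, c.probabilities, where="post",
                      lw=1.0, label=f"i={c.order}")
    axes[-1].set_title("all orders")
    axes[-1].set_xlabel("observation duration (s)")
    axes[-1].legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def _setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(name)s: %(message)s"))
    root = logging.getLogger("fpwatch")
    if not root.handlers:
        root.addHandler(handler)
    root.setLevel(logging.INFO if verbose else logging.WARNING)
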