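"""Session-level QA orchestration, tolerance evaluation and report rendering.

``run_session_qa`` executes the full pipeline on one session:
extract AP signal -> min-max normalize -> moving-mean smooth -> segment
cycles -> 25%/75% phase times -> beam intervals -> cycle/interval pairing
-> aggregates, plus the optional EPID cine comparison and ion-chamber dose
comparison, and evaluates the results against a tolerance policy.

The default timing tolerance is 0.10 s per metric (the customary gating
temporal-accuracy action level for linac QA); the dose tolerance is 0.5%
of the reference mean. All internal math is full precision; rounding to
2 decimals (half away from zero) happens only in the rendered summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._stats import round_half_away
from .epid_cine import (
    RoiSpec,
    compare_epid_vs_log,
    compute_roi_series,
    detect_beam_on_frames,
    epid_beam_durations,
    epid_duration_stats,
    load_cine_frames,
)
from .errors import StageError
from .gating_log_io import read_gating_log
from .respiratory_signal import (
    average_periodic_signal,
    extract_component,
    minmax_normalize,
    moving_mean_smooth,
    segment_cycles,
)
from .sync_metrics import (
    SessionResult,
    build_session_result,
    dose_comparison,
    pair_cycles_intervals,
    reproducibility_trend,
    session_to_dict,
)
from .trigger_analysis import detect_beam_intervals

__all__ = [
    "TolerancePolicy",
    "QAConfig",
    "QAReport",
    "run_session_qa",
    "evaluate_tolerances",
    "render_report",
    "trend_from_reports",
]


@dataclass
class TolerancePolicy:
    """Pass/fail thresholds; boundary equality passes.

    ``enabled`` maps metric names to booleans; a disabled metric is
    reported as "not evaluated", never pass/fail.
    """

    max_abs_mean_delta_s: float = 0.10
    max_abs_duration_gap_s: float = 0.10
    max_dose_diff_pct: float = 0.5
    enabled: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        if min(self.max_abs_mean_delta_s, self.max_abs_duration_gap_s,
               self.max_dose_diff_pct) <= 0:
            raise ValueError("all tolerances must be positive")

    def is_enabled(self, metric: str) -> bool:
        return self.enabled.get(metric, True)


@dataclass
class QAConfig:
    """All pipeline knobs with their module defaults."""

    axis: str = "z"
    smooth_window: int = 5
    min_prominence: float = 0.2
    min_separation_fraction: float = 0.4
    anchor: str = "peak"
    refine_peaks: bool = True
    gating_window: tuple[float, float] = (0.25, 0.75)
    sd_mode: str = "population"
    strict_edges: bool = False
    threshold_fraction: float = 0.5
    epid_median_filter: bool = False
    epid_frame_period_s: float | None = 0.04
    roi_side_cm_at_iso: float = 5.0
    sad_cm: float = 100.0
    sid_cm: float = 150.0
    dose_paired: bool = True
    seed: int | None = None
    tolerance: TolerancePolicy = field(default_factory=TolerancePolicy)

    @classmethod
    def from_dict(cls, d: dict) -> "QAConfig":
        d = dict(d)
        tol = d.pop("tolerance", None)
        cfg = cls(**d)
        if tol is not None:
            cfg.tolerance = TolerancePolicy(**tol)
        if isinstance(cfg.gating_window, list):
            cfg.gating_window = tuple(cfg.gating_window)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gating_window"] = list(self.gating_window)
        return d


@dataclass
class QAReport:
    session: dict
    average_signal: dict
    epid: dict | None
    dose: dict | None
    metrics: dict
    tolerance_results: dict
    failed_stages: dict
    provenance: dict
    # kept alongside for in-process use (not serialized)
    session_result: SessionResult | None = None

    def payload(self, include_timestamp: bool = True) -> dict:
        d = {
            "session": self.session,
            "average_signal": self.average_signal,
            "epid": self.epid,
            "dose": self.dose,
            "metrics": self.metrics,
            "tolerance_results": self.tolerance_results,
            "failed_stages": self.failed_stages,
            "provenance": dict(self.provenance),
        }
        if not include_timestamp:
            d["provenance"].pop("generated_at", None)
        return d


def _sha256(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _input_hashes(log_path, epid_path) -> dict[str, str]:
    hashes = {str(log_path): _sha256(log_path)}
    if epid_path is not None:
        p = Path(epid_path)
        files = sorted(p.iterdir()) if p.is_dir() else [p]
        for f in files:
            if f.is_file():
                hashes[str(f)] = _sha256(f)
    return hashes


def evaluate_tolerances(metrics: dict, policy: TolerancePolicy) -> dict:
    """Map each metric to pass / fail / not evaluated.

    ``|value| <= tolerance`` passes (boundary equality passes).
    """
    tol_of = {
        "delta_on_mean_s": policy.max_abs_mean_delta_s,
        "delta_off_mean_s": policy.max_abs_mean_delta_s,
        "duration_gap_s": policy.max_abs_duration_gap_s,
        "dose_diff_pct": policy.max_dose_diff_pct,
    }
    results = {}
    for metric, tol in tol_of.items():
        if metric not in metrics or metrics[metric] is None:
            continue
        value = float(metrics[metric])
        if not policy.is_enabled(metric):
            results[metric] = {"value": value, "tolerance": tol,
                               "status": "not evaluated"}
        else:
            results[metric] = {
                "value": value,
                "tolerance": tol,
                "status": "pass" if abs(value) <= tol else "fail",
            }
    return results


def run_session_qa(
    log_path: str | os.PathLike,
    epid_path: str | os.PathLike | None = None,
    doses_ref: list[float] | None = None,
    doses_gated: list[float] | None = None,
    config: QAConfig | None = None,
) -> QAReport:
    """Run the complete QA pipeline on one session.

    Core timing stages raise :class:`~gateqa.errors.StageError` (naming
    the stage) on failure; failures in the optional EPID and dose stages
    are recorded in ``failed_stages`` and the partial report is returned.
    Deterministic given inputs and config.
    """
    cfg = config or QAConfig()
    failed: dict[str, str] = {}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            raise StageError(name, str(exc)) from exc

    record = stage("read_log", read_gating_log, log_path)
    ap = stage("extract", extract_component, record.motion, cfg.axis)
    norm = stage("normalize", minmax_normalize, ap)
    smooth = stage("smooth", moving_mean_smooth, norm, cfg.smooth_window)
    cycles = stage(
        "segment",
        segment_cycles,
        smooth,
        min_prominence=cfg.min_prominence,
        min_separation_fraction=cfg.min_separation_fraction,
        anchor=cfg.anchor,
        refine=cfg.refine_peaks,
    )
    if not cycles:
        raise StageError("segment", "no respiratory cycles detected")
    intervals = stage(
        "triggers", detect_beam_intervals, record.beam, cfg.strict_edges
    )
    pairing = stage(
        "pairing", pair_cycles_intervals, cycles, intervals, cfg.gating_window
    )
    session = stage(
        "aggregate", build_session_result, record.session_id, pairing, cfg.sd_mode
    )
    avg = stage("average_signal", average_periodic_signal, smooth, cycles)

    metrics = {
        "delta_on_mean_s": session.aggregates["delta_on"].mean,
        "delta_off_mean_s": session.aggregates["delta_off"].mean,
        "duration_gap_s": session.duration_gap,
        "window_duration_mean_s": session.aggregates["window_duration"].mean,
        "trigger_duration_mean_s": session.aggregates["trigger_duration"].mean,
    }

    epid_block = None
    if epid_path is not None:
        try:
            stack = load_cine_frames(
                epid_path,
                frame_period=cfg.epid_frame_period_s,
                sid_cm=cfg.sid_cm,
                sad_cm=cfg.sad_cm,
            )
            roi = RoiSpec(side_cm_at_iso=cfg.roi_side_cm_at_iso,
                          sad_cm=stack.sad_cm, sid_cm=stack.sid_cm)
            series = compute_roi_series(stack, roi,
                                        median_filter=cfg.epid_median_filter)
            _, segments = detect_beam_on_frames(series, cfg.threshold_fraction)
            durations = epid_beam_durations(segments, series.frame_period)
            log_durations = [r.trigger_duration for r in session.records]
            comparison = compare_epid_vs_log(durations, log_durations, cfg.sd_mode)
            stats = epid_duration_stats(durations, cfg.sd_mode)
            epid_block = {
                "n_frames": int(stack.frames.shape[0]),
                "frame_period_s": series.frame_period,
                "n_segments": len(segments),
                "durations_s": durations,
                "duration_mean_s": stats.mean,
                "duration_sd_s": stats.sd,
                "vs_log_mode": comparison.mode,
                "vs_log_mean_diff_s": comparison.mean_diff,
                "vs_log_diff_sd_s": (comparison.diff_stats.sd
                                     if comparison.diff_stats else None),
            }
            metrics["epid_minus_log_mean_diff_s"] = comparison.mean_diff
        except Exception as exc:  # noqa: BLE001 - optional stage, partial report
            failed["epid"] = str(exc)

    dose_block = None
    if doses_ref is not None and doses_gated is not None:
        try:
            dc = dose_comparison(doses_ref, doses_gated,
                                 paired=cfg.dose_paired, sd_mode=cfg.sd_mode)
            dose_block = {
                "reference_mean_cgy": dc.reference_stats.mean,
                "reference_sd_cgy": dc.reference_stats.sd,
                "gated_mean_cgy": dc.gated_stats.mean,
                "gated_sd_cgy": dc.gated_stats.sd,
                "diff_mean_cgy": dc.diff_stats.mean if dc.diff_stats else None,
                "diff_sd_cgy": dc.diff_stats.sd if dc.diff_stats else None,
                "paired": cfg.dose_paired,
            }
            diff_mean = (dc.diff_stats.mean if dc.diff_stats is not None
                         else dc.gated_stats.mean - dc.reference_stats.mean)
            dose_block["diff_pct_of_reference"] = (
                100.0 * diff_mean / dc.reference_stats.mean
            )
            metrics["dose_diff_cgy"] = diff_mean
            metrics["dose_diff_pct"] = dose_block["diff_pct_of_reference"]
        except Exception as exc:  # noqa: BLE001
            failed["dose"] = str(exc)

    tolerance_results = evaluate_tolerances(metrics, cfg.tolerance)
    provenance = {
        "gateqa_version": __version__,
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "input_hashes": _input_hashes(log_path, epid_path),
        "generated_at": datetime.now(timezone.utc).isoformat(),
    }
    return QAReport(
        session=session_to_dict(session),
        average_signal={
            "phase_grid": avg.phase_grid.tolist(),
            "mean_v": avg.mean_v.tolist(),
            "sd_v": avg.sd_v.tolist(),
            "n_cycles": avg.n_cycles,
        },
        epid=epid_block,
        dose=dose_block,
        metrics=metrics,
        tolerance_results=tolerance_results,
        failed_stages=failed,
        provenance=provenance,
        session_result=session,
    )


def _summary_table(report: QAReport) -> pd.DataFrame:
    """Per-cycle columns then AVG / STD / Median, rounded to 2 decimals."""
    session = report.session
    recs = session["records"]
    rows = []
    for metric in ("delta_on_s", "delta_off_s", "window_duration_s",
                   "trigger_duration_s"):
        agg = session["aggregates"][metric.removesuffix("_s")]
        row = {"metric": metric}
        for r in recs:
            row[f"cycle_{r['cycle_index'] + 1}"] = round_half_away(r[metric])
        row["AVG"] = round_half_away(agg["mean"])
        row["STD"] = round_half_away(agg["sd"])
        row["Median"] = round_half_away(agg["median"])
        rows.append(row)
    return pd.DataFrame(rows)


def render_report(
    report: QAReport,
    out_dir: str | os.PathLike,
    formats: tuple[str, ...] = ("json", "csv"),
    plot: bool = False,
) -> dict[str, str]:
    """Write the report as JSON and/or CSV tables, optionally with a plot.

    The plot shows the average periodic signal with the planned 25-75%
    phase band and the measured trigger on/off phases marked.
    """
    out = Path(os.fspath(out_dir))
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    if "json" in formats:
        p = out / "report.json"
        with open(p, "w", encoding="utf-8") as fh:
            json.dump(report.payload(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        written["json"] = str(p)
    if "csv" in formats:
        per_cycle = pd.DataFrame(report.session["records"])
        p1 = out / "per_cycle.csv"
        per_cycle.to_csv(p1, index=False)
        p2 = out / "summary.csv"
        _summary_table(report).to_csv(p2, index=False)
        written["per_cycle_csv"] = str(p1)
        written["summary_csv"] = str(p2)
    if plot:
        written["plot"] = _plot_average_signal(report, out / "average_signal.png")
    return written


def _plot_average_signal(report: QAReport, path: Path) -> str:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    avg = report.average_signal
    grid = np.asarray(avg["phase_grid"])
    mean_v = np.asarray(avg["mean_v"])
    sd_v = np.asarray(avg["sd_v"])
    lo, hi = report.provenance["config"]["gating_window"]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(100 * grid, mean_v, color="C0", label="average periodic signal")
    ax.fill_between(100 * grid, mean_v - sd_v, mean_v + sd_v,
                    color="C0", alpha=0.2, label="±1 SD")
    ax.axvspan(100 * lo, 100 * hi, color="C2", alpha=0.15,
               label="planned gating window")
    for r in report.session["records"]:
        window = r["t75_s"] - r["t25_s"]
        period = 2 * window  # window spans half the cycle by construction
        on_phase = lo + (r["t_on_s"] - r["t25_s"]) / period
        off_phase = hi + (r["t_off_s"] - r["t75_s"]) / period
        ax.axvline(100 * on_phase, color="C3", lw=0.8, alpha=0.6)
        ax.axvline(100 * off_phase, color="C3", lw=0.8, alpha=0.6)
    ax.set_xlabel("respiratory phase (%)")
    ax.set_ylabel("normalized AP amplitude")
    ax.set_title(f"session {report.session['session_id']}")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)


def trend_from_reports(report_paths: list[str | os.PathLike]):
    """Reproducibility trend across sessions from rendered report JSONs.

    Returns the per-session table and the per-metric max drift of the
    mean, exactly as :func:`gateqa.sync_metrics.reproducibility_trend`.
    """
    from .sync_metrics import CycleSyncRecord
    from ._stats import AggregateStats

    sessions = []
    for p in report_paths:
        with open(p, encoding="utf-8") as fh:
            d = json.load(fh)
        s = d["session"]
        records = [
            CycleSyncRecord(
                cycle_index=r["cycle_index"], t25=r["t25_s"], t75=r["t75_s"],
                t_on=r["t_on_s"], t_off=r["t_off_s"],
            )
            for r in s["records"]
        ]
        aggregates = {
            m: AggregateStats(mean=a["mean"], sd=a["sd"], median=a["median"],
                              n=a["n"], sd_mode=a.get("sd_mode", "population"))
            for m, a in s["aggregates"].items()
        }
        sessions.append(
            SessionResult(
                session_id=s["session_id"],
                records=records,
                aggregates=aggregates,
                duration_gap=s["duration_gap_s"],
            )
        )
    return reproducibility_trend(sessions)
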