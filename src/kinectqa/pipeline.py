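"""End-to-end experiment orchestration: recordings → metrics → comparisons.

An experiment is a set of recordings (body-tracking JSON and/or depth
stacks, each with a condition label), a set of depth regions of interest,
and a comparison mode:

* ``independent`` — recordings are distinct conditions; per-ROI pixel
  random errors are compared with Kruskal–Wallis + Dunn/Bonferroni;
* ``repeated`` — recordings repeat one condition; the same pixels across
  recordings form the blocks of a Friedman test.

The report mirrors the study-style summary tables: per-ROI random-error
five-number summaries and invalid counts, per-joint MDE with a
median/IQR row, ankle-distance boxplot statistics, and the comparison
outcomes, plus a provenance block (config hash, versions, seed) so a
rerun is checkably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .depth_metrics import compute_random_error, count_invalid, summarize_random_error
from .io_formats import (
    ConditionMetadata,
    DepthFrameStack,
    RegionOfInterest,
    TrackingSequence,
    read_depth_stack,
    read_tracking_json,
)
from .joints import ANALYSIS_JOINTS
from .stats_compare import ComparisonResult, compare_independent, compare_repeated
from .tracking_metrics import compute_mde, cut_frames, joint_pair_distance

logger = logging.getLogger(__name__)

__all__ = ["RecordingInput", "ExperimentConfig", "ExperimentReport", "run_experiment",
           "make_report_tables"]


@dataclass
class RecordingInput:
    """One recording: label plus tracking and/or depth sources.

    Sources may be paths (loaded lazily) or already-loaded containers.
    """

    label: str
    tracking: TrackingSequence | str | Path | None = None
    depth: DepthFrameStack | str | Path | None = None
    metadata: ConditionMetadata | None = None

    def load_tracking(self) -> TrackingSequence | None:
        if self.tracking is None or isinstance(self.tracking, TrackingSequence):
            return self.tracking
        return read_tracking_json(self.tracking)

    def load_depth(self) -> DepthFrameStack | None:
        if self.depth is None or isinstance(self.depth, DepthFrameStack):
            return self.depth
        return read_depth_stack(self.depth)


@dataclass
class ExperimentConfig:
    recordings: list[RecordingInput]
    rois: list[RegionOfInterest] = field(default_factory=list)
    cut: int = 60
    half_width: int = 30
    joints: tuple[str, ...] = ANALYSIS_JOINTS
    ankle_pair: tuple[str, str] = ("ANKLE_LEFT", "ANKLE_RIGHT")
    alpha: float = 0.05
    mode: str = "independent"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.recordings:
            raise ValueError("experiment needs at least one recording")
        labels = [r.label for r in self.recordings]
        if len(set(labels)) != len(labels):
            raise ValueError("recording labels must be unique")
        if self.mode not in ("independent", "repeated"):
            raise ValueError("mode must be 'independent' or 'repeated'")
        if self.mode == "independent" and len(labels) >= 3 and len(set(labels)) < 3:
            raise ValueError("independent mode requires >= 3 distinct labels")

    def content_hash(self) -> str:
        """Stable hash of the analysis parameters (not the input data)."""
        payload = {
            "labels": [r.label for r in self.recordings],
            "rois": [
                (r.name, r.row_start, r.col_start, r.height, r.width)
                for r in self.rois
            ],
            "cut": self.cut,
            "half_width": self.half_width,
            "joints": list(self.joints),
            "ankle_pair": list(self.ankle_pair),
            "alpha": self.alpha,
            "mode": self.mode,
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


@dataclass
class ExperimentReport:
    depth_summaries: pd.DataFrame  # rows: (roi, recording) five-number summaries
    invalid_counts: pd.DataFrame  # rows: (roi, recording) invalid sample counts
    mde_table: pd.DataFrame  # joints × recordings, mm; + Median/Q1/Q3 rows
    ankle_distance: pd.DataFrame  # recordings × boxplot stats
    comparisons: dict[str, ComparisonResult]  # per ROI
    events: list[dict]  # structured log of dropped/undefined data
    provenance: dict


def _comparison_to_frame(result: ComparisonResult) -> pd.DataFrame:
    rows = []
    if result.pairwise:
        for pw in result.pairwise:
            rows.append(
                {
                    "group_a": pw.group_a,
                    "group_b": pw.group_b,
                    "z": pw.statistic,
                    "p_raw": pw.p_raw,
                    "p_adjusted": pw.p_adjusted,
                    "significant": pw.significant,
                }
            )
    return pd.DataFrame(rows)


def run_experiment(cfg: ExperimentConfig) -> ExperimentReport:
    """Run metrics and comparisons over all recordings; deterministic."""
    events: list[dict] = []
    depth_rows = []
    invalid_rows = []
    mde_cols: dict[str, dict[str, float]] = {}
    mde_stats: dict[str, tuple[float, float, float]] = {}
    ankle_rows = []
    re_values: dict[str, dict[str, np.ndarray]] = {roi.name: {} for roi in cfg.rois}
    re_maps: dict[str, dict[str, np.ndarray]] = {roi.name: {} for roi in cfg.rois}

    for rec in cfg.recordings:
        try:
            seq = rec.load_tracking()
            stack = rec.load_depth()
        except Exception as exc:
            raise RuntimeError(f"recording {rec.label!r}: loading failed: {exc}") from exc

        if stack is not None:
            for roi in cfg.rois:
                try:
                    error_map = compute_random_error(stack, roi, cut=cfg.cut)
                    summary = summarize_random_error(error_map)
                    n_invalid = count_invalid(stack, roi, cut=cfg.cut)
                except Exception as exc:
                    raise RuntimeError(
                        f"recording {rec.label!r}, stage depth_metrics, "
                        f"roi {roi.name!r}: {exc}"
                    ) from exc
                n_undefined = roi.area - summary.n_pixels_defined
                if n_undefined:
                    events.append(
                        {
                            "event": "undefined_pixels",
                            "recording": rec.label,
                            "roi": roi.name,
                            "count": n_undefined,
                        }
                    )
                depth_rows.append(
                    {
                        "roi": roi.name,
                        "recording": rec.label,
                        "min": summary.min,
                        "max": summary.max,
                        "median": summary.median,
                        "q1": summary.q1,
                        "q3": summary.q3,
                        "n_pixels_defined": summary.n_pixels_defined,
                    }
                )
                invalid_rows.append(
                    {
                        "roi": roi.name,
                        "recording": rec.label,
                        "n_invalid": n_invalid,
                        "n_samples": roi.area * error_map.n_analyzed_frames,
                    }
                )
                re_values[roi.name][rec.label] = error_map.defined_values()
                re_maps[roi.name][rec.label] = error_map.re

        if seq is not None:
            if seq.gap_frames:
                events.append(
                    {
                        "event": "gap_frames",
                        "recording": rec.label,
                        "count": len(seq.gap_frames),
                    }
                )
            try:
                analyzed = cut_frames(seq, cfg.cut)
                mde = compute_mde(
                    analyzed, joints=cfg.joints, half_width=cfg.half_width
                )
                ankles = joint_pair_distance(analyzed, *cfg.ankle_pair)
            except Exception as exc:
                raise RuntimeError(
                    f"recording {rec.label!r}, stage tracking_metrics: {exc}"
                ) from exc
            mde_cols[rec.label] = mde.mde
            mde_stats[rec.label] = (mde.median, mde.q1, mde.q3)
            ankle_rows.append(
                {
                    "recording": rec.label,
                    "min": ankles.summary.min,
                    "q1": ankles.summary.q1,
                    "median": ankles.summary.median,
                    "q3": ankles.summary.q3,
                    "max": ankles.summary.max,
                }
            )

    comparisons: dict[str, ComparisonResult] = {}
    for roi in cfg.rois:
        per_rec = re_values[roi.name]
        if len(per_rec) < 3:
            continue
        labels = [rec.label for rec in cfg.recordings if rec.label in per_rec]
        try:
            if cfg.mode == "independent":
                comparisons[roi.name] = compare_independent(
                    [per_rec[lab] for lab in labels], labels=labels, alpha=cfg.alpha
                )
            else:
                # align pixels across recordings; NaN (undefined) rows dropped
                mat = np.stack(
                    [re_maps[roi.name][lab].ravel() for lab in labels], axis=1
                )
                comparisons[roi.name] = compare_repeated(
                    mat, labels=labels, alpha=cfg.alpha
                )
                if comparisons[roi.name].n_dropped_rows:
                    events.append(
                        {
                            "event": "dropped_rows",
                            "roi": roi.name,
                            "count": comparisons[roi.name].n_dropped_rows,
                        }
                    )
        except Exception as exc:
            raise RuntimeError(
                f"stage stats_compare, roi {roi.name!r}: {exc}"
            ) from exc

    mde_table = pd.DataFrame(mde_cols)
    if not mde_table.empty:
        stats_rows = pd.DataFrame(
            {lab: list(mde_stats[lab]) for lab in mde_table.columns},
            index=["Median", "Q1", "Q3"],
        )
        mde_table = pd.concat([mde_table.sort_index(), stats_rows])

    provenance = {
        "config_hash": cfg.content_hash(),
        "kinectqa_version": __version__,
        "numpy_version": np.__version__,
        "seed": cfg.seed,
        "cut": cfg.cut,
        "half_width": cfg.half_width,
        "mode": cfg.mode,
        "alpha": cfg.alpha,
    }
    return ExperimentReport(
        depth_summaries=pd.DataFrame(depth_rows),
        invalid_counts=pd.DataFrame(invalid_rows),
        mde_table=mde_table,
        ankle_distance=pd.DataFrame(ankle_rows),
        comparisons=comparisons,
        events=events,
        provenance=provenance,
    )


def make_report_tables(report: ExperimentReport, out_dir: str | Path) -> dict[str, Path]:
    """Write the report as CSV/JSON files; returns the written paths.

    Floats are written with Python's shortest round-tripping repr, so
    re-parsing a table recovers the report's numbers exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _write(frame: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out_dir / name
        frame.to_csv(path, index=index)
        written[name] = path

    if not report.depth_summaries.empty:
        _write(report.depth_summaries, "depth_random_error.csv")
    if not report.invalid_counts.empty:
        _write(report.invalid_counts, "invalid_counts.csv")
    if not report.mde_table.empty:
        _write(report.mde_table, "mde.csv", index=True)
        joint_rows = report.mde_table.drop(index=["Median", "Q1", "Q3"], errors="ignore")
        is_lowest = joint_rows.eq(joint_rows.min(axis=1), axis=0)
        _write(is_lowest, "mde_lowest.csv", index=True)
    if not report.ankle_distance.empty:
        _write(report.ankle_distance, "ankle_distance_boxplot.csv")
    if report.comparisons:
        omnibus = pd.DataFrame(
            [
                {
                    "roi": name,
                    "test": res.test_name,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "significant": res.significant,
                }
                for name, res in report.comparisons.items()
            ]
        )
        _write(omnibus, "comparisons_omnibus.csv")
        pairwise_frames = []
        for name, res in report.comparisons.items():
            frame = _comparison_to_frame(res)
            if not frame.empty:
                frame.insert(0, "roi", name)
                pairwise_frames.append(frame)
        if pairwise_frames:
            _write(pd.concat(pairwise_frames, ignore_index=True), "comparisons_pairwise.csv")

    (out_dir / "provenance.json").write_text(json.dumps(report.provenance, indent=1))
    written["provenance.json"] = out_dir / "provenance.json"
    events_path = out_dir / "events.jsonl"
    events_path.write_text("".join(json.dumps(e) + "\n" for e in report.events))
    written["events.jsonl"] = events_path
    return written
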