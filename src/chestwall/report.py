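"""Per-subject analysis pipeline and cohort summaries.

``analyze_subject`` chains the whole method: gap filling, divergence-theorem
compartment volumes, stable-window selection, breath segmentation, breathing
pattern, paradox classification and the bell-shaped chest index (computed at
the end-expiratory instants the segmentation provides).  Cohort summaries
report median and interquartile range per group, plus the Spearman rank
correlation between bell index and pulmonary-ribcage contribution.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .breath_analysis import (
    BreathingPattern,
    breathing_pattern,
    classify_paradox,
    segment_breaths,
    select_stable_window,
)
from .errors import ChestwallError, StageError, UndefinedCorrelationError
from .marker_model import MarkerLayout, TrajectorySet, fill_gaps, load_trajectories
from .shape_index import DEFAULT_SHAPE_THRESHOLDS, ShapeResult, bell_shape_index
from .surface_volume import compartment_volumes

__all__ = [
    "AnalysisConfig",
    "SubjectReport",
    "CohortSummary",
    "analyze_subject",
    "cohort_summary",
    "rank_correlation",
]

log = logging.getLogger("chestwall")

SUMMARY_METRICS = ("bell_index", "v_e", "rr", "v_t", "rsbi", "pct_rcp", "pct_ab")


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable pipeline settings with their defaults.

    ``max_gap_s`` — longest marker occlusion repaired by interpolation;
    ``min_window_s`` — minimum stable quiet-breathing window;
    ``lowpass_hz`` — zero-phase low-pass cutoff for extremum detection;
    ``min_breath_s`` / ``prominence_frac`` — breath detector bounds;
    ``shape_thresholds`` — bell / rectangular / inverted-triangle bounds;
    ``bed_offset_m`` — posterior closure offset below the lowest marker.
    """

    max_gap_s: float = 0.25
    min_window_s: float = 40.0
    lowpass_hz: float = 2.0
    min_breath_s: float = 0.5
    prominence_frac: float = 0.25
    shape_thresholds: tuple[float, float] = DEFAULT_SHAPE_THRESHOLDS
    bed_offset_m: float = 0.01

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if "shape_thresholds" in doc:
            doc["shape_thresholds"] = tuple(doc["shape_thresholds"])
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["shape_thresholds"] = list(doc["shape_thresholds"])
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


@dataclass
class SubjectReport:
    """Everything the pipeline measures for one subject."""

    subject_id: str
    posture: str
    shape: ShapeResult
    pattern: BreathingPattern
    paradox: bool
    qc: dict

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "posture": self.posture,
            "shape": self.shape.to_dict(),
            "pattern": self.pattern.to_dict(),
            "paradox": self.paradox,
            "qc": self.qc,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _stage(name: str, subject_id: str):
    class _Ctx:
        def __enter__(self):
            log.debug("[%s] stage %s", subject_id, name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, ChestwallError) and not isinstance(
                exc, StageError
            ):
                raise StageError(name, subject_id, exc) from exc
            return False

    return _Ctx()


def analyze_subject(
    source: str | Path | TrajectorySet,
    layout: MarkerLayout,
    config: AnalysisConfig | None = None,
    subject_id: str | None = None,
    posture: str = "supine",
) -> SubjectReport:
    """Run the full per-subject pipeline; deterministic for fixed input.

    *source* is a trajectory file path or an in-memory
    :class:`TrajectorySet`.  Any stage failure is re-raised as a
    :class:`StageError` carrying the stage name and subject id.
    """
    cfg = config or AnalysisConfig()
    if isinstance(source, (str, Path)):
        sid = subject_id or Path(source).stem
        with _stage("load", sid):
            traj = load_trajectories(source, layout=layout)
    else:
        traj = source
        sid = subject_id or "subject"
    n_gaps_before = int((~traj.gap_mask).sum())
    with _stage("fill_gaps", sid):
        traj = fill_gaps(traj, cfg.max_gap_s)
    n_gaps_after = int((~traj.gap_mask).sum())
    with _stage("compartment_volumes", sid):
        series = compartment_volumes(traj, layout, bed_offset=cfg.bed_offset_m)
    with _stage("select_stable_window", sid):
        window = select_stable_window(
            series,
            min_duration_s=cfg.min_window_s,
            cutoff_hz=cfg.lowpass_hz,
            min_breath_s=cfg.min_breath_s,
            prominence_frac=cfg.prominence_frac,
        )
    with _stage("segment_breaths", sid):
        breaths = segment_breaths(
            series,
            window=window,
            cutoff_hz=cfg.lowpass_hz,
            min_breath_s=cfg.min_breath_s,
            prominence_frac=cfg.prominence_frac,
        )
    with _stage("breathing_pattern", sid):
        pattern = breathing_pattern(breaths)
    with _stage("classify_paradox", sid):
        paradox_label, _ = classify_paradox(breaths)
    with _stage("bell_shape_index", sid):
        shape = bell_shape_index(
            traj,
            layout,
            window=window,
            end_expiratory_times=breaths.frame["t_start"].to_numpy(),
            thresholds=cfg.shape_thresholds,
        )
    qc = {
        "window_s": [round(window[0], 6), round(window[1], 6)],
        "n_breaths": pattern.n_breaths,
        "gap_samples_filled": n_gaps_before - n_gaps_after,
        "gap_samples_remaining": n_gaps_after,
    }
    return SubjectReport(
        subject_id=sid,
        posture=posture,
        shape=shape,
        pattern=pattern,
        paradox=paradox_label == "paradox",
        qc=qc,
    )


# ---------------------------------------------------------------------------
# Cohort summaries
# ---------------------------------------------------------------------------


@dataclass
class CohortSummary:
    """Per-group median/IQR table and index-vs-contribution correlation."""

    table: pd.DataFrame
    rho: float
    p_value: float
    n_subjects: int

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def _report_metrics(r: SubjectReport) -> dict:
    return {
        "bell_index": r.shape.bell_index,
        "v_e": r.pattern.v_e,
        "rr": r.pattern.rr,
        "v_t": r.pattern.v_t,
        "rsbi": r.pattern.rsbi,
        "pct_rcp": r.pattern.pct_rcp,
        "pct_ab": r.pattern.pct_ab,
    }


def cohort_summary(
    reports: list[SubjectReport],
    groups: dict[str, str] | None = None,
) -> CohortSummary:
    """Median and IQR of every metric per group, plus the Spearman rank
    correlation between bell index and pulmonary-ribcage contribution
    across all subjects.

    *groups* maps subject id to group name; omitted subjects (or a missing
    mapping) fall into a single group "all".  Empty input raises.
    """
    if not reports:
        raise ValueError("no reports to summarise")
    recs = []
    for r in reports:
        g = (groups or {}).get(r.subject_id, "all")
        recs.append({"subject_id": r.subject_id, "group": g, **_report_metrics(r)})
    df = pd.DataFrame(recs)
    if groups is not None:
        empty = set(groups.values()) - set(df["group"])
        if empty:
            raise ValueError(f"groups without any subject: {sorted(empty)}")
    rows = []
    for g, sub in df.groupby("group", sort=False):
        row: dict = {"group": g, "n": len(sub)}
        for m in SUMMARY_METRICS:
            row[f"{m}_median"] = float(sub[m].median())
            row[f"{m}_q25"] = float(sub[m].quantile(0.25))
            row[f"{m}_q75"] = float(sub[m].quantile(0.75))
        rows.append(row)
    table = pd.DataFrame(rows)
    rho, p = rank_correlation(df["bell_index"].to_numpy(), df["pct_rcp"].to_numpy())
    return CohortSummary(table=table, rho=rho, p_value=p, n_subjects=len(df))


def rank_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midranks for ties.

    Two-sided p-value from the t-distribution approximation
    ``t = rho * sqrt((n-2) / (1-rho^2))`` with n-2 degrees of freedom.
    Constant input is undefined and raises.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1D arrays with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("rank correlation of a constant vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
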