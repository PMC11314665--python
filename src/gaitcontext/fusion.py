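"""Fuse per-frame environmental context with per-bout gait statistics.

Scene-camera frames and IMU samples share a clock (up to a configurable
constant offset).  Each analysed frame is assigned to the walking bout
whose interval contains its timestamp; per bout we then summarize how
often a hazard sat in the immediate walking path, how often gaze was on
the path, and whether hazard episodes went entirely unattended.  The
result — temporal gait characteristics side by side with the context
summary, optionally against the wearer's own lab-based normative values
— is the contextualized gait report.

No fall-risk score is computed: the report exposes the ingredients
(gait instability and its environmental context) for interpretation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

from .gait import TemporalGaitStats, WalkingBout
from .path_overlap import FrameContext, attention_on_hazards
from .taxonomy import Taxonomy, is_hazard_class


@dataclass
class BoutContextSummary:
    bout: WalkingBout
    n_frames: int
    hazard_in_path_fraction: Optional[float]
    gaze_on_path_fraction: Optional[float]
    in_path_class_counts: dict[str, int] = field(default_factory=dict)
    unattended_hazard_windows: int = 0


@dataclass
class BoutReport:
    bout: WalkingBout
    gait: TemporalGaitStats
    context: Optional[BoutContextSummary]
    deltas: Optional[dict[str, float]] = None


@dataclass
class ContextualizedGaitReport:
    bouts: list[BoutReport]
    normative: Optional[TemporalGaitStats] = None


def align(
    contexts: Sequence[FrameContext],
    bouts: Sequence[WalkingBout],
    tolerance: float = 0.0,
    clock_offset: float = 0.0,
) -> dict[int, list[FrameContext]]:
    """Assign frames to bouts by timestamp.

    A frame belongs to bout ``i`` when its (offset-corrected) timestamp
    lies in ``[start - tolerance, end + tolerance]``; earlier bouts win
    where tolerance makes intervals touch.  Frames outside all bouts are
    left unassigned.  ``clock_offset`` is added to frame timestamps to
    map the camera clock onto the IMU clock.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    ts = [c.timestamp for c in contexts]
    if any(b < a for a, b in zip(ts, ts[1:])):
        raise ValueError("frame contexts must be time-ordered")
    starts = [b.start for b in bouts]
    if any(b < a for a, b in zip(starts, starts[1:])):
        raise ValueError("bouts must be time-ordered")
    mapping: dict[int, list[FrameContext]] = {i: [] for i in range(len(bouts))}
    for c in contexts:
        t = c.timestamp + clock_offset
        for i, bout in enumerate(bouts):
            if bout.start - tolerance <= t <= bout.end + tolerance:
                mapping[i].append(c)
                break
    return mapping


def summarize_bout_context(
    bout: WalkingBout,
    contexts: Sequence[FrameContext],
    taxonomy: Taxonomy,
    attention_window: float = 2.0,
) -> BoutContextSummary:
    """Aggregate frame-level hazard flags over one bout.

    ``unattended_hazard_windows`` counts attention windows (length
    ``attention_window`` seconds) in which a hazard was present in the
    walking path on at least one frame but gazed on none — episodes
    where an in-path hazard drew no visual attention at all.
    """
    n = len(contexts)
    if n == 0:
        return BoutContextSummary(
            bout=bout,
            n_frames=0,
            hazard_in_path_fraction=None,
            gaze_on_path_fraction=None,
        )
    hazard_frac = sum(c.hazard_in_path for c in contexts) / n
    gaze_frac = sum(c.gaze_on_path for c in contexts) / n
    class_counts: dict[str, int] = {}
    for c in contexts:
        for v in c.verdicts:
            if v.in_path and is_hazard_class(taxonomy, v.detection.class_name):
                name = taxonomy[v.detection.class_name].name
                class_counts[name] = class_counts.get(name, 0) + 1
    unattended = sum(
        1 for _start, frac in attention_on_hazards(contexts, attention_window)
        if frac is not None and frac == 0.0
    )
    return BoutContextSummary(
        bout=bout,
        n_frames=n,
        hazard_in_path_fraction=hazard_frac,
        gaze_on_path_fraction=gaze_frac,
        in_path_class_counts=class_counts,
        unattended_hazard_windows=unattended,
    )


_STAT_KEYS = (
    "step_mean", "step_std", "step_asy",
    "stance_mean", "stance_std", "stance_asy",
    "swing_mean", "swing_std", "swing_asy",
)


def build_report(
    stats_per_bout: Sequence[tuple[WalkingBout, TemporalGaitStats]],
    summaries: Sequence[Optional[BoutContextSummary]],
    normative: Optional[TemporalGaitStats] = None,
) -> ContextualizedGaitReport:
    """Assemble the contextualized gait report.

    ``summaries[i]`` pairs with ``stats_per_bout[i]`` (``None`` when the
    bout had no video coverage).  With normative (lab) stats given, each
    bout also carries stat-minus-normative deltas.
    """
    if len(stats_per_bout) != len(summaries):
        raise ValueError("bout sets of stats and summaries differ in length")
    rows = []
    norm_row = normative.as_row() if normative is not None else None
    for (bout, stats), summary in zip(stats_per_bout, summaries):
        deltas = None
        if norm_row is not None:
            row = stats.as_row()
            deltas = {k: row[k] - norm_row[k] for k in _STAT_KEYS}
        rows.append(BoutReport(bout=bout, gait=stats, context=summary, deltas=deltas))
    return ContextualizedGaitReport(bouts=rows, normative=normative)


def report_to_dict(report: ContextualizedGaitReport) -> dict:
    """JSON-serializable form of a report (lossless for scalar fields)."""

    def stats_dict(s: TemporalGaitStats) -> dict:
        d = s.as_row()
        d["n_steps"] = s.n_steps
        return d

    out: dict = {"bouts": []}
    for r in report.bouts:
        entry: dict = {
            "bout": {"start": r.bout.start, "end": r.bout.end},
            "gait": stats_dict(r.gait),
        }
        if r.context is not None:
            c = r.context
            entry["context"] = {
                "n_frames": c.n_frames,
                "hazard_in_path_fraction": c.hazard_in_path_fraction,
                "gaze_on_path_fraction": c.gaze_on_path_fraction,
                "in_path_class_counts": dict(sorted(c.in_path_class_counts.items())),
                "unattended_hazard_windows": c.unattended_hazard_windows,
            }
        else:
            entry["context"] = None
        if r.deltas is not None:
            entry["deltas_vs_normative"] = r.deltas
        out["bouts"].append(entry)
    if report.normative is not None:
        out["normative"] = stats_dict(report.normative)
    return out


def write_report_json(report: ContextualizedGaitReport, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report_to_dict(report), fh, indent=2, sort_keys=True)


def report_rows(report: ContextualizedGaitReport) -> list[dict]:
    """Flat rows (one per bout) with Mean/STD/Asy columns for CSV export."""
    rows = []
    for i, r in enumerate(report.bouts):
        row: dict = {"bout": i, "start": r.bout.start, "end": r.bout.end}
        row.update(r.gait.as_row())
        if r.context is not None:
            row["n_frames"] = r.context.n_frames
            row["hazard_in_path_fraction"] = r.context.hazard_in_path_fraction
            row["gaze_on_path_fraction"] = r.context.gaze_on_path_fraction
            row["unattended_hazard_windows"] = r.context.unattended_hazard_windows
        rows.append(row)
    return rows
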