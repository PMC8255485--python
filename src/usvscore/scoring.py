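"""Behavioral preference scores and occupancy-normalized vocalization scores.

The combined vocalization score (CVS) of a zone is the number of 40 ms
call frames on the raster while the animal occupied that zone, divided
by the seconds spent there — a call rate in frames/s.  Its universe is
the fifteen 50-kHz labels (fourteen subtypes plus Unclear); long 22-kHz
alarm calls are excluded.  The subtype vocalization score (SVS) applies
the same normalization to a single subtype, so CVS is the sum of SVS
over the fifteen-label universe.  Delta scores (dCVS, dSVS) subtract
the low-value zone from the high-value zone (higher sucrose minus lower
for the sucrose discrimination task; social minus non-social for the
social-sucrose preference test), normalizing away inter-individual
differences in absolute call rates.

Rare subtypes are dropped from subtype-level analyses by a prevalence
filter: a subtype is kept when it accounts for at least the threshold
percentage (default 2%) of all non-22-kHz call frames pooled over the
dataset; Unclear stays in CVS but never enters subtype analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .io_formats import TrialMeta, condition_identities, sucrose_level
from .sync import ZoneSubtypeCounts
from .vocabulary import CVS_SUBTYPES, KHZ22, SHORT_CODES, SUBTYPES_50KHZ

#: Offset added before the log transform of CVS; ln(cvs + LOG_EPSILON).
#: 0.001 frames/s is a floor of about one call frame per 1000 s of occupancy.
LOG_EPSILON = 1e-3


@dataclass(frozen=True)
class PreferenceScore:
    """Percentage of reward-zone time spent in the focal zone."""

    percent: float  # NaN when both zone times are zero
    focal_seconds: float
    other_seconds: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.percent)


def preference_score(t_focal: float, t_other: float) -> PreferenceScore:
    """100 x t_focal / (t_focal + t_other); neutral-platform time never
    enters.  Undefined (NaN) when the animal visited neither zone."""
    if t_focal < 0 or t_other < 0:
        raise ValueError("zone times must be non-negative")
    total = t_focal + t_other
    pct = math.nan if total == 0 else 100.0 * t_focal / total
    return PreferenceScore(pct, t_focal, t_other)


def cvs(total_call_frames: int, occupancy_seconds: float) -> float:
    """Combined vocalization score: call frames per second of occupancy.

    The numerator must already be restricted to the 15-label universe
    (no 22-kHz frames).  Returns NaN for zero occupancy.
    """
    if total_call_frames < 0:
        raise ValueError("frame count must be non-negative")
    if occupancy_seconds < 0:
        raise ValueError("occupancy must be non-negative")
    if occupancy_seconds == 0:
        return math.nan
    return total_call_frames / occupancy_seconds


def log_cvs(value: float) -> float:
    """Natural log of CVS with a small offset: ln(cvs + 0.001)."""
    if math.isnan(value):
        return math.nan
    if value < 0:
        raise ValueError("CVS must be non-negative")
    return math.log(value + LOG_EPSILON)


def cvs_frames(counts: ZoneSubtypeCounts, zone: str) -> int:
    """Call frames in *zone* over the CVS universe (excludes 22 kHz)."""
    zc = counts.counts.get(zone, {})
    return sum(n for s, n in zc.items() if s != KHZ22)


def svs_table(counts: ZoneSubtypeCounts,
              zones: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Per-zone, per-subtype vocalization rates (frames/s).

    Rows are zones, columns the 15 CVS labels plus a ``CVS`` total
    column.  Zones with zero occupancy get NaN rates.
    """
    if zones is None:
        zones = counts.zones
    rows = []
    for z in zones:
        occ = counts.occupancy_seconds(z)
        zc = counts.counts.get(z, {})
        row: dict[str, float] = {"zone": z, "occupancy_s": occ}
        for s in CVS_SUBTYPES:
            row[s] = (zc.get(s, 0) / occ) if occ > 0 else math.nan
        row["CVS"] = cvs(cvs_frames(counts, z), occ) if occ > 0 else math.nan
        rows.append(row)
    df = pd.DataFrame(rows).set_index("zone")
    return df


def delta_scores(focal: pd.Series | dict, other: pd.Series | dict) -> pd.Series:
    """High-value-zone minus low-value-zone rates, per score column.

    Antisymmetric under zone swap; NaN propagates when either zone's
    score is undefined.
    """
    f = pd.Series(focal, dtype=float)
    o = pd.Series(other, dtype=float)
    return f - o


@dataclass(frozen=True)
class SubtypeFilterResult:
    """Outcome of the prevalence cut-off on 50-kHz subtypes."""

    prevalence_percent: dict[str, float]
    included: tuple[str, ...]
    excluded: tuple[str, ...]
    threshold_percent: float

    def report(self) -> pd.DataFrame:
        rows = [
            {
                "subtype": s,
                "code": SHORT_CODES[s],
                "prevalence_percent": self.prevalence_percent.get(s, 0.0),
                "included": s in self.included,
            }
            for s in CVS_SUBTYPES
        ]
        return pd.DataFrame(rows)


def subtype_filter(
    pooled_counts: dict[str, int] | pd.Series,
    threshold_percent: float = 2.0,
) -> SubtypeFilterResult:
    """Prevalence filter over pooled call-frame counts.

    Prevalence of a subtype is its share (%) of all non-22-kHz call
    frames (Unclear counts toward the denominator).  A 50-kHz subtype is
    included when its prevalence is at least the threshold; Unclear is
    always excluded from subtype-level analyses regardless of
    prevalence, and 22-kHz frames never enter.
    """
    counts = {str(k): int(v) for k, v in dict(pooled_counts).items()}
    for s, n in counts.items():
        if n < 0:
            raise ValueError(f"negative count for {s!r}")
    denom = sum(n for s, n in counts.items() if s != KHZ22)
    if denom == 0:
        raise ValueError("no call frames: prevalence undefined")
    prevalence = {
        s: 100.0 * counts.get(s, 0) / denom for s in CVS_SUBTYPES
    }
    included = tuple(
        s for s in SUBTYPES_50KHZ if prevalence[s] >= threshold_percent
    )
    excluded = tuple(
        s for s in CVS_SUBTYPES if s not in included
    )
    return SubtypeFilterResult(
        prevalence_percent=prevalence,
        included=included,
        excluded=excluded,
        threshold_percent=threshold_percent,
    )


# ---------------------------------------------------------------------------
# Cohort-level score tables
# ---------------------------------------------------------------------------

SCORE_ID_COLS = ["animal", "task", "condition", "day", "zone", "role"]


def score_trial(
    meta: TrialMeta, counts: ZoneSubtypeCounts,
    focal_zone: str, other_zone: str,
) -> pd.DataFrame:
    """Long-format score rows (one per open reward zone) for one trial.

    ``role`` is ``"focal"`` for the higher-sucrose (SDT) or social
    (SSPT) zone and ``"other"`` for its competitor.
    """
    focal_id, other_id = condition_identities(meta.task, meta.condition)
    svs = svs_table(counts, zones=(focal_zone, other_zone))
    rows = []
    for zone, role, ident in (
        (focal_zone, "focal", focal_id),
        (other_zone, "other", other_id),
    ):
        occ = counts.occupancy_seconds(zone)
        total_frames = cvs_frames(counts, zone)
        row = {
            "animal": meta.animal,
            "task": meta.task,
            "condition": meta.condition,
            "day": meta.day,
            "zone": zone,
            "role": role,
            "reward": ident,
            "occupancy_s": occ,
            "call_frames": total_frames,
            "cvs": cvs(total_frames, occ) if occ > 0 else math.nan,
        }
        row["log_cvs"] = log_cvs(row["cvs"])
        for s in CVS_SUBTYPES:
            row[f"svs_{SHORT_CODES[s]}"] = svs.loc[zone, s]
        rows.append(row)
    return pd.DataFrame(rows)


def score_cohort(
    trials: list[tuple[TrialMeta, ZoneSubtypeCounts, str, str]],
) -> pd.DataFrame:
    """Concatenate per-trial score rows over a cohort."""
    frames = [score_trial(*t) for t in trials]
    return pd.concat(frames, ignore_index=True)


def preference_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-trial preference scores from a long score table."""
    rows = []
    for (animal, task, condition, day), grp in scores.groupby(
        ["animal", "task", "condition", "day"], sort=True
    ):
        focal = grp[grp.role == "focal"].iloc[0]
        other = grp[grp.role == "other"].iloc[0]
        pref = preference_score(focal.occupancy_s, other.occupancy_s)
        rows.append({
            "animal": animal, "task": task, "condition": condition,
            "day": day, "preference_percent": pref.percent,
            "focal_s": pref.focal_seconds, "other_s": pref.other_seconds,
        })
    return pd.DataFrame(rows)


def delta_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-trial dCVS and per-subtype dSVS (focal minus other zone)."""
    value_cols = ["cvs"] + [f"svs_{SHORT_CODES[s]}" for s in CVS_SUBTYPES]
    rows = []
    for (animal, task, condition, day), grp in scores.groupby(
        ["animal", "task", "condition", "day"], sort=True
    ):
        focal = grp[grp.role == "focal"].iloc[0]
        other = grp[grp.role == "other"].iloc[0]
        d = delta_scores(focal[value_cols], other[value_cols])
        row = {"animal": animal, "task": task, "condition": condition,
               "day": day, "dcvs": d["cvs"],
               "dlog_cvs": log_cvs(focal["cvs"]) - log_cvs(other["cvs"])
               if not (math.isnan(focal["cvs"]) or math.isnan(other["cvs"]))
               else math.nan}
        for s in CVS_SUBTYPES:
            row[f"dsvs_{SHORT_CODES[s]}"] = d[f"svs_{SHORT_CODES[s]}"]
        if task == "SSPT":
            row["sucrose_percent"] = sucrose_level(condition)
        else:
            row["sucrose_percent"] = math.nan
        rows.append(row)
    return pd.DataFrame(rows)
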