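"""Tabular interchange formats for the vocalization pipeline.

Readers for annotation-software call-label exports and video-tracking
exports, a YAML zone-map loader for the X-shaped maze, and the CSV
writers for pipeline outputs.  Dialects are declared explicitly
(delimiter, decimal separator, column names) rather than sniffed:
European tracking exports routinely use a decimal comma.

Conventions enforced throughout: times are seconds from trial start
(t = 0), call intervals are half-open ``[start, end)``, coordinates are
cm with the origin at the maze center and y increasing toward the arm
that holds the juvenile restrainer for layout group A.  Row numbers in
error messages are 1-based data rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Point, Polygon

from .vocabulary import SUBTYPE_CODES

REWARD_IDENTITIES = ("2%", "5%", "10%", "Juvenile")
SDT_CONDITIONS = ("2v5", "2v10", "5v10")
SSPT_CONDITIONS = ("Jv2", "Jv5", "Jv10")
ARMS = ("N", "E", "S", "W")


# ---------------------------------------------------------------------------
# Core records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CallLabel:
    """One annotated vocalization: interval, subtype, and either four
    per-channel amplitudes (dB) or a pre-selected 1-based channel index."""

    start: float
    end: float
    subtype: str
    amplitudes: tuple[float, float, float, float] | None = None
    channel: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.start < self.end):
            raise ValueError(
                f"call interval must satisfy 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.subtype not in SUBTYPE_CODES:
            raise ValueError(f"unknown subtype {self.subtype!r}")
        if self.amplitudes is not None and len(self.amplitudes) != 4:
            raise ValueError("amplitudes must hold exactly 4 channels")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class TrackRecord:
    """One video frame of position tracking; NaN coordinates mark a
    tracking gap (subject not detected), preserved rather than dropped."""

    t: float
    x: float
    y: float

    @property
    def is_gap(self) -> bool:
        return math.isnan(self.x) or math.isnan(self.y)


@dataclass(frozen=True)
class TrialMeta:
    """Identity of one trial: animal, task, condition, day, maze layout group."""

    animal: str
    task: str  # "SDT" | "SSPT" | "Habituation"
    condition: str
    day: int
    group: str = "A"

    def __post_init__(self) -> None:
        legal = {
            "SDT": SDT_CONDITIONS,
            "SSPT": SSPT_CONDITIONS,
            "Habituation": ("hab",),
        }
        if self.task not in legal:
            raise ValueError(f"unknown task {self.task!r}")
        if self.condition not in legal[self.task]:
            raise ValueError(
                f"condition {self.condition!r} not legal for task {self.task!r}"
            )
        if self.group not in ("A", "B"):
            raise ValueError(f"layout group must be A or B, got {self.group!r}")

    @property
    def key(self) -> str:
        return f"{self.animal}_{self.task}_{self.condition}_d{self.day}"


def condition_identities(task: str, condition: str) -> tuple[str, str]:
    """Reward identities open in a condition as ``(focal, other)``.

    SDT: focal is the higher sucrose concentration.  SSPT: focal is the
    juvenile (social) side.
    """
    if task == "SDT":
        lo, hi = condition.split("v")
        return f"{hi}%", f"{lo}%"
    if task == "SSPT":
        suc = condition[2:]
        return "Juvenile", f"{suc}%"
    raise ValueError(f"no reward identities for task {task!r}")


def sucrose_level(condition: str) -> float:
    """Sucrose concentration (%) of the non-social side of an SSPT condition."""
    if not condition.startswith("Jv"):
        raise ValueError(f"not an SSPT condition: {condition!r}")
    return float(condition[2:])


# ---------------------------------------------------------------------------
# Dialects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabelDialect:
    delimiter: str = ","
    decimal: str = "."
    start_col: str = "start_s"
    end_col: str = "end_s"
    subtype_col: str = "subtype"
    amplitude_cols: tuple[str, str, str, str] | None = (
        "amp_ch1", "amp_ch2", "amp_ch3", "amp_ch4",
    )
    channel_col: str | None = "channel"


@dataclass(frozen=True)
class TrackDialect:
    delimiter: str = ","
    decimal: str = "."
    t_col: str = "t_s"
    x_col: str = "x_cm"
    y_col: str = "y_cm"


#: Tab-delimited, decimal-comma variants typical of European exports.
EUROPEAN_TRACK_DIALECT = TrackDialect(delimiter="\t", decimal=",")
EUROPEAN_LABEL_DIALECT = LabelDialect(delimiter="\t", decimal=",")


# ---------------------------------------------------------------------------
# Label / track readers and writers
# ---------------------------------------------------------------------------

def read_label_table(
    path: str | Path, dialect: LabelDialect = LabelDialect()
) -> list[CallLabel]:
    """Parse a call-label export into :class:`CallLabel` records.

    Every row must parse; the first offending row raises a ValueError
    naming its 1-based data-row index.
    """
    df = pd.read_csv(path, sep=dialect.delimiter, decimal=dialect.decimal)
    for col in (dialect.start_col, dialect.end_col, dialect.subtype_col):
        if col not in df.columns:
            raise ValueError(f"label table {path} lacks required column {col!r}")
    has_amp = dialect.amplitude_cols is not None and all(
        c in df.columns for c in dialect.amplitude_cols
    )
    has_chan = dialect.channel_col is not None and dialect.channel_col in df.columns

    calls: list[CallLabel] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        subtype = str(rowd[dialect.subtype_col]).strip()
        if subtype not in SUBTYPE_CODES:
            raise ValueError(f"unknown subtype {subtype!r}, row {i}")
        start = float(rowd[dialect.start_col])
        end = float(rowd[dialect.end_col])
        if not (0.0 <= start < end):
            raise ValueError(
                f"bad call interval [{start}, {end}), row {i}: "
                "need 0 <= start < end"
            )
        amps = None
        if has_amp:
            vals = [rowd[c] for c in dialect.amplitude_cols]
            if not any(pd.isna(v) for v in vals):
                amps = tuple(float(v) for v in vals)
        chan = None
        if has_chan and not pd.isna(rowd[dialect.channel_col]):
            chan = int(rowd[dialect.channel_col])
        calls.append(CallLabel(start, end, subtype, amps, chan))
    return calls


def write_label_table(
    calls: Sequence[CallLabel], path: str | Path,
    dialect: LabelDialect = LabelDialect(),
) -> None:
    """Inverse of :func:`read_label_table`; times at full float precision."""
    cols: dict[str, list] = {
        dialect.start_col: [c.start for c in calls],
        dialect.end_col: [c.end for c in calls],
        dialect.subtype_col: [c.subtype for c in calls],
    }
    if dialect.amplitude_cols is not None:
        for j, name in enumerate(dialect.amplitude_cols):
            cols[name] = [
                c.amplitudes[j] if c.amplitudes is not None else np.nan
                for c in calls
            ]
    if dialect.channel_col is not None:
        cols[dialect.channel_col] = [
            c.channel if c.channel is not None else np.nan for c in calls
        ]
    df = pd.DataFrame(cols)
    df.to_csv(path, sep=dialect.delimiter, index=False)


def read_track_table(
    path: str | Path, dialect: TrackDialect = TrackDialect()
) -> list[TrackRecord]:
    """Parse a tracking export; blank positions become gap records."""
    df = pd.read_csv(path, sep=dialect.delimiter, decimal=dialect.decimal)
    for col in (dialect.t_col, dialect.x_col, dialect.y_col):
        if col not in df.columns:
            raise ValueError(f"track table {path} lacks required column {col!r}")
    t = df[dialect.t_col].to_numpy(dtype=float)
    if np.any(np.isnan(t)):
        raise ValueError("track table has missing time stamps")
    bad = np.nonzero(np.diff(t) < 0)[0]
    if bad.size:
        raise ValueError(
            f"non-monotone time in track table at row {int(bad[0]) + 2}"
        )
    x = df[dialect.x_col].to_numpy(dtype=float)
    y = df[dialect.y_col].to_numpy(dtype=float)
    return [TrackRecord(float(ti), float(xi), float(yi))
            for ti, xi, yi in zip(t, x, y)]


def write_track_table(
    tracks: Sequence[TrackRecord], path: str | Path,
    dialect: TrackDialect = TrackDialect(),
) -> None:
    df = pd.DataFrame({
        dialect.t_col: [r.t for r in tracks],
        dialect.x_col: [r.x for r in tracks],
        dialect.y_col: [r.y for r in tracks],
    })
    df.to_csv(path, sep=dialect.delimiter, index=False)


# ---------------------------------------------------------------------------
# Zone map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZoneMap:
    """Geometry of the X-shaped maze and the reward identity of each arm.

    ``zones`` maps zone names (``"N_reward"``, ``"N_sand"``, ...) to
    polygons; the neutral zone is the central disc and is not a polygon
    entry — any point outside every polygon is assigned to it.
    ``assignments`` maps layout group → arm → reward identity.
    """

    zones: dict[str, Polygon]
    neutral_center: tuple[float, float]
    neutral_radius: float
    assignments: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        names = sorted(self.zones)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                inter = self.zones[a].intersection(self.zones[b])
                if inter.area > 1e-9:
                    raise ValueError(f"zone polygons {a!r} and {b!r} overlap")
        for group, arm_map in self.assignments.items():
            seen: dict[str, str] = {}
            for arm, ident in arm_map.items():
                if ident not in REWARD_IDENTITIES:
                    raise ValueError(f"unknown reward identity {ident!r}")
                if ident in seen:
                    raise ValueError(
                        f"group {group}: reward identity {ident!r} mapped to "
                        f"both arm {seen[ident]} and arm {arm}"
                    )
                seen[ident] = arm
            if set(seen) != set(REWARD_IDENTITIES):
                raise ValueError(
                    f"group {group} must assign all of {REWARD_IDENTITIES}"
                )

    @property
    def zone_names(self) -> tuple[str, ...]:
        return tuple(sorted(self.zones))

    def zone_of(self, x: float, y: float) -> str:
        """Name of the zone containing (x, y); ``"neutral"`` if none."""
        p = Point(x, y)
        for name in self.zone_names:
            poly = self.zones[name]
            if poly.contains(p) or poly.touches(p):
                return name
        return "neutral"

    def arm_of_identity(self, identity: str, group: str) -> str:
        for arm, ident in self.assignments[group].items():
            if ident == identity:
                return arm
        raise KeyError(identity)

    def reward_zone(self, identity: str, group: str) -> str:
        return f"{self.arm_of_identity(identity, group)}_reward"

    def zones_for(self, meta: TrialMeta) -> tuple[str, str]:
        """(focal, other) reward-zone names for a trial's open arms."""
        focal_id, other_id = condition_identities(meta.task, meta.condition)
        return (self.reward_zone(focal_id, meta.group),
                self.reward_zone(other_id, meta.group))


_ARM_DIRECTIONS = {"N": (0.0, 1.0), "E": (1.0, 0.0),
                   "S": (0.0, -1.0), "W": (-1.0, 0.0)}

DEFAULT_ZONE_CONFIG: dict = {
    "neutral": {"center": [0.0, 0.0], "radius": 18.0},
    "arm_width": 14.0,
    "arm_length": 60.0,
    "sand_depth": 17.0,
    "reward_depth": 20.0,
    "groups": {
        "A": {"N": "Juvenile", "E": "10%", "S": "5%", "W": "2%"},
        "B": {"N": "5%", "E": "2%", "S": "10%", "W": "Juvenile"},
    },
}


def _arm_rect(direction: tuple[float, float], r0: float, r1: float,
              half_width: float) -> Polygon:
    dx, dy = direction
    px, py = -dy, dx  # unit perpendicular
    corners = [
        (dx * r0 + px * half_width, dy * r0 + py * half_width),
        (dx * r1 + px * half_width, dy * r1 + py * half_width),
        (dx * r1 - px * half_width, dy * r1 - py * half_width),
        (dx * r0 - px * half_width, dy * r0 - py * half_width),
    ]
    return Polygon(corners)


def build_zone_map(config: dict | None = None) -> ZoneMap:
    """Construct a :class:`ZoneMap` from a parameter dictionary.

    Each arm carries a sandpaper zone at its entrance and a reward zone
    at its distal end; the stretch between them belongs to no polygon
    and therefore scores as neutral, mirroring the exclusion of
    non-reward-zone time from the analysis.
    """
    cfg = dict(DEFAULT_ZONE_CONFIG)
    if config:
        cfg.update(config)
    r_neutral = float(cfg["neutral"]["radius"])
    half_w = float(cfg["arm_width"]) / 2.0
    arm_end = r_neutral + float(cfg["arm_length"])
    sand_r1 = r_neutral + float(cfg["sand_depth"])
    reward_r0 = arm_end - float(cfg["reward_depth"])
    if not (r_neutral < sand_r1 <= reward_r0 < arm_end):
        raise ValueError("sand and reward zones must not overlap")
    zones: dict[str, Polygon] = {}
    for arm, direction in _ARM_DIRECTIONS.items():
        zones[f"{arm}_sand"] = _arm_rect(direction, r_neutral, sand_r1, half_w)
        zones[f"{arm}_reward"] = _arm_rect(direction, reward_r0, arm_end, half_w)
    return ZoneMap(
        zones=zones,
        neutral_center=tuple(cfg["neutral"]["center"]),
        neutral_radius=r_neutral,
        assignments={g: dict(m) for g, m in cfg["groups"].items()},
    )


def default_zone_map() -> ZoneMap:
    return build_zone_map()


def load_zone_map(path: str | Path) -> ZoneMap:
    """Load a zone map from a YAML parameter file (geometric invariants
    are checked at construction)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return build_zone_map(cfg)


def write_zone_map_config(config: dict | None, path: str | Path) -> None:
    cfg = dict(DEFAULT_ZONE_CONFIG)
    if config:
        cfg.update(config)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Pipeline output tables
# ---------------------------------------------------------------------------

#: All numeric pipeline outputs are printed with 6 significant digits;
#: undefined scores (e.g. zero occupancy) serialize as empty cells.
FLOAT_FORMAT = "%.6g"


def write_scores_table(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, index=False, float_format=FLOAT_FORMAT, na_rep="")


def read_scores_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
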