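"""Fuse call labels and position tracking onto a common 25 Hz frame raster.

The raster is one-hot: each 40 ms frame carries at most one subtype
label.  A frame ``k`` spans ``[k/rate, (k+1)/rate)`` and is labeled by a
call whenever the call interval overlaps the span by any positive
amount — short 30–40 ms calls straddling a frame boundary therefore
light up both frames, so frame counts are never below call counts.

Zone assignment picks, for every frame, the position sample nearest in
time within one frame period; frames with no such sample are gaps.
Points inside no zone polygon fall to the central neutral platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import shapely

from .io_formats import CallLabel, TrackRecord, ZoneMap
from .vocabulary import CODE_TO_LABEL, SILENCE_CODE, SUBTYPE_CODES

GAP = "gap"
NEUTRAL = "neutral"


def n_frames_for(duration: float, frame_rate: float) -> int:
    return int(math.ceil(duration * frame_rate - 1e-9))


def frames_to_seconds(frames: int, frame_rate: float = 25.0) -> float:
    """Vocalization time implied by a raster frame count."""
    if frame_rate <= 0:
        raise ValueError("frame rate must be positive")
    return frames / frame_rate


@dataclass(frozen=True)
class FrameSeries:
    """One-hot subtype raster: integer code per frame (0 = silence)."""

    codes: np.ndarray  # int16, length n_frames
    frame_rate: float

    @property
    def n_frames(self) -> int:
        return int(self.codes.size)

    def labels(self) -> list[str]:
        return [CODE_TO_LABEL.get(int(c), "silence") for c in self.codes]

    def frame_count(self, subtype: str) -> int:
        return int(np.count_nonzero(self.codes == SUBTYPE_CODES[subtype]))


@dataclass(frozen=True)
class ZoneTimeline:
    """Zone name per frame; ``"neutral"`` for the platform and any
    unmapped point, ``"gap"`` where tracking was unresolvable."""

    zones: np.ndarray  # object array of zone names
    frame_rate: float

    @property
    def n_frames(self) -> int:
        return int(self.zones.size)

    def occupancy_frames(self, zone: str) -> int:
        return int(np.count_nonzero(self.zones == zone))


@dataclass(frozen=True)
class ZoneSubtypeCounts:
    """Call-frame counts per zone x subtype plus per-zone occupancy.

    ``counts[zone][subtype]`` is the number of frames the animal spent
    in *zone* while a call of *subtype* was on the raster; occupancy is
    in frames, with seconds derived as frames / frame_rate.
    """

    counts: dict[str, dict[str, int]]
    occupancy_frames: dict[str, int]
    frame_rate: float

    def occupancy_seconds(self, zone: str) -> float:
        return self.occupancy_frames.get(zone, 0) / self.frame_rate

    @property
    def zones(self) -> tuple[str, ...]:
        return tuple(sorted(self.occupancy_frames))

    def total_labeled_frames(self) -> int:
        return sum(sum(z.values()) for z in self.counts.values())

    def subtype_totals(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for zc in self.counts.values():
            for s, n in zc.items():
                out[s] = out.get(s, 0) + n
        return out


def select_channel(call: CallLabel) -> int:
    """Pick the 1-based recording channel with the largest amplitude.

    Ties break to the lowest index; a call with no amplitudes but a
    pre-selected channel passes that through.
    """
    if call.amplitudes is None:
        if call.channel is None:
            raise ValueError("call has neither amplitudes nor a channel")
        return call.channel
    return int(np.argmax(call.amplitudes)) + 1


def _frame_span(start: float, end: float, frame_rate: float) -> tuple[int, int]:
    """Half-open frame index range [k0, k1) of frames a call overlaps."""
    k0 = int(math.floor(start * frame_rate))
    k1 = int(math.ceil(end * frame_rate))
    return k0, k1


def rasterize_labels(
    calls: list[CallLabel] | tuple[CallLabel, ...],
    frame_rate: float,
    duration: float,
) -> FrameSeries:
    """One-hot rasterization of call intervals.

    Calls must lie within ``[0, duration)``; overlapping calls of
    different subtypes violate the one-hot constraint and raise.
    Overlaps of the *same* subtype merge silently.  Two non-overlapping
    calls may still share the frame straddling their boundary; the
    earlier call keeps it (the frame stays one-hot).
    """
    n = n_frames_for(duration, frame_rate)
    codes = np.zeros(n, dtype=np.int16)
    ordered = sorted(calls, key=lambda c: (c.start, c.end))
    prev_end = -np.inf
    prev_subtype: str | None = None
    for c in ordered:
        if c.end <= c.start:
            raise ValueError(f"zero-length call at t={c.start}")
        if c.start < 0 or c.start >= duration:
            raise ValueError(
                f"call at t={c.start} outside trial [0, {duration})"
            )
        if c.start < prev_end and c.subtype != prev_subtype:
            raise ValueError(
                f"one-hot violation: {c.subtype!r} call at t={c.start} "
                f"overlaps a {prev_subtype!r} call"
            )
        k0, k1 = _frame_span(c.start, min(c.end, duration), frame_rate)
        k1 = min(k1, n)
        code = SUBTYPE_CODES[c.subtype]
        seg = codes[k0:k1]
        # an earlier call may already own the boundary frame; it keeps it
        seg[seg == SILENCE_CODE] = code
        prev_end = max(prev_end, c.end)
        prev_subtype = c.subtype
    return FrameSeries(codes=codes, frame_rate=frame_rate)


def assign_zones(
    tracks: list[TrackRecord] | tuple[TrackRecord, ...],
    zone_map: ZoneMap,
    frame_rate: float,
    duration: float,
) -> ZoneTimeline:
    """Per-frame zone assignment from tracking samples.

    Each frame takes the zone of the non-gap sample nearest in time to
    the frame start, provided it lies within one frame period; frames
    without such a sample become gaps.
    """
    if not tracks:
        raise ValueError("empty track")
    n = n_frames_for(duration, frame_rate)
    t = np.array([r.t for r in tracks], dtype=float)
    x = np.array([r.x for r in tracks], dtype=float)
    y = np.array([r.y for r in tracks], dtype=float)
    valid = ~(np.isnan(x) | np.isnan(y))
    tv, xv, yv = t[valid], x[valid], y[valid]

    zones = np.full(n, GAP, dtype=object)
    if tv.size:
        frame_t = np.arange(n, dtype=float) / frame_rate
        idx = np.searchsorted(tv, frame_t)
        left = np.clip(idx - 1, 0, tv.size - 1)
        right = np.clip(idx, 0, tv.size - 1)
        pick = np.where(
            np.abs(tv[right] - frame_t) < np.abs(frame_t - tv[left]),
            right, left,
        )
        dist = np.abs(tv[pick] - frame_t)
        ok = dist <= (1.0 / frame_rate) + 1e-12

        # vectorized point-in-polygon per zone; unmatched points -> neutral
        zname = np.full(tv.size, NEUTRAL, dtype=object)
        unset = np.ones(tv.size, dtype=bool)
        for name in zone_map.zone_names:
            poly = zone_map.zones[name]
            if not np.any(unset):
                break
            inside = shapely.contains_xy(poly, xv[unset], yv[unset]) | \
                shapely.intersects_xy(poly.exterior, xv[unset], yv[unset])
            sel = np.nonzero(unset)[0][inside]
            zname[sel] = name
            unset[sel] = False
        zones[ok] = zname[pick[ok]]
    return ZoneTimeline(zones=zones, frame_rate=frame_rate)


def tabulate(frames: FrameSeries, zones: ZoneTimeline) -> ZoneSubtypeCounts:
    """Cross-tabulate call frames by zone and subtype.

    Conservation holds by construction: summing counts over all zones
    (neutral included) recovers the raster's labeled-frame total, and
    per-zone occupancies sum to the frame count net of gaps.
    """
    if frames.n_frames != zones.n_frames:
        raise ValueError(
            f"length mismatch: {frames.n_frames} label frames vs "
            f"{zones.n_frames} zone frames"
        )
    counts: dict[str, dict[str, int]] = {}
    occupancy: dict[str, int] = {}
    zone_names = np.unique(zones.zones)
    for zname in zone_names:
        mask = zones.zones == zname
        if zname == GAP:
            continue
        occupancy[str(zname)] = int(np.count_nonzero(mask))
        zcodes = frames.codes[mask]
        labeled = zcodes[zcodes != SILENCE_CODE]
        if labeled.size:
            vals, cnts = np.unique(labeled, return_counts=True)
            counts[str(zname)] = {
                CODE_TO_LABEL[int(v)]: int(c) for v, c in zip(vals, cnts)
            }
        else:
            counts[str(zname)] = {}
    return ZoneSubtypeCounts(
        counts=counts, occupancy_frames=occupancy, frame_rate=frames.frame_rate
    )
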