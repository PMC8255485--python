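"""Synthetic cohorts with known ground truth.

Stands in for raw recordings of the paradigm (none are publicly
available): every downstream stage — file ingestion, 25 Hz
synchronization, occupancy-normalized scoring, the statistical
battery — can be exercised against planted parameters.

The generative model, kept deliberately minimal:

* **Occupancy** is a semi-Markov shuttle: exponential dwell in a reward
  zone, return to the neutral platform (exponential dwell there), then
  a Bernoulli choice of the next reward zone whose probability is
  derived from the target preference (the long-run fraction of
  reward-zone time spent in the focal zone).
* **Calls** form a zone-inhomogeneous Poisson process per subtype,
  thinned to enforce the one-hot constraint (no two calls overlap in
  time).  Call durations are gamma distributed: short ~35 ms for the
  50-kHz family, seconds-long for 22-kHz alarm calls.  Emission rates
  are calibrated so that a zone's expected combined vocalization score
  (frames per occupied second) hits a target: a call of mean duration
  d lights 1 + d*rate_frames frames in expectation, so the call rate
  for a subtype is ``cvs_target * mix / (1 + frame_rate * d)``.
* **Microphones**: four channels; a call's amplitude on each channel is
  a source level minus ``20*log10(1 + d/d0)`` distance attenuation plus
  Gaussian noise, so the nearest microphone is loudest in expectation.

Ground-truth per-zone, per-subtype frame counts are computed here with
an independent per-call frame loop (not via the sync module), so the
exact round-trip check does not test a path against itself.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import yaml

from .io_formats import (
    DEFAULT_ZONE_CONFIG,
    CallLabel,
    LabelDialect,
    TrackDialect,
    TrackRecord,
    TrialMeta,
    ZoneMap,
    build_zone_map,
    sucrose_level,
    write_label_table,
    write_track_table,
)
from .sync import GAP, NEUTRAL, ZoneTimeline, n_frames_for
from .vocabulary import KHZ22, SUBTYPES_50KHZ, UNCLEAR

# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OccupancyModel:
    """Semi-Markov shuttle between two open reward zones via the
    neutral platform."""

    focal_zone: str
    other_zone: str
    target_preference: float  # fraction of reward-zone time in focal zone
    mean_dwell_focal: float = 25.0
    mean_dwell_other: float = 25.0
    mean_dwell_neutral: float = 5.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_preference <= 1.0):
            raise ValueError("target_preference must be in [0, 1]")
        for v in (self.mean_dwell_focal, self.mean_dwell_other,
                  self.mean_dwell_neutral):
            if v <= 0:
                raise ValueError("dwell means must be positive")

    @property
    def p_choose_focal(self) -> float:
        """Entry probability into the focal zone from neutral such that
        the expected reward-time fraction equals the target."""
        tp = self.target_preference
        mf, mo = self.mean_dwell_focal, self.mean_dwell_other
        denom = tp * mo + (1.0 - tp) * mf
        return tp * mo / denom

    def transition_matrix(self) -> pd.DataFrame:
        """Rows (from-zone) sum to 1 over {focal, other, neutral}."""
        q = self.p_choose_focal
        rows = {
            self.focal_zone: {self.focal_zone: 0.0, self.other_zone: 0.0,
                              NEUTRAL: 1.0},
            self.other_zone: {self.focal_zone: 0.0, self.other_zone: 0.0,
                              NEUTRAL: 1.0},
            NEUTRAL: {self.focal_zone: q, self.other_zone: 1.0 - q,
                      NEUTRAL: 0.0},
        }
        return pd.DataFrame(rows).T


@dataclass(frozen=True)
class DurationSpec:
    """Gamma call-duration distribution (seconds)."""

    mean: float
    shape: float = 4.0

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.shape <= 0:
            raise ValueError("duration mean and shape must be positive")


#: Default call durations: the 50-kHz family is 30-40 ms, 22-kHz calls
#: run seconds.
DEFAULT_DURATIONS: dict[str, DurationSpec] = {
    **{s: DurationSpec(0.035) for s in SUBTYPES_50KHZ},
    "Short": DurationSpec(0.02),
    UNCLEAR: DurationSpec(0.035),
    KHZ22: DurationSpec(1.8, shape=6.0),
}


@dataclass(frozen=True)
class EmissionModel:
    """Per-zone, per-subtype call emission rates (calls per occupied
    second) plus call-duration distributions."""

    rates: dict[str, dict[str, float]]  # zone name -> subtype -> calls/s
    durations: dict[str, DurationSpec] = field(
        default_factory=lambda: dict(DEFAULT_DURATIONS))

    def __post_init__(self) -> None:
        for zone, zr in self.rates.items():
            for s, r in zr.items():
                if s not in DEFAULT_DURATIONS and s not in self.durations:
                    raise ValueError(f"no duration spec for subtype {s!r}")
                if not np.isfinite(r) or r < 0:
                    raise ValueError(f"rate for {zone}/{s} must be >= 0")


def rates_from_cvs(
    cvs_target: float,
    mix: dict[str, float],
    frame_rate: float = 25.0,
    durations: dict[str, DurationSpec] | None = None,
) -> dict[str, float]:
    """Subtype call rates whose expected combined score is *cvs_target*.

    *mix* gives each subtype's share of call frames; it is normalized to
    sum to 1.  A call of mean duration d occupies ``1 + frame_rate*d``
    frames in expectation, which sets the calls/s needed per subtype.
    """
    durations = durations or DEFAULT_DURATIONS
    total = sum(mix.values())
    if total <= 0:
        raise ValueError("mix must have positive mass")
    return {
        s: cvs_target * (w / total) / (1.0 + frame_rate * durations[s].mean)
        for s, w in mix.items()
    }


@dataclass(frozen=True)
class MicArrayModel:
    """Four-microphone array with log-distance amplitude attenuation."""

    positions: tuple[tuple[float, float], ...] = (
        (14.0, 72.0), (72.0, -14.0), (-14.0, -72.0), (-72.0, 14.0))
    source_level_db: float = -10.0
    d0_cm: float = 10.0
    noise_sd_db: float = 2.0

    def __post_init__(self) -> None:
        if len(self.positions) != 4:
            raise ValueError("exactly 4 microphones required")
        if self.d0_cm <= 0 or self.noise_sd_db < 0:
            raise ValueError("bad attenuation parameters")

    def amplitudes(self, x: float, y: float,
                   rng: np.random.Generator) -> tuple[float, ...]:
        out = []
        for mx, my in self.positions:
            d = math.hypot(x - mx, y - my)
            amp = self.source_level_db - 20.0 * math.log10(1.0 + d / self.d0_cm)
            if self.noise_sd_db > 0:
                amp += rng.normal(0.0, self.noise_sd_db)
            out.append(amp)
        return tuple(out)


# ---------------------------------------------------------------------------
# Trajectory generation
# ---------------------------------------------------------------------------


def _dwell_segments(model: OccupancyModel, duration: float,
                    rng: np.random.Generator) -> list[tuple[float, float, str]]:
    """(t0, t1, zone) segments covering [0, duration); starts neutral."""
    segs: list[tuple[float, float, str]] = []
    t = 0.0
    zone = NEUTRAL
    q = model.p_choose_focal
    means = {model.focal_zone: model.mean_dwell_focal,
             model.other_zone: model.mean_dwell_other,
             NEUTRAL: model.mean_dwell_neutral}
    while t < duration:
        dwell = rng.exponential(means[zone])
        t1 = min(t + dwell, duration)
        segs.append((t, t1, zone))
        t = t1
        if zone == NEUTRAL:
            zone = model.focal_zone if rng.random() < q else model.other_zone
        else:
            zone = NEUTRAL
    return segs


def timeline_from_segments(
    segments: list[tuple[float, float, str]],
    duration: float, frame_rate: float,
) -> ZoneTimeline:
    n = n_frames_for(duration, frame_rate)
    zones = np.full(n, NEUTRAL, dtype=object)
    for t0, t1, zone in segments:
        k0 = int(math.floor(t0 * frame_rate))
        k1 = min(int(math.ceil(t1 * frame_rate)), n)
        # a frame belongs to the segment active at the frame start
        if t0 > k0 / frame_rate + 1e-12:
            k0 += 1
        zones[k0:k1] = zone
    return ZoneTimeline(zones=zones, frame_rate=frame_rate)


def _uniform_points_in(polygon, n: int, rng: np.random.Generator,
                       margin: float = 1.0) -> np.ndarray:
    """Uniform points strictly inside a polygon (rejection sampling on a
    polygon shrunk by *margin* cm, so points survive any boundary
    convention downstream)."""
    inner = polygon.buffer(-margin)
    if inner.is_empty:
        inner = polygon
    minx, miny, maxx, maxy = inner.bounds
    pts = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(4 * (n - got), 16)
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        ok = shapely.contains_xy(inner, xs, ys)
        take = min(int(ok.sum()), n - got)
        sel = np.nonzero(ok)[0][:take]
        pts[got:got + take, 0] = xs[sel]
        pts[got:got + take, 1] = ys[sel]
        got += take
    return pts


def generate_trajectory(
    model: OccupancyModel,
    zone_map: ZoneMap,
    duration: float,
    frame_rate: float,
    rng: np.random.Generator,
) -> tuple[list[TrackRecord], ZoneTimeline]:
    """One position sample per frame, each inside its zone's polygon
    (neutral frames inside the central disc)."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if frame_rate <= 0:
        raise ValueError("frame rate must be positive")
    segments = _dwell_segments(model, duration, rng)
    timeline = timeline_from_segments(segments, duration, frame_rate)
    n = timeline.n_frames
    xy = np.empty((n, 2))
    from shapely.geometry import Point
    neutral_disc = Point(*zone_map.neutral_center).buffer(
        zone_map.neutral_radius)
    for zone in np.unique(timeline.zones):
        mask = timeline.zones == zone
        poly = neutral_disc if zone == NEUTRAL else zone_map.zones[str(zone)]
        xy[mask] = _uniform_points_in(poly, int(mask.sum()), rng)
    t = np.arange(n) / frame_rate
    return ([TrackRecord(float(t[k]), float(xy[k, 0]), float(xy[k, 1]))
             for k in range(n)], timeline)


# ---------------------------------------------------------------------------
# Call generation
# ---------------------------------------------------------------------------


def generate_calls(
    model: EmissionModel,
    timeline: ZoneTimeline,
    mics: MicArrayModel,
    rng: np.random.Generator,
    positions: np.ndarray | None = None,
) -> list[CallLabel]:
    """Zone-dependent Poisson call emission, thinned to non-overlap.

    *positions* (n_frames x 2) locates the caller for the amplitude
    model; without it the maze center is used.  All-zero rates yield an
    empty list.
    """
    frame_rate = timeline.frame_rate
    duration = timeline.n_frames / frame_rate
    zones = timeline.zones
    # contiguous zone segments
    change = np.nonzero(zones[1:] != zones[:-1])[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [timeline.n_frames]])

    candidates: list[tuple[float, float, str]] = []
    for k0, k1 in zip(starts, ends):
        zone = str(zones[k0])
        zrates = model.rates.get(zone)
        if not zrates:
            continue
        t0, t1 = k0 / frame_rate, k1 / frame_rate
        span = t1 - t0
        for subtype, rate in sorted(zrates.items()):
            if rate <= 0:
                continue
            n_calls = rng.poisson(rate * span)
            if n_calls == 0:
                continue
            call_starts = rng.uniform(t0, t1, n_calls)
            spec = model.durations.get(subtype, DEFAULT_DURATIONS[subtype])
            durs = rng.gamma(spec.shape, spec.mean / spec.shape, n_calls)
            durs = np.maximum(durs, 1e-3)
            for s, dcall in zip(call_starts, durs):
                candidates.append((float(s), float(min(s + dcall, duration)),
                                   subtype))
    candidates.sort()
    calls: list[CallLabel] = []
    prev_end = 0.0
    for start, end, subtype in candidates:
        if start < prev_end or end <= start:
            continue  # thinning: enforce the one-hot constraint
        if positions is not None:
            k = min(int(start * frame_rate), positions.shape[0] - 1)
            sx, sy = float(positions[k, 0]), float(positions[k, 1])
        else:
            sx, sy = 0.0, 0.0
        amps = mics.amplitudes(sx, sy, rng)
        calls.append(CallLabel(start, end, subtype, amps))
        prev_end = end
    return calls


def ground_truth_counts(
    calls: list[CallLabel], timeline: ZoneTimeline,
) -> dict[str, dict[str, int]]:
    """Per-zone, per-subtype frame counts implied by the generated calls.

    Independent per-call frame loop with the same binning conventions
    the pipeline documents: a frame is lit by any positive overlap, and
    when two adjacent calls share a boundary frame the earlier call
    keeps it.  Frames on tracking gaps are not counted.
    """
    fr = timeline.frame_rate
    n = timeline.n_frames
    counts: dict[str, dict[str, int]] = {}
    prev_k1 = 0
    for c in sorted(calls, key=lambda c: (c.start, c.end)):
        k0 = int(math.floor(c.start * fr))
        k1 = min(int(math.ceil(c.end * fr)), n)
        k0 = max(k0, prev_k1)  # earlier call keeps a shared boundary frame
        for k in range(k0, k1):
            zone = str(timeline.zones[k])
            if zone == GAP:
                continue
            zc = counts.setdefault(zone, {})
            zc[c.subtype] = zc.get(c.subtype, 0) + 1
        prev_k1 = max(prev_k1, k1)
    return counts


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror the paradigm's design: 10-minute trials rasterized
    at 25 Hz, eight analyzed animals, two labeled sucrose-discrimination
    conditions over two repetition days, and three social-sucrose
    conditions of one day each.
    """

    n_animals: int = 8
    sdt_conditions: tuple[str, ...] = ("2v10", "5v10")
    sdt_days: tuple[int, ...] = (2, 3)
    sspt_conditions: tuple[str, ...] = ("Jv2", "Jv5", "Jv10")
    trial_duration: float = 600.0
    frame_rate: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trial_duration <= 0 or self.frame_rate <= 0:
            raise ValueError("duration and frame rate must be positive")
        if any(c not in ("2v5", "2v10", "5v10") for c in self.sdt_conditions):
            raise ValueError("illegal SDT condition")
        if any(c not in ("Jv2", "Jv5", "Jv10") for c in self.sspt_conditions):
            raise ValueError("illegal SSPT condition")

    def trial_metas(self) -> list[TrialMeta]:
        metas: list[TrialMeta] = []
        seen: set[str] = set()
        for i in range(self.n_animals):
            animal = f"rat{i + 1:02d}"
            group = "A" if i % 2 == 0 else "B"
            for cond in self.sdt_conditions:
                for day in self.sdt_days:
                    metas.append(TrialMeta(animal, "SDT", cond, day, group))
            for day, cond in enumerate(self.sspt_conditions, start=1):
                metas.append(TrialMeta(animal, "SSPT", cond, day, group))
        for m in metas:
            if m.key in seen:
                raise ValueError(f"duplicate trial key {m.key}")
            seen.add(m.key)
        return metas


#: Group-mean occupancy preferences (fraction of reward-zone time in the
#: focal zone) defining the default study conditions: SDT preference for
#: the sweeter side grows over repetition days; SSPT juvenile preference
#: falls as the competing sucrose concentration rises.
SDT_PREFERENCE_BY_DAY = {1: 0.633, 2: 0.691, 3: 0.817}
SSPT_PREFERENCE = {"Jv2": 0.615, "Jv5": 0.547, "Jv10": 0.194}

#: Default combined-score targets (call frames per occupied second).
SDT_CVS = {  # condition -> (focal/high zone, other/low zone)
    "2v5": (0.17, 0.30),
    "2v10": (0.21, 0.407),
    "5v10": (0.13, 0.213),
}
SSPT_CVS_OTHER = 0.313     # non-social (sucrose) zone
SSPT_DELTA_BASE = 0.048    # dCVS at zero sucrose
SSPT_DELTA_SLOPE = 0.034   # dCVS per sucrose percentage point
NEUTRAL_CVS = 0.08
#: 22-kHz call rates (calls/s); a single alarm call runs seconds and
#: fills ~46 raster frames, so these low rates still leave roughly a
#: quarter of all labeled frames in the 22-kHz category.
RATE_22KHZ = {"focal": 0.001, "other": 0.003, NEUTRAL: 0.003}

#: Subtype mixes (shares of 50-kHz call frames). The social zone is
#: trill-dominated, non-social zones flat-dominated; the six rare
#: subtypes stay below the 2% prevalence cut-off.
_RARE = {s: 0.006 for s in ("Step-Down", "Inverted-U", "Step-Up",
                            "Multi-Step", "Downward-Ramp", "Upward-Ramp")}
MIX_SOCIAL = {
    "Trill": 0.33, "Flat": 0.14, "Composite": 0.14, "Complex": 0.12,
    "Short": 0.06, "Flat-Trill-combination": 0.05, "Trill-with-Jump": 0.03,
    "Split": 0.02, UNCLEAR: 0.06, **_RARE,
}
MIX_NONSOCIAL = {
    "Flat": 0.46, "Trill": 0.13, "Complex": 0.10, "Split": 0.06,
    "Short": 0.05, "Composite": 0.05, "Flat-Trill-combination": 0.02,
    "Trill-with-Jump": 0.01, UNCLEAR: 0.04, **_RARE,
}

#: Animal-level heterogeneity: multiplicative vocal propensity (lognormal
#: sigma), additive random intercept on the social-zone rate (frames/s),
#: and logit-scale jitter of occupancy preference.
PROPENSITY_SIGMA = 0.25
DELTA_INTERCEPT_SD = 0.08
PREFERENCE_LOGIT_SD = 0.3


def _substream(seed: int, *parts: str) -> np.random.Generator:
    """Deterministic per-key substream: master seed plus a CRC32 of the
    key, kept below 2**31."""
    tag = zlib.crc32("/".join(parts).encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


@dataclass(frozen=True)
class AnimalEffects:
    propensity: float
    delta_intercept: float
    pref_logit_shift: float


def animal_effects(config: SimConfig, animal: str) -> AnimalEffects:
    rng = _substream(config.seed, "animal", animal)
    return AnimalEffects(
        propensity=float(np.exp(rng.normal(-PROPENSITY_SIGMA ** 2 / 2,
                                           PROPENSITY_SIGMA))),
        delta_intercept=float(rng.normal(0.0, DELTA_INTERCEPT_SD)),
        pref_logit_shift=float(rng.normal(0.0, PREFERENCE_LOGIT_SD)),
    )


def _jitter_preference(p: float, shift: float) -> float:
    logit = math.log(p / (1.0 - p)) + shift
    return 1.0 / (1.0 + math.exp(-logit))


def _inflate_for_thinning(
    rates: dict[str, float],
    durations: dict[str, DurationSpec] | None = None,
) -> dict[str, float]:
    """Compensate the non-overlap thinning loss.

    Thinning drops a candidate call when it starts inside an accepted
    one, so accepted rates fall short of candidate rates by the busy
    fraction of the line: accepted = candidate * (1 - busy).  Feeding
    the desired accepted rates through ``1 / (1 - busy)`` keeps the
    realized zone scores on their calibration targets (the loss grows
    with the rate, which would otherwise compress planted between-zone
    contrasts).
    """
    durations = durations or DEFAULT_DURATIONS
    busy = sum(r * durations[s].mean for s, r in rates.items())
    if busy >= 0.5:
        raise ValueError("emission rates too high: busy fraction >= 0.5")
    factor = 1.0 / (1.0 - busy)
    return {s: r * factor for s, r in rates.items()}


def trial_models(
    config: SimConfig, meta: TrialMeta, zone_map: ZoneMap,
    delta_slope: float = SSPT_DELTA_SLOPE,
) -> tuple[OccupancyModel, EmissionModel]:
    """Planted occupancy and emission models for one trial."""
    eff = animal_effects(config, meta.animal)
    focal_zone, other_zone = zone_map.zones_for(meta)
    if meta.task == "SDT":
        base_pref = SDT_PREFERENCE_BY_DAY[meta.day]
        cvs_focal, cvs_other = SDT_CVS[meta.condition]
        cvs_focal *= eff.propensity
        cvs_other *= eff.propensity
        mix_focal = mix_other = MIX_NONSOCIAL
    else:
        base_pref = SSPT_PREFERENCE[meta.condition]
        suc = sucrose_level(meta.condition)
        cvs_other = SSPT_CVS_OTHER * eff.propensity
        cvs_focal = (cvs_other + SSPT_DELTA_BASE + delta_slope * suc
                     + eff.delta_intercept)
        mix_focal, mix_other = MIX_SOCIAL, MIX_NONSOCIAL
    cvs_focal = max(cvs_focal, 0.005)
    cvs_other = max(cvs_other, 0.005)
    occupancy = OccupancyModel(
        focal_zone=focal_zone, other_zone=other_zone,
        target_preference=_jitter_preference(base_pref,
                                             eff.pref_logit_shift),
    )
    fr = config.frame_rate
    rates = {
        focal_zone: _inflate_for_thinning(
            {**rates_from_cvs(cvs_focal, mix_focal, fr),
             KHZ22: RATE_22KHZ["focal"]}),
        other_zone: _inflate_for_thinning(
            {**rates_from_cvs(cvs_other, mix_other, fr),
             KHZ22: RATE_22KHZ["other"]}),
        NEUTRAL: _inflate_for_thinning(
            {**rates_from_cvs(NEUTRAL_CVS * eff.propensity,
                              MIX_NONSOCIAL, fr),
             KHZ22: RATE_22KHZ[NEUTRAL]}),
    }
    return occupancy, EmissionModel(rates=rates)


@dataclass
class TrialSim:
    """One simulated trial with its ground truth."""

    meta: TrialMeta
    calls: list[CallLabel]
    tracks: list[TrackRecord] | None
    timeline: ZoneTimeline
    focal_zone: str
    other_zone: str
    true_counts: dict[str, dict[str, int]]

    def occupancy_frames(self, zone: str) -> int:
        return self.timeline.occupancy_frames(zone)


def simulate_trial(
    config: SimConfig, meta: TrialMeta, zone_map: ZoneMap,
    with_positions: bool = True,
    delta_slope: float = SSPT_DELTA_SLOPE,
    mics: MicArrayModel | None = None,
) -> TrialSim:
    mics = mics or MicArrayModel()
    occupancy, emission = trial_models(config, meta, zone_map, delta_slope)
    rng = _substream(config.seed, "trial", meta.key)
    if with_positions:
        tracks, timeline = generate_trajectory(
            occupancy, zone_map, config.trial_duration, config.frame_rate, rng)
        positions = np.array([[r.x, r.y] for r in tracks])
    else:
        segments = _dwell_segments(occupancy, config.trial_duration, rng)
        timeline = timeline_from_segments(segments, config.trial_duration,
                                          config.frame_rate)
        tracks, positions = None, None
    calls = generate_calls(emission, timeline, mics, rng, positions)
    return TrialSim(
        meta=meta, calls=calls, tracks=tracks, timeline=timeline,
        focal_zone=occupancy.focal_zone, other_zone=occupancy.other_zone,
        true_counts=ground_truth_counts(calls, timeline),
    )


def simulate_cohort(
    config: SimConfig, zone_map: ZoneMap | None = None,
    with_positions: bool = False,
    delta_slope: float = SSPT_DELTA_SLOPE,
) -> list[TrialSim]:
    """In-memory cohort (fast path: no position sampling by default)."""
    zone_map = zone_map or build_zone_map()
    return [simulate_trial(config, m, zone_map, with_positions, delta_slope)
            for m in config.trial_metas()]


def cohort_delta_table(sims: list[TrialSim]) -> pd.DataFrame:
    """Per-trial delta scores straight from simulated ground truth.

    Bypasses file I/O and rasterization (whose exactness the round-trip
    suite checks separately); used for parameter-recovery experiments
    where thousands of cohorts are scored.
    """
    from . import scoring
    from .sync import ZoneSubtypeCounts

    trials = []
    for s in sims:
        occ = {str(z): s.timeline.occupancy_frames(str(z))
               for z in np.unique(s.timeline.zones) if str(z) != GAP}
        zc = ZoneSubtypeCounts(counts=s.true_counts, occupancy_frames=occ,
                               frame_rate=s.timeline.frame_rate)
        trials.append((s.meta, zc, s.focal_zone, s.other_zone))
    return scoring.delta_table(scoring.score_cohort(trials))


@dataclass(frozen=True)
class CohortDataset:
    """A written-to-disk cohort: manifest path plus its parsed content."""

    root: Path
    manifest: dict

    @property
    def manifest_path(self) -> Path:
        return self.root / "manifest.yaml"


def generate_cohort(
    config: SimConfig,
    outdir: str | Path,
    zone_map_config: dict | None = None,
    delta_slope: float = SSPT_DELTA_SLOPE,
) -> CohortDataset:
    """Write a complete synthetic cohort: per-trial label and track
    tables, a YAML manifest, and ground-truth sidecar CSVs.

    Byte-deterministic for a fixed config (same seed twice gives
    identical files).
    """
    root = Path(outdir)
    (root / "trials").mkdir(parents=True, exist_ok=True)
    zone_map = build_zone_map(zone_map_config)
    metas = config.trial_metas()

    trial_entries = []
    gt_rows = []
    occ_rows = []
    for meta in metas:
        sim = simulate_trial(config, meta, zone_map, with_positions=True,
                             delta_slope=delta_slope)
        lpath = f"trials/{meta.key}_labels.csv"
        tpath = f"trials/{meta.key}_tracks.csv"
        write_label_table(sim.calls, root / lpath, LabelDialect())
        write_track_table(sim.tracks, root / tpath, TrackDialect())
        trial_entries.append({
            "animal": meta.animal, "task": meta.task,
            "condition": meta.condition, "day": int(meta.day),
            "group": meta.group, "labels": lpath, "tracks": tpath,
        })
        for zone in sorted(sim.true_counts):
            for subtype in sorted(sim.true_counts[zone]):
                gt_rows.append({
                    "trial": meta.key, "zone": zone, "subtype": subtype,
                    "frames": sim.true_counts[zone][subtype],
                })
        for zone in sorted(np.unique(sim.timeline.zones)):
            occ_rows.append({
                "trial": meta.key, "zone": str(zone),
                "frames": sim.timeline.occupancy_frames(str(zone)),
            })

    manifest = {
        "seed": int(config.seed),
        "frame_rate": float(config.frame_rate),
        "trial_duration": float(config.trial_duration),
        "zone_map": zone_map_config or dict(DEFAULT_ZONE_CONFIG),
        "delta_slope": float(delta_slope),
        "trials": trial_entries,
    }
    with open(root / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    pd.DataFrame(gt_rows).to_csv(root / "ground_truth_counts.csv", index=False)
    pd.DataFrame(occ_rows).to_csv(root / "ground_truth_occupancy.csv",
                                  index=False)
    return CohortDataset(root=root, manifest=manifest)
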