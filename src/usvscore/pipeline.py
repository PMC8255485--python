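"""End-to-end orchestration: simulate -> ingest -> sync -> score -> stats.

Each stage reads and writes plain CSV/YAML in the run directory, so a
later stage can be re-run on saved outputs and reproduce its results
bit-exactly.  The run log keeps a mandatory audit trail of every
exclusion rule: 22-kHz frames, Unclear frames, prevalence-filtered
subtypes, neutral-platform frames and tracking gaps.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import scoring, stats, sync
from .io_formats import (
    LabelDialect,
    TrackDialect,
    TrialMeta,
    build_zone_map,
    read_label_table,
    read_scores_table,
    read_track_table,
    write_scores_table,
)
from .synthetic import SimConfig, generate_cohort
from .vocabulary import KHZ22, SHORT_CODES, UNCLEAR

log = logging.getLogger("usvscore")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: Path
    mode: str = "synthetic"          # "synthetic" | "files"
    cohort_dir: Path | None = None   # manifest location (files mode)
    zone_map: dict | None = None
    threshold_percent: float = 2.0
    seed: int = 0
    sim: SimConfig | None = None
    label_dialect: LabelDialect = field(default_factory=LabelDialect)
    track_dialect: TrackDialect = field(default_factory=TrackDialect)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "files":
            if self.cohort_dir is None:
                raise ValueError("files mode requires cohort_dir")
            self.cohort_dir = Path(self.cohort_dir)
            if not (self.cohort_dir / "manifest.yaml").exists():
                raise FileNotFoundError(
                    f"no manifest.yaml in {self.cohort_dir}")
        if self.sim is None:
            self.sim = SimConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        sim_raw = raw.pop("sim", None)
        if sim_raw is not None:
            sim_raw.setdefault("seed", raw.get("seed", 0))
            for key in ("sdt_conditions", "sdt_days", "sspt_conditions"):
                if key in sim_raw:
                    sim_raw[key] = tuple(sim_raw[key])
            raw["sim"] = SimConfig(**sim_raw)
        return cls(**raw)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and trial key."""

    def __init__(self, stage: str, trial: str | None, cause: Exception):
        self.stage, self.trial = stage, trial
        where = f"stage {stage!r}" + (f", trial {trial!r}" if trial else "")
        super().__init__(f"{where}: {cause}")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def simulate(config: RunConfig) -> Path:
    """Generate a synthetic cohort under ``outdir/cohort``."""
    if config.mode != "synthetic":
        raise ValueError("simulate only applies to synthetic mode")
    cohort_dir = config.outdir / "cohort"
    sim = dataclasses.replace(config.sim, seed=config.seed)
    generate_cohort(sim, cohort_dir, zone_map_config=config.zone_map)
    log.info("simulated cohort: %d trials -> %s",
             len(sim.trial_metas()), cohort_dir)
    return cohort_dir


def _load_manifest(cohort_dir: Path) -> dict:
    with open(cohort_dir / "manifest.yaml") as fh:
        return yaml.safe_load(fh)


def score(config: RunConfig, cohort_dir: Path | None = None) -> None:
    """Ingest label/track tables, synchronize at the raster rate, and
    write score, preference, delta and count tables."""
    cohort_dir = cohort_dir or (
        config.cohort_dir if config.mode == "files"
        else config.outdir / "cohort")
    manifest = _load_manifest(cohort_dir)
    frame_rate = float(manifest["frame_rate"])
    duration = float(manifest["trial_duration"])
    zone_map = build_zone_map(manifest.get("zone_map") or config.zone_map)

    trials = []
    count_rows = []
    occ_rows = []
    audit = {"frames_22khz": 0, "frames_unclear": 0,
             "frames_neutral_zone": 0, "frames_gap": 0,
             "frames_labeled_total": 0}
    for entry in manifest["trials"]:
        meta = TrialMeta(entry["animal"], entry["task"], entry["condition"],
                         int(entry["day"]), entry.get("group", "A"))
        try:
            calls = read_label_table(cohort_dir / entry["labels"],
                                     config.label_dialect)
            tracks = read_track_table(cohort_dir / entry["tracks"],
                                      config.track_dialect)
            frames = sync.rasterize_labels(calls, frame_rate, duration)
            timeline = sync.assign_zones(tracks, zone_map, frame_rate,
                                         duration)
            counts = sync.tabulate(frames, timeline)
            focal, other = zone_map.zones_for(meta)
            trials.append((meta, counts, focal, other))
        except Exception as err:
            raise StageError("score", meta.key, err) from err

        totals = counts.subtype_totals()
        audit["frames_22khz"] += totals.get(KHZ22, 0)
        audit["frames_unclear"] += totals.get(UNCLEAR, 0)
        audit["frames_labeled_total"] += sum(totals.values())
        neutral_counts = counts.counts.get(sync.NEUTRAL, {})
        audit["frames_neutral_zone"] += sum(neutral_counts.values())
        n_occ = sum(counts.occupancy_frames.values())
        audit["frames_gap"] += frames.n_frames - n_occ
        for zone in sorted(counts.counts):
            for subtype, n in sorted(counts.counts[zone].items()):
                count_rows.append({"trial": meta.key, "zone": zone,
                                   "subtype": subtype, "frames": n})
        for zone in sorted(counts.occupancy_frames):
            occ_rows.append({"trial": meta.key, "zone": zone,
                             "frames": counts.occupancy_frames[zone]})

    scores = scoring.score_cohort(trials)
    prefs = scoring.preference_table(scores)
    deltas = scoring.delta_table(scores)
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    write_scores_table(scores, out / "scores.csv")
    write_scores_table(prefs, out / "preferences.csv")
    write_scores_table(deltas, out / "deltas.csv")
    pd.DataFrame(count_rows).to_csv(out / "counts.csv", index=False)
    pd.DataFrame(occ_rows).to_csv(out / "occupancy.csv", index=False)
    for key, val in sorted(audit.items()):
        log.info("exclusion accounting: %s = %d", key, val)
    with open(out / "exclusions.yaml", "w") as fh:
        yaml.safe_dump({k: int(v) for k, v in audit.items()}, fh,
                       sort_keys=True)


def _mean_over_days(scores: pd.DataFrame, value: str) -> pd.DataFrame:
    """Per animal x condition x role means (collapsing repetition days)."""
    return (scores.groupby(["animal", "task", "condition", "role"],
                           as_index=False)[value].mean())


def analyze(config: RunConfig) -> None:
    """Run the statistical battery on saved score tables."""
    out = config.outdir
    scores = read_scores_table(out / "scores.csv")
    prefs = read_scores_table(out / "preferences.csv")
    deltas = read_scores_table(out / "deltas.csv")
    counts = pd.read_csv(out / "counts.csv")

    results: list[stats.TestResult] = []
    mixed_rows: list[dict] = []

    # --- subtype prevalence filter (pooled over both tasks) ---
    pooled = counts.groupby("subtype")["frames"].sum()
    filt = scoring.subtype_filter(pooled, config.threshold_percent)
    write_scores_table(filt.report(), out / "filter_report.csv")
    excluded_frames = int(sum(
        pooled.get(s, 0) for s in filt.excluded if s not in (UNCLEAR,)))
    log.info("exclusion accounting: frames_filtered_subtypes = %d "
             "(excluded: %s)", excluded_frames,
             ", ".join(SHORT_CODES[s] for s in filt.excluded))
    included = list(filt.included)
    if not included:
        log.warning("no subtypes included at threshold %.3g%%; "
                    "subtype-level analyses skipped",
                    config.threshold_percent)

    # --- behavior: preference ANOVAs and t tests ---
    sdt_pref = prefs[prefs.task == "SDT"]
    if (sdt_pref.condition.nunique() >= 2 and sdt_pref.day.nunique() >= 2):
        try:
            results += stats.rm_anova_within(
                sdt_pref, "preference_percent", "animal",
                ["condition", "day"])
        except ValueError as err:
            log.warning("SDT preference ANOVA skipped: %s", err)
    sspt_pref = prefs[prefs.task == "SSPT"]
    if sspt_pref.condition.nunique() >= 2:
        try:
            results += stats.rm_anova_within(
                sspt_pref, "preference_percent", "animal", ["condition"])
            results += stats.posthoc_pairwise(
                sspt_pref, "preference_percent", "animal", "condition")
        except ValueError as err:
            log.warning("SSPT preference ANOVA skipped: %s", err)
    for cond, grp in sspt_pref.groupby("condition"):
        if len(grp) < 2:
            continue
        r = stats.t_test("one_sample", grp.preference_percent.to_numpy(),
                         50.0, name=f"SSPT {cond}: juvenile pref vs 50%")
        results.append(r)
        r2 = stats.t_test("paired", grp.focal_s.to_numpy(),
                          grp.other_s.to_numpy(),
                          name=f"SSPT {cond}: social vs sucrose zone time")
        results.append(r2)

    # --- combined vocalization score ANOVAs (log CVS as DV) ---
    for task in ("SDT", "SSPT"):
        sub = scores[scores.task == task]
        if sub.empty or sub.condition.nunique() < 2:
            continue
        cell = _mean_over_days(sub, "log_cvs").rename(
            columns={"log_cvs": "dv"})
        try:
            res = stats.rm_anova_within(cell, "dv", "animal",
                                        ["condition", "role"])
            results += [dataclasses.replace(
                r, name=f"{task} log-CVS {r.name}") for r in res]
        except ValueError as err:
            log.warning("%s CVS ANOVA skipped: %s", task, err)

    # --- between-subtype: Kruskal-Wallis on dSVS per condition ---
    if included:
        dcols = {s: f"dsvs_{SHORT_CODES[s]}" for s in included}
        for task in ("SDT", "SSPT"):
            dsub = deltas[deltas.task == task]
            for cond, grp in dsub.groupby("condition"):
                groups = [grp[c].dropna().to_numpy()
                          for c in dcols.values()]
                if any(g.size < 2 for g in groups):
                    continue
                kw = stats.rank_test(
                    "kruskal_wallis", *groups,
                    name=f"{task} {cond}: dSVS between subtypes")
                results.append(kw)
                if kw.p < 0.05:
                    pairs = [(a, b) for i, a in enumerate(included)
                             for b in included[i + 1:]]
                    for a, b in pairs:
                        mw = stats.rank_test(
                            "mann_whitney", grp[dcols[a]].dropna(),
                            grp[dcols[b]].dropna(),
                            name=(f"{task} {cond}: dSVS "
                                  f"{SHORT_CODES[a]} vs {SHORT_CODES[b]}"))
                        mw = dataclasses.replace(
                            mw, p_adjusted=stats.bonferroni(mw.p, len(pairs)))
                        results.append(mw)

        # --- within-subtype: Wilcoxon (SDT), Friedman (SSPT) ---
        sdt_d = deltas[deltas.task == "SDT"]
        conds = sorted(sdt_d.condition.unique())
        if len(conds) == 2:
            wide = sdt_d.pivot_table(index="animal", columns="condition",
                                     values=list(dcols.values()),
                                     observed=True)
            for s in included:
                col = dcols[s]
                try:
                    a = wide[(col, conds[0])].dropna()
                    b = wide[(col, conds[1])].dropna()
                except KeyError:
                    continue
                if len(a) == len(b) and len(a) >= 2:
                    results.append(stats.rank_test(
                        "wilcoxon_signed_rank", a.to_numpy(), b.to_numpy(),
                        name=(f"SDT {SHORT_CODES[s]}: dSVS "
                              f"{conds[0]} vs {conds[1]}")))
        sspt_d = deltas[deltas.task == "SSPT"]
        if sspt_d.condition.nunique() >= 3:
            for s in included:
                wide = sspt_d.pivot_table(index="animal",
                                          columns="condition",
                                          values=dcols[s], observed=True)
                if wide.isna().any().any() or wide.shape[0] < 2:
                    continue
                results.append(stats.rank_test(
                    "friedman", wide.to_numpy(),
                    name=f"SSPT {SHORT_CODES[s]}: dSVS across conditions"))

    # --- mixed linear models: dCVS / dSVS vs sucrose concentration ---
    sspt_rows = deltas[deltas.task == "SSPT"]
    if not sspt_rows.empty and sspt_rows.sucrose_percent.nunique() >= 2:
        try:
            fit = stats.fit_mixed_model(sspt_rows, "dcvs")
            mixed_rows.append({"dv": "dcvs", **fit.as_row()})
        except ValueError as err:
            log.warning("dCVS mixed model skipped: %s", err)
        for s in included:
            try:
                fit = stats.fit_mixed_model(sspt_rows, f"dsvs_{SHORT_CODES[s]}")
                mixed_rows.append(
                    {"dv": f"dsvs_{SHORT_CODES[s]}", **fit.as_row()})
            except ValueError as err:
                log.warning("mixed model for %s skipped: %s", s, err)

    mixed_cols = ["dv", "intercept", "slope", "slope_se", "ci_low", "ci_high",
                  "t", "df", "p", "re_variance", "resid_variance",
                  "r2_marginal", "n_obs", "n_groups", "method", "ci_method",
                  "note"]
    write_scores_table(stats.results_table(results), out / "stats.csv")
    write_scores_table(pd.DataFrame(mixed_rows, columns=mixed_cols),
                       out / "mixed.csv")
    log.info("analyze: %d tests, %d mixed models", len(results),
             len(mixed_rows))


def report(config: RunConfig) -> Path:
    """Condense run outputs into a plain-text summary."""
    out = config.outdir
    lines = ["usvscore run report", "=" * 40]
    excl = out / "exclusions.yaml"
    if excl.exists():
        with open(excl) as fh:
            audit = yaml.safe_load(fh)
        lines.append("exclusion accounting (frames):")
        for k, v in sorted(audit.items()):
            lines.append(f"  {k}: {v}")
    filt = out / "filter_report.csv"
    if filt.exists():
        fr = pd.read_csv(filt)
        kept = fr[fr.included.astype(bool)]
        lines.append(f"subtypes included ({len(kept)}): "
                     + ", ".join(kept.code))
    statsf = out / "stats.csv"
    if statsf.exists():
        st = pd.read_csv(statsf)
        lines.append(f"tests run: {len(st)}")
        sig = st[st.p < 0.05]
        lines.append(f"tests with p < 0.05 (uncorrected): {len(sig)}")
    mixedf = out / "mixed.csv"
    if mixedf.exists():
        mx = pd.read_csv(mixedf)
        for _, row in mx.iterrows():
            lines.append(
                f"mixed model {row['dv']}: slope {row['slope']:.4g} "
                f"[{row['ci_low']:.4g}, {row['ci_high']:.4g}] "
                f"p = {row['p']:.4g}")
    path = out / "report.txt"
    path.write_text("\n".join(lines) + "\n")
    return path


def run_pipeline(config: RunConfig) -> Path:
    """simulate (synthetic mode) -> score -> analyze -> report."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(config.outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        if config.mode == "synthetic":
            cohort_dir = simulate(config)
        else:
            cohort_dir = config.cohort_dir
        score(config, cohort_dir)
        analyze(config)
        return report(config)
    finally:
        handler.close()
        log.removeHandler(handler)
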