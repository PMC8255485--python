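# Methods

This note documents the models, conventions and numerical choices
behind `usvscore`, and what the synthetic-data tests do and do not
establish about real recordings.

## Synchronization model

Call labels arrive as half-open intervals `[start, end)` in seconds
from trial start; tracking arrives as timestamped positions in cm,
origin at the maze center, y toward the juvenile arm of layout
group A.  Both streams are fused on a raster of 40 ms frames
(`frame k = [k/25, (k+1)/25)`); a trial of duration `T` has
`ceil(25·T)` frames.

**Overlap rule.** A frame carries a subtype whenever a call of that
subtype overlaps it by any positive amount.  The alternative (majority
overlap) would erase 30–40 ms calls that straddle a frame boundary;
with the any-overlap rule a call of duration `d` occupies between
`floor(25·d)` and `floor(25·d) + 2` frames, and frame counts are never
below call counts.  Consequences embraced rather than fought: long
22-kHz calls dominate raw frame counts (seconds each, ~46 frames),
which is exactly why they are excluded from the 50-kHz scoring
universe.

**One-hot constraint.** Overlapping calls of different subtypes are an
annotation error and rejected.  Two *adjacent* calls may share the
boundary frame; the earlier call keeps it.  This tie-break is
deterministic, order-independent (calls are sorted by onset), and
preserves the one-hot property.

**Channel selection.** Each call's loudest of the four microphone
channels is selected (argmax; ties to the lowest index); a
pre-selected channel column passes through.

**Zone assignment.** Each frame takes the zone of the non-gap tracking
sample nearest in time within one frame period; frames with no such
sample are *gaps*.  Points inside no zone polygon (the central
platform, arm midsections) fall to *neutral*.  Gap frames are excluded
from both occupancy and call-frame counts; neutral-zone frames are
tabulated but excluded from zone-normalized scores, symmetric with the
exclusion of neutral-zone *time* from the behavioral analysis.

## Zone map

The maze is parameterized, not hard-coded: four arms (14 cm wide,
60 cm long) off a neutral disc (radius 18 cm), each arm holding a
sandpaper zone at its entrance (17 cm deep) and a reward zone at its
distal end.  Reward-zone depth is a config parameter (default 20 cm)
because the physical extent of the scored zone is a tracking-software
setting, not a constant of the apparatus.  Layout groups A and B share
geometry but permute the reward identities (2 %, 5 %, 10 %, Juvenile)
across arms.  Disjointness of polygons and uniqueness of identity
assignments are validated at load.

## Scores

- `CVS_z` = 50-kHz-universe call frames in zone z / occupancy seconds
  of z.  The universe is the 14 subtypes + Unclear; 22 kHz excluded.
- `log CVS = ln(CVS + ε)`, ε = 0.001 frames/s — a floor of about one
  call frame per 1000 s.  Natural log; the offset only matters for
  zero-rate cells and keeps the ANOVA DV finite.  Raw CVS is reported
  alongside; the log enters only where the analysis calls for it.
- `SVS_z(s)` = frames of subtype s in z / occupancy seconds; additivity
  `Σ_s SVS = CVS` holds by construction.
- Deltas: SDT `high − low sucrose zone`; SSPT `social − non-social`.
- Preference: `100·t_focal/(t_focal + t_other)`; undefined (NaN, never
  0) when both zone times are zero.
- Prevalence filter: share of each subtype among all non-22-kHz call
  frames pooled across both tasks (Unclear counts in the denominator,
  consistent with the 15-label CVS universe); a subtype is kept at
  ≥ threshold % (default 2).  Unclear is excluded from subtype-level
  analyses regardless of prevalence.

## Statistical battery

- **Within-subject ANOVA** (1 or 2 factors): balanced-design
  sums-of-squares, each effect tested against its subject-by-effect
  interaction; partial η² = SS_eff/(SS_eff+SS_err).  No sphericity
  correction is applied, matching the analysis convention this
  pipeline reproduces; incomplete designs are rejected, not imputed.
  For a two-level factor, F equals the squared paired t.
- **Post hocs**: paired t over all level pairs, Bonferroni
  (`p_adj = min(1, m·p)`).
- **Rank tests**: midranks for ties.  Exact nulls by enumeration up to
  a configurable total-n cutoff (default 10): Mann–Whitney and
  Kruskal–Wallis enumerate group assignments, Wilcoxon enumerates sign
  patterns, Friedman convolves per-subject rank permutations (a
  dynamic program over column rank-sum vectors, so 8 subjects × 3
  conditions stays cheap).  Asymptotic modes: tie-corrected χ² for
  Kruskal–Wallis/Friedman, normal approximation for Mann–Whitney
  *without* continuity correction — so the two-group Kruskal–Wallis p
  and the Mann–Whitney p coincide — and for Wilcoxon *with* continuity
  correction.
- **Cohen's κ** = (p_o − p_e)/(1 − p_e).
- **Mixed model**: `DV ~ intercept + β·sucrose% + (1 | animal)`, REML
  via statsmodels.  Marginal R² is the variance-partition form
  var(Xβ̂)/(var(Xβ̂)+σ²_animal+σ²_resid).  A singular random-intercept
  variance or non-convergence falls back to pooled OLS with a warning.

**Slope interval.**  The default CI is *cluster-based*: per-animal OLS
slopes `b_i` with `CI = b̄ ± t_{0.975, g−1}·sd(b_i)/√g`.  In this
balanced design the fitted slope equals `b̄`, and the interval stays
calibrated under arbitrary within-animal correlation and
condition-dependent residual variance.  The latter is not hypothetical:
the dCVS measurement error grows sharply in the condition where the
social zone is visited briefly at a high call rate (variance of a
count-rate estimate scales as rate/occupancy), and the homoscedastic
model-based ("Wald") interval under-covers there by several points.
The Wald-t interval (df = n_obs − n_groups − 1, which is 15 at
24 observations / 8 animals) remains available via
`ci_method="wald"`.

## Synthetic cohorts

The generator emulates the study conditions so that planted parameters
are recoverable end-to-end:

- **Design**: 8 animals, 600 s trials at 25 Hz; two labeled SDT
  conditions (2v10, 5v10) × repetition days 2–3; three SSPT conditions
  (Jv2, Jv5, Jv10), one day each.  Layout groups alternate A/B across
  animals.
- **Occupancy**: a semi-Markov shuttle — exponential dwell in a reward
  zone (mean 25 s), exponential dwell on the neutral platform (mean
  5 s) between visits, Bernoulli choice of the next reward zone with
  entry probability derived from the target preference so the expected
  reward-time fraction equals it.  Group-mean targets: SDT preference
  for the sweeter side 63.3/69.1/81.7 % on days 1/2/3; SSPT juvenile
  preference 61.5/54.7/19.4 % for Jv2/Jv5/Jv10.  Positions are drawn
  uniformly inside the occupied zone's polygon (1 cm interior margin).
- **Emission**: per-zone inhomogeneous Poisson candidates per subtype,
  thinned to enforce non-overlap.  Durations are gamma (50-kHz family
  mean 35 ms, Short 20 ms; 22-kHz mean 1.8 s).  A call of mean
  duration d occupies `1 + 25·d` frames in expectation, which converts
  a zone's target CVS into per-subtype call rates; candidate rates are
  further inflated by `1/(1 − busy fraction)` to cancel the thinning
  loss, which otherwise grows with the rate and compresses planted
  between-zone contrasts by a few percent.
- **Targets** (frames/s): SSPT non-social zone 0.313; social zone
  `0.313·f_i + 0.048 + 0.034·c + a_i` (c = sucrose %), i.e. a planted
  dCVS slope of 0.034 per percentage point; SDT low/high zones
  0.407/0.21 (2v10) and 0.213/0.13 (5v10); neutral 0.08.  Animal
  heterogeneity: lognormal vocal propensity `f_i` (σ = 0.25, mean 1),
  Gaussian random intercept `a_i` on the social-zone rate (sd 0.08),
  logit jitter of occupancy preference (sd 0.3).  Subtype mixes are
  trill-dominated in the social zone and flat-dominated elsewhere,
  with six rare subtypes held below the 2 % cut-off; 22-kHz rates are
  set so alarm calls take roughly a quarter of labeled frames.
- **Determinism**: one master seed; per-trial and per-animal
  substreams are derived by hashing the trial/animal key (CRC32,
  folded below 2³¹) into a `SeedSequence`, so cohorts are
  byte-reproducible and order-independent.
- **Ground truth**: per-zone per-subtype frame counts are computed at
  generation time by an independent per-call loop using the same
  documented binning conventions, and written as sidecar CSVs.

**What the generator does not model**: call bouts and serial
dependence between calls, caller identity (experimental vs juvenile
animal — unattributable in the paradigm itself), sandpaper-zone
transit (the shuttle teleports between reward zones and the platform),
tracking dropouts, acoustic waveforms, or day-to-day learning within
the vocal scores.  Passing recovery tests therefore establishes that
the *pipeline arithmetic* is faithful and that the statistical
procedures are calibrated at the experiment's design size — not that real
rat data satisfy the generative assumptions.

## Measured calibration (computed by the test suite / acceptance script)

At the recovery design (500 replicate cohorts, 8 animals × 3 SSPT
conditions): the mean recovered dCVS slope sits within 10 % of the
planted 0.034 (residual shortfall of a few percent from boundary-frame
sharing and zone-exit truncation of calls), and the default CI covers
the truth in 93–97 % of replicates.  The generator→files→pipeline
round-trip reproduces every per-zone per-subtype frame count exactly.

## Numerical conventions

- Times are seconds (floats); label/track files written by the
  generator keep full float precision so frame-bin assignment survives
  the round trip.  Pipeline output CSVs print 6 significant digits;
  undefined scores serialize as empty cells.
- Error messages cite 1-based data rows.
- Exact rank-test p values compare statistics with a 1e-12 slack to
  absorb float jitter in midrank arithmetic.
- Degenerate inputs are flagged, not coerced: zero-variance t tests
  and all-zero Wilcoxon differences return NaN statistics with a note;
  zero occupancy yields NaN scores; an all-100 % prevalence threshold
  runs the pipeline with subtype analyses skipped.

## Problem sizes in the shipped suites

The test and acceptance runs use 2-animal cohorts for file round-trips,
the full 8-animal design for statistics, 500 replicates for recovery,
and 10 000–20 000 s single trials for law-of-large-numbers checks —
sizes chosen to exercise every code path at the experiment's design
scale while keeping a full run in minutes on one CPU.
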