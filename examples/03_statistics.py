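"""The statistical battery on a simulated cohort.

Simulates the default study conditions (8 animals, three social-sucrose
conditions), then asks the two headline questions: do juvenile
preferences differ across competing sucrose concentrations, and does
the social-minus-sucrose vocalization difference (dCVS) grow with
sucrose concentration?
"""

from usvscore.scoring import preference_score
from usvscore.stats import fit_mixed_model, rank_test, rm_anova_within, t_test
from usvscore.synthetic import SimConfig, cohort_delta_table, simulate_cohort

config = SimConfig(n_animals=8, sdt_conditions=(), sdt_days=(), seed=7)
sims = simulate_cohort(config)

# behavioral preference per trial
rows = []
for s in sims:
    focal = s.occupancy_frames(s.focal_zone) / 25.0
    other = s.occupancy_frames(s.other_zone) / 25.0
    rows.append({"animal": s.meta.animal, "condition": s.meta.condition,
                 "preference_percent": preference_score(focal, other).percent})
import pandas as pd
prefs = pd.DataFrame(rows)

(anova,) = rm_anova_within(prefs, "preference_percent", "animal",
                           ["condition"])
print(f"juvenile preference across conditions: "
      f"F({anova.df[0]:.0f}, {anova.df[1]:.0f}) = {anova.statistic:.1f}, "
      f"p = {anova.p:.2g}, partial eta^2 = {anova.effect:.2f}")

for cond, grp in prefs.groupby("condition"):
    r = t_test("one_sample", grp.preference_percent.to_numpy(), 50.0)
    print(f"  {cond}: mean {grp.preference_percent.mean():.0f}% "
          f"(t({r.df}) = {r.statistic:.2f}, p = {r.p:.2g})")

# vocal dose-response: dCVS vs sucrose concentration, random intercept
deltas = cohort_delta_table(sims)
fit = fit_mixed_model(deltas, "dcvs")
print(f"\ndCVS ~ sucrose%: slope = {fit.slope:.4f} frames/s per point "
      f"[{fit.ci_low:.4f}, {fit.ci_high:.4f}], p = {fit.p:.2g} "
      f"(planted slope: 0.034)")

# within-subtype Friedman across the three conditions for Trill
wide = deltas.pivot_table(index="animal", columns="condition",
                          values="dsvs_Tr").dropna()
fr = rank_test("friedman", wide.to_numpy())
print(f"Trill dSVS across conditions: chi2_F({fr.df}) = "
      f"{fr.statistic:.2f}, p = {fr.p:.2g}")

# A preference ANOVA near the planted condition contrast, one-sample
# t tests matching the planted 61/55/19% preferences, and a recovered
# slope near 0.034 show the pipeline reading back what was planted.
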