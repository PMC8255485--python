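"""The paradigm's within-subject statistical battery.

Within-subject (repeated-measures) ANOVAs with partial eta squared,
Bonferroni-corrected pairwise post hocs, one-sample/paired/independent
t tests with Cohen's d, rank tests (Kruskal-Wallis, Mann-Whitney,
Wilcoxon signed-rank, Friedman) with exact small-sample nulls, a
random-intercept mixed linear model for the dose-response of delta
vocalization scores on sucrose concentration, and Cohen's kappa for
inter-rater agreement.

The ANOVA is computed from the balanced-design sums-of-squares
decomposition directly (no sphericity correction is applied, and
incomplete designs are rejected rather than imputed).  Rank tests use
midranks for ties; below a configurable sample-size cutoff their null
distributions are enumerated exactly, above it a tie-corrected normal
or chi-squared approximation is used.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Largest total sample size at which rank-test nulls are enumerated exactly.
EXACT_CUTOFF = 10


@dataclass(frozen=True)
class TestResult:
    """One test outcome: statistic, degrees of freedom, p, effect size."""

    name: str
    statistic_name: str
    statistic: float
    df: float | tuple[float, float] | None
    p: float
    effect_name: str | None = None
    effect: float | None = None
    p_adjusted: float | None = None
    note: str | None = None

    @property
    def degenerate(self) -> bool:
        return self.note is not None and self.note.startswith("degenerate")

    def as_row(self) -> dict:
        df = self.df
        if isinstance(df, tuple):
            df = f"{df[0]:g},{df[1]:g}"
        return {
            "test": self.name,
            "statistic_name": self.statistic_name,
            "statistic": self.statistic,
            "df": df,
            "p": self.p,
            "p_adjusted": self.p_adjusted,
            "effect_name": self.effect_name,
            "effect": self.effect,
            "note": self.note,
        }


RESULT_COLUMNS = ["test", "statistic_name", "statistic", "df", "p",
                  "p_adjusted", "effect_name", "effect", "note"]


def results_table(results: list[TestResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in results],
                        columns=RESULT_COLUMNS)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p value, capped at 1."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return min(1.0, p * m)


# ---------------------------------------------------------------------------
# t tests
# ---------------------------------------------------------------------------

def t_test(
    mode: str,
    x,
    y_or_mu=None,
    alternative: str = "two-sided",
    name: str | None = None,
) -> TestResult:
    """Classical Student t tests with Cohen's d.

    ``mode``: ``one_sample`` (x vs scalar mu), ``paired`` (x vs y of the
    same length; the test runs on x - y) or ``independent``
    (pooled-variance two-sample).  A zero-variance test quantity yields
    a degenerate result (NaN statistic) rather than an infinite t.
    """
    x = np.asarray(x, dtype=float)
    if mode == "one_sample":
        mu = float(y_or_mu)
        if x.size < 2:
            raise ValueError("need at least 2 observations")
        d = x - mu
        label = name or f"one-sample t vs {mu:g}"
        return _t_from_diffs(d, x.size - 1, label, alternative)
    if mode == "paired":
        y = np.asarray(y_or_mu, dtype=float)
        if x.shape != y.shape:
            raise ValueError("paired samples must have equal length")
        if x.size < 2:
            raise ValueError("need at least 2 pairs")
        return _t_from_diffs(x - y, x.size - 1, name or "paired t", alternative)
    if mode == "independent":
        y = np.asarray(y_or_mu, dtype=float)
        if x.size < 2 or y.size < 2:
            raise ValueError("need at least 2 observations per group")
        n1, n2 = x.size, y.size
        v1, v2 = x.var(ddof=1), y.var(ddof=1)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        label = name or "independent t"
        if sp2 == 0:
            return TestResult(label, "t", math.nan, n1 + n2 - 2, math.nan,
                              "cohen_d", math.nan,
                              note="degenerate: zero variance")
        t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
        p = _t_p(t, df, alternative)
        dval = (x.mean() - y.mean()) / math.sqrt(sp2)
        return TestResult(label, "t", t, df, p, "cohen_d", dval)
    raise ValueError(f"unknown t-test mode {mode!r}")


def _t_from_diffs(d: np.ndarray, df: int, name: str,
                  alternative: str) -> TestResult:
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            # all differences exactly zero: t = 0/0
            return TestResult(name, "t", math.nan, df, math.nan,
                              "cohen_d", math.nan,
                              note="degenerate: zero variance")
        return TestResult(name, "t", math.nan, df, math.nan,
                          "cohen_d", math.nan,
                          note="degenerate: zero variance, nonzero mean")
    t = d.mean() / (sd / math.sqrt(d.size))
    return TestResult(name, "t", t, df, _t_p(t, df, alternative),
                      "cohen_d", d.mean() / sd)


def _t_p(t: float, df: float, alternative: str) -> float:
    if alternative == "two-sided":
        return 2.0 * sps.t.sf(abs(t), df)
    if alternative == "greater":
        return float(sps.t.sf(t, df))
    if alternative == "less":
        return float(sps.t.cdf(t, df))
    raise ValueError(f"unknown alternative {alternative!r}")


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA (balanced, fully within-subject)
# ---------------------------------------------------------------------------

def rm_anova_within(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: list[str] | tuple[str, ...],
) -> list[TestResult]:
    """One- or two-factor fully within-subject ANOVA on a balanced design.

    Every subject must contribute exactly one observation per factor
    cell; missing cells raise (no imputation).  Each effect is tested
    against its own subject-by-effect interaction error term; partial
    eta squared is SS_effect / (SS_effect + SS_error).
    """
    within = list(within)
    if len(within) not in (1, 2):
        raise ValueError("supports 1 or 2 within-subject factors")
    cols = [subject] + within + [dv]
    d = data[cols].dropna(subset=[dv])
    sizes = d.groupby([subject] + within, observed=True).size()
    if (sizes != 1).any():
        raise ValueError("design not balanced: need exactly one observation "
                         "per subject x cell (missing or duplicated cells)")
    subjects = d[subject].unique()
    n_cells = int(np.prod([d[f].nunique() for f in within]))
    if len(sizes) != len(subjects) * n_cells:
        raise ValueError("design not balanced: missing cells")

    y = d[dv].to_numpy(dtype=float)
    grand = y.mean()

    def _means(*factors: str) -> pd.Series:
        return d.groupby(list(factors), observed=True)[dv].mean()

    if len(within) == 1:
        a_f = within[0]
        A = _means(a_f)
        S = _means(subject)
        s, a = len(S), len(A)
        ss_a = s * float(((A - grand) ** 2).sum())
        fit = (A[d[a_f]].to_numpy() + S[d[subject]].to_numpy() - grand)
        ss_err = float(((y - fit) ** 2).sum())
        return [_anova_result(a_f, ss_a, a - 1, ss_err, (a - 1) * (s - 1))]

    a_f, b_f = within
    A, B, S = _means(a_f), _means(b_f), _means(subject)
    AB, AS, BS = _means(a_f, b_f), _means(a_f, subject), _means(b_f, subject)
    s, a, b = len(S), len(A), len(B)

    av = A[d[a_f]].to_numpy()
    bv = B[d[b_f]].to_numpy()
    sv = S[d[subject]].to_numpy()
    abv = AB[pd.MultiIndex.from_frame(d[[a_f, b_f]])].to_numpy()
    asv = AS[pd.MultiIndex.from_frame(d[[a_f, subject]])].to_numpy()
    bsv = BS[pd.MultiIndex.from_frame(d[[b_f, subject]])].to_numpy()

    ss_a = s * b * float(((A - grand) ** 2).sum())
    ss_b = s * a * float(((B - grand) ** 2).sum())
    # row-wise sum counts each (j,k) cell once per subject, i.e. s times,
    # which is exactly the balanced-design SS_AB = s * sum_jk (...)^2
    ss_ab = float(((abv - av - bv + grand) ** 2).sum())
    ss_as = float(((asv - av - sv + grand) ** 2).sum())
    ss_bs = float(((bsv - bv - sv + grand) ** 2).sum())
    resid = y - abv - asv - bsv + av + bv + sv - grand
    ss_abs = float((resid ** 2).sum())

    return [
        _anova_result(a_f, ss_a, a - 1, ss_as, (a - 1) * (s - 1)),
        _anova_result(b_f, ss_b, b - 1, ss_bs, (b - 1) * (s - 1)),
        _anova_result(f"{a_f} x {b_f}", ss_ab, (a - 1) * (b - 1),
                      ss_abs, (a - 1) * (b - 1) * (s - 1)),
    ]


def _anova_result(effect: str, ss: float, df1: int, ss_err: float,
                  df2: int) -> TestResult:
    if df2 <= 0:
        raise ValueError("no error degrees of freedom")
    ms, ms_err = ss / df1, ss_err / df2
    if ms_err == 0:
        f = math.inf if ss > 0 else 0.0
        p = 0.0 if ss > 0 else 1.0
        note = "degenerate: zero error variance" if ss == 0 else None
    else:
        f = ms / ms_err
        p = float(sps.f.sf(f, df1, df2))
        note = None
    eta = ss / (ss + ss_err) if (ss + ss_err) > 0 else math.nan
    return TestResult(f"rm-ANOVA: {effect}", "F", f, (df1, df2), p,
                      "partial_eta_sq", eta, note=note)


def posthoc_pairwise(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    factor: str,
    correction: str = "bonferroni",
) -> list[TestResult]:
    """Pairwise within-subject (paired t) comparisons over factor levels,
    Bonferroni-corrected across all level pairs."""
    if correction != "bonferroni":
        raise ValueError("only Bonferroni correction is supported")
    wide = data.pivot_table(index=subject, columns=factor, values=dv,
                            observed=True)
    if wide.isna().any().any():
        raise ValueError("post hoc requires complete data per subject")
    levels = list(wide.columns)
    pairs = list(itertools.combinations(levels, 2))
    m = len(pairs)
    out = []
    for la, lb in pairs:
        r = t_test("paired", wide[la].to_numpy(), wide[lb].to_numpy(),
                   name=f"post hoc {factor}: {la} vs {lb}")
        p_adj = bonferroni(r.p, m) if not math.isnan(r.p) else math.nan
        out.append(TestResult(r.name, r.statistic_name, r.statistic, r.df,
                              r.p, r.effect_name, r.effect,
                              p_adjusted=p_adj, note=r.note))
    return out


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

def rank_test(kind: str, *data, method: str = "auto",
              exact_cutoff: int = EXACT_CUTOFF,
              name: str | None = None) -> TestResult:
    """Dispatch to a rank test with midrank ties.

    ``kind``: ``kruskal_wallis`` / ``mann_whitney`` (independent groups
    as separate arrays), ``wilcoxon_signed_rank`` (two paired arrays or
    one array of differences), ``friedman`` (subjects x conditions
    matrix).  ``method``: ``exact`` enumerates the permutation null,
    ``asymptotic`` uses the large-sample approximation, ``auto`` picks
    exact when the total sample size is at most ``exact_cutoff``.
    """
    dispatch = {
        "kruskal_wallis": _kruskal,
        "mann_whitney": _mann_whitney,
        "wilcoxon_signed_rank": _wilcoxon,
        "friedman": _friedman,
    }
    if kind not in dispatch:
        raise ValueError(f"unknown rank test {kind!r}")
    return dispatch[kind](data, method, exact_cutoff, name)


def _resolve_method(method: str, n_total: int, cutoff: int) -> str:
    if method == "auto":
        return "exact" if n_total <= cutoff else "asymptotic"
    if method in ("exact", "asymptotic"):
        return method
    raise ValueError(f"unknown method {method!r}")


def _kw_statistic(groups: list[np.ndarray]) -> tuple[float, int]:
    """Tie-corrected Kruskal-Wallis H over midranks."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - ((counts ** 3 - counts).sum()) / (n ** 3 - n)
    if tie == 0:
        raise ValueError("all values identical: ranks carry no information")
    return h / tie, len(groups) - 1


def _kruskal(data, method, cutoff, name) -> TestResult:
    groups = [np.asarray(g, dtype=float) for g in data]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    n = sum(g.size for g in groups)
    h, dfree = _kw_statistic(groups)
    mode = _resolve_method(method, n, cutoff)
    label = name or "Kruskal-Wallis"
    if mode == "asymptotic":
        p = float(sps.chi2.sf(h, dfree))
        return TestResult(label, "H", h, dfree, p)
    # exact: enumerate all assignments of pooled values to group sizes
    pooled = np.concatenate(groups)
    sizes = [g.size for g in groups]
    total = 0
    at_least = 0
    for assign in _group_assignments(pooled.size, sizes):
        perm_groups = [pooled[list(ix)] for ix in assign]
        hp, _ = _kw_statistic(perm_groups)
        total += 1
        if hp >= h - 1e-12:
            at_least += 1
    return TestResult(label, "H", h, dfree, at_least / total,
                      note="exact")


def _group_assignments(n: int, sizes: list[int]):
    """All ways to partition indices 0..n-1 into ordered groups of the
    given sizes."""
    idx = tuple(range(n))

    def rec(remaining: tuple[int, ...], sizes_left: list[int]):
        if not sizes_left:
            yield ()
            return
        k = sizes_left[0]
        for combo in itertools.combinations(remaining, k):
            rest = tuple(i for i in remaining if i not in combo)
            for tail in rec(rest, sizes_left[1:]):
                yield (combo,) + tail

    yield from rec(idx, sizes)


def _mann_whitney(data, method, cutoff, name) -> TestResult:
    x, y = (np.asarray(a, dtype=float) for a in data)
    if x.size == 0 or y.size == 0:
        raise ValueError("need non-empty samples")
    n1, n2 = x.size, y.size
    ranks = sps.rankdata(np.concatenate([x, y]))
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mode = _resolve_method(method, n1 + n2, cutoff)
    label = name or "Mann-Whitney"
    if mode == "asymptotic":
        # no continuity correction, so the two-group Kruskal-Wallis
        # chi-squared p and this normal p coincide
        res = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        return TestResult(label, "U", float(u1), None, float(res.pvalue))
    center = n1 * n2 / 2.0
    dev = abs(u1 - center)
    total = at_least = 0
    for combo in itertools.combinations(range(ranks.size), n1):
        # ranks are fixed; the combo selects which observations are "x"
        up = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(up - center) >= dev - 1e-12:
            at_least += 1
    return TestResult(label, "U", float(u1), None, at_least / total,
                      note="exact")


def _signed_rank_parts(data) -> tuple[np.ndarray, np.ndarray]:
    if len(data) == 2:
        x, y = (np.asarray(a, dtype=float) for a in data)
        if x.shape != y.shape:
            raise ValueError("paired samples must have equal length")
        d = x - y
    elif len(data) == 1:
        d = np.asarray(data[0], dtype=float)
    else:
        raise ValueError("wilcoxon takes one difference array or two samples")
    d = d[d != 0]  # standard zero-discard convention
    return d, np.abs(d)


def _wilcoxon(data, method, cutoff, name) -> TestResult:
    d, absd = _signed_rank_parts(data)
    label = name or "Wilcoxon signed-rank"
    if d.size == 0:
        return TestResult(label, "W-", math.nan, None, math.nan,
                          note="degenerate: all differences zero")
    ranks = sps.rankdata(absd)
    w_minus = float(ranks[d < 0].sum())
    w_plus = float(ranks[d > 0].sum())
    mode = _resolve_method(method, d.size, cutoff)
    if mode == "asymptotic":
        res = sps.wilcoxon(d, correction=True, method="approx")
        return TestResult(label, "W-", w_minus, None, float(res.pvalue))
    # exact: enumerate all 2^m sign assignments of the midranks
    m = d.size
    w_min_obs = min(w_plus, w_minus)
    total = at_most = 0
    for signs in itertools.product((1.0, -1.0), repeat=m):
        sp = float(sum(r for r, s in zip(ranks, signs) if s > 0))
        sm = float(ranks.sum() - sp)
        total += 1
        if min(sp, sm) <= w_min_obs + 1e-12:
            at_most += 1
    return TestResult(label, "W-", w_minus, None, at_most / total,
                      note="exact")


def _friedman_statistic(matrix: np.ndarray) -> tuple[float, int]:
    """Tie-corrected Friedman chi-squared from a subjects x conditions
    matrix of within-subject midranks."""
    n, k = matrix.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, matrix)
    colsum = ranks.sum(axis=0)
    chi = 12.0 / (n * k * (k + 1)) * (colsum ** 2).sum() - 3 * n * (k + 1)
    ties = 0.0
    for row in matrix:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts ** 3 - counts).sum())
    c = 1.0 - ties / (n * k * (k ** 2 - 1))
    if c == 0:
        raise ValueError("every subject's values are all tied")
    return chi / c, k - 1


def _friedman(data, method, cutoff, name) -> TestResult:
    if len(data) == 1:
        matrix = np.asarray(data[0], dtype=float)
    else:
        matrix = np.column_stack([np.asarray(a, dtype=float) for a in data])
    if matrix.ndim != 2 or matrix.shape[1] < 2:
        raise ValueError("need a subjects x conditions matrix, >= 2 conditions")
    if np.isnan(matrix).any():
        raise ValueError("matrix contains NaN; drop incomplete subjects first")
    n, k = matrix.shape
    chi, dfree = _friedman_statistic(matrix)
    mode = _resolve_method(method, n, cutoff)
    label = name or "Friedman"
    if mode == "asymptotic":
        return TestResult(label, "chi2_F", chi, dfree,
                          float(sps.chi2.sf(chi, dfree)))
    # exact: within each subject the rank row is exchangeable; convolve
    # the distribution of column rank-sum vectors across subjects.
    dist: dict[tuple[float, ...], float] = {tuple([0.0] * k): 1.0}
    for row in matrix:
        r = sps.rankdata(row)
        w = 1.0 / math.factorial(k)
        # weight each distinct ordering by its multiplicity among k! orderings
        mult: dict[tuple[float, ...], int] = {}
        for p in itertools.permutations(r):
            mult[p] = mult.get(p, 0) + 1
        new: dict[tuple[float, ...], float] = {}
        for state, prob in dist.items():
            for p, cnt in mult.items():
                key = tuple(s + v for s, v in zip(state, p))
                new[key] = new.get(key, 0.0) + prob * cnt * w
        dist = new
    # tie correction factor is permutation-invariant
    ties = 0.0
    for row in matrix:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts ** 3 - counts).sum())
    c = 1.0 - ties / (n * k * (k ** 2 - 1))
    p = 0.0
    for colsum, prob in dist.items():
        chi_p = (12.0 / (n * k * (k + 1)) * sum(v ** 2 for v in colsum)
                 - 3 * n * (k + 1)) / c
        if chi_p >= chi - 1e-12:
            p += prob
    return TestResult(label, "chi2_F", chi, dfree, min(1.0, p), note="exact")


# ---------------------------------------------------------------------------
# Mixed linear model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixedFit:
    """Random-intercept linear model fit: DV ~ fixed slope + (1 | group)."""

    intercept: float
    slope: float
    slope_se: float
    ci_low: float
    ci_high: float
    t_value: float
    df: float
    p: float
    re_variance: float
    resid_variance: float
    r2_marginal: float
    n_obs: int
    n_groups: int
    method: str  # "mixed-reml" or "ols-fallback"
    ci_method: str = "cluster"
    note: str | None = None

    def as_row(self) -> dict:
        return {
            "intercept": self.intercept, "slope": self.slope,
            "slope_se": self.slope_se, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "t": self.t_value, "df": self.df,
            "p": self.p, "re_variance": self.re_variance,
            "resid_variance": self.resid_variance,
            "r2_marginal": self.r2_marginal, "n_obs": self.n_obs,
            "n_groups": self.n_groups, "method": self.method,
            "ci_method": self.ci_method, "note": self.note,
        }


def fit_mixed_model(
    data: pd.DataFrame,
    dv: str,
    fixed: str = "sucrose_percent",
    group: str = "animal",
    conf_level: float = 0.95,
    ci_method: str = "cluster",
) -> MixedFit:
    """Random-intercept Gaussian model of a delta vocalization score on
    sucrose concentration, fit by REML.

    The slope is per sucrose percentage point.  Marginal R-squared
    follows the variance-partition convention: var(fixed-effect
    prediction) over the sum of fixed, random-intercept and residual
    variances.  A singular random-intercept variance (or
    non-convergence) falls back to pooled ordinary least squares with a
    warning.

    ``ci_method`` picks the interval for the slope.  ``"cluster"``
    (default, requires every animal to share the same design points)
    uses the between-animal dispersion of per-animal OLS slopes with a
    t quantile on n_groups - 1 df: in a balanced design the fitted
    slope is the mean of the per-animal slopes, so this interval stays
    calibrated even when the residual variance differs across
    conditions (it does here: a zone visited briefly at a high call
    rate yields a much noisier score than one visited long).
    ``"wald"`` uses the model standard error with a t quantile on
    n_obs - n_groups - 1 df (the homoscedastic model-based interval).
    """
    import statsmodels.api as sm

    d = data[[group, fixed, dv]].dropna()
    n_per = d.groupby(group)[fixed].nunique()
    if (n_per < 2).any():
        raise ValueError("every group needs >= 2 distinct fixed-effect levels")
    ydat = d[dv].to_numpy(dtype=float)
    xdat = d[fixed].to_numpy(dtype=float)
    exog = sm.add_constant(xdat)
    n_obs = int(d.shape[0])
    n_groups = int(d[group].nunique())
    df_t = n_obs - n_groups - 1

    fit = None
    note = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(ydat, exog, groups=d[group].to_numpy())
            fit = model.fit(reml=True)
        re_var = float(np.asarray(fit.cov_re)[0, 0])
        slope_se = float(np.asarray(fit.bse)[1])
        if not fit.converged or not np.isfinite(slope_se):
            fit = None
            note = "fallback: mixed model did not converge"
        elif re_var < 1e-10:
            fit = None
            note = "fallback: singular random-intercept variance"
    except Exception as err:  # numerical failure on degenerate data
        fit = None
        note = f"fallback: {type(err).__name__}"

    if fit is not None:
        intercept, slope = float(fit.fe_params[0]), float(fit.fe_params[1])
        se = slope_se
        resid_var = float(fit.scale)
        method = "mixed-reml"
    else:
        warnings.warn("mixed model degenerate; using pooled OLS "
                      f"({note})", stacklevel=2)
        ols = sm.OLS(ydat, exog).fit()
        intercept, slope = float(ols.params[0]), float(ols.params[1])
        se = float(ols.bse[1])
        re_var = 0.0
        resid_var = float(ols.mse_resid)
        df_t = n_obs - 2
        method = "ols-fallback"

    if ci_method == "cluster" and n_groups >= 3:
        per_slope = []
        for _, grp in d.groupby(group):
            gx = grp[fixed].to_numpy(dtype=float)
            gy = grp[dv].to_numpy(dtype=float)
            per_slope.append(float(np.polyfit(gx, gy, 1)[0]))
        b = np.asarray(per_slope)
        se_ci = float(b.std(ddof=1) / math.sqrt(b.size))
        df_ci = float(b.size - 1)
    elif ci_method in ("cluster", "wald"):
        se_ci, df_ci = se, float(df_t)
        ci_method = "wald"
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    if se_ci > 0 and df_ci > 0:
        tq = float(sps.t.ppf(0.5 + conf_level / 2.0, df_ci))
        tval = slope / se_ci
        p = 2.0 * float(sps.t.sf(abs(tval), df_ci))
        lo, hi = slope - tq * se_ci, slope + tq * se_ci
    else:
        tval, p = math.nan, math.nan
        lo = hi = slope
    fixed_pred = intercept + slope * xdat
    var_f = float(np.var(fixed_pred))
    denom = var_f + re_var + resid_var
    r2 = var_f / denom if denom > 0 else math.nan
    return MixedFit(intercept, slope, se, lo, hi, tval, df_ci, p,
                    re_var, resid_var, r2, n_obs, n_groups, method,
                    ci_method, note)


# ---------------------------------------------------------------------------
# Inter-rater agreement
# ---------------------------------------------------------------------------

def cohen_kappa(labels_a, labels_b) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e) over two equal-length
    categorical sequences."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length 1-D label sequences")
    if a.size == 0:
        raise ValueError("empty sequences")
    p_o = float(np.mean(a == b))
    cats = np.union1d(a, b)
    pa = np.array([np.mean(a == c) for c in cats])
    pb = np.array([np.mean(b == c) for c in cats])
    p_e = float(pa @ pb)
    if p_e >= 1.0:
        raise ValueError("chance agreement is 1: kappa undefined")
    return (p_o - p_e) / (1.0 - p_e)
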