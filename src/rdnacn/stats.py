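"""Cohort association statistics.

Nonparametric tests mirroring a Prism/R-style analysis of copy-number /
phenotype cohorts: Spearman correlations, two-sided Mann-Whitney group
comparisons, Wilcoxon matched-pairs tests for the twin design, OLS-residual
age adjustment, medication-stratified correlations, the exponential-plateau
growth model, and per-week growth/CN correlations.

Each rank test has two branches with a fixed, documented crossover:

* an exact branch that enumerates the full permutation null (all ``n!``
  rank permutations for Spearman at ``n <= 8``; all ``C(N, n1)`` group
  assignments for Mann-Whitney at ``N <= 12``; all ``2^n`` sign patterns
  for Wilcoxon at ``<= 12`` informative pairs).  Two-sided exact p-values
  count outcomes whose statistic deviates from the null centre at least as
  far as observed;
* a large-sample branch delegated to scipy (tie-corrected normal
  approximations; the t-distribution approximation for Spearman).

Ties always use average ranks.  The branch taken is recorded on every
result for provenance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

SPEARMAN_EXACT_MAX_N = 8
MANNWHITNEY_EXACT_MAX_N = 12  # combined group size
WILCOXON_EXACT_MAX_N = 12  # informative (non-zero-difference) pairs
_EPS = 1e-12


@dataclass(frozen=True)
class SpearmanResult:
    r: float
    p: float
    n: int
    method: str  # exact_permutation | asymptotic


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # U statistic of the first group
    p: float
    n1: int
    n2: int
    method: str


@dataclass(frozen=True)
class WilcoxonResult:
    w_plus: float  # sum of positive-difference ranks
    p: float
    n_pairs: int  # informative pairs
    method: str


def _as_finite(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    return float(rxc @ ryc) / denom


# ---------------------------------------------------------------------------
# Spearman


def spearman_correlation(x, y) -> SpearmanResult:
    """Two-sided Spearman rank correlation with average-rank ties.

    Exact permutation p (full enumeration of y-rank permutations) for
    ``n <= 8``; scipy's large-sample approximation otherwise.
    """
    x = _as_finite(x, "x")
    y = _as_finite(y, "y")
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    r_obs = _rank_corr(rx, ry)
    if n <= SPEARMAN_EXACT_MAX_N:
        perms = np.array(list(itertools.permutations(ry)))
        rxc = rx - rx.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        rs = (pc @ rxc) / np.sqrt((pc * pc).sum(axis=1) * float(rxc @ rxc))
        p = float(np.mean(np.abs(rs) >= abs(r_obs) - _EPS))
        return SpearmanResult(r=r_obs, p=p, n=n, method="exact_permutation")
    res = sps.spearmanr(x, y)
    return SpearmanResult(r=float(res.statistic), p=float(res.pvalue), n=n,
                          method="asymptotic")


# ---------------------------------------------------------------------------
# Mann-Whitney


def mann_whitney(group_a, group_b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test with average-rank ties.

    Exact (all group assignments enumerated; p counts assignments with
    ``|U - n1*n2/2|`` at least the observed deviation) for combined
    ``n <= 12``; tie-corrected normal approximation with continuity
    correction otherwise.
    """
    a = _as_finite(group_a, "group_a")
    b = _as_finite(group_b, "group_b")
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    if n1 + n2 <= MANNWHITNEY_EXACT_MAX_N:
        mu = n1 * n2 / 2
        dev_obs = abs(u1 - mu)
        count = 0
        total = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
            if abs(u - mu) >= dev_obs - _EPS:
                count += 1
            total += 1
        return MannWhitneyResult(u=u1, p=count / total, n1=n1, n2=n2, method="exact_enumeration")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(u=float(res.statistic), p=float(res.pvalue),
                             n1=n1, n2=n2, method="asymptotic")


# ---------------------------------------------------------------------------
# Wilcoxon matched pairs


def wilcoxon_signed_rank_paired(x, y) -> WilcoxonResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped.  Exact sign-flip enumeration (p counts
    sign patterns with ``|W+ - n(n+1)/4|`` at least the observed deviation)
    for up to 12 informative pairs; normal approximation otherwise.
    """
    x = _as_finite(x, "x")
    y = _as_finite(y, "y")
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences zero: no information for the test")
    if n < 3:
        raise ValueError("need >= 3 non-zero differences")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= WILCOXON_EXACT_MAX_N:
        mu = n * (n + 1) / 4
        dev_obs = abs(w_plus - mu)
        bits = (np.arange(2 ** n)[:, None] >> np.arange(n)) & 1
        ws = bits @ ranks
        p = float(np.mean(np.abs(ws - mu) >= dev_obs - _EPS))
        return WilcoxonResult(w_plus=w_plus, p=p, n_pairs=n, method="exact_enumeration")
    res = sps.wilcoxon(d, alternative="two-sided", method="approx", correction=False)
    return WilcoxonResult(w_plus=w_plus, p=float(res.pvalue), n_pairs=n, method="asymptotic")


# ---------------------------------------------------------------------------
# age adjustment and stratified correlation


def age_adjust(values, age) -> np.ndarray:
    """Residualise a trait on age by OLS and re-centre at the cohort mean."""
    v = _as_finite(values, "values")
    a = _as_finite(age, "age")
    if v.shape != a.shape or len(v) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(a) == 0:
        raise ValueError("constant age: adjustment undefined")
    X = np.column_stack([np.ones_like(a), a])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta + v.mean()


@dataclass(frozen=True)
class StratifiedCorrelation:
    pooled: SpearmanResult
    by_stratum: Mapping[str, SpearmanResult]
    skipped: tuple[str, ...] = ()


def stratified_correlation(records: pd.DataFrame, stratum_col: str,
                           x_col: str, y_col: str) -> StratifiedCorrelation:
    """Pooled plus per-stratum Spearman correlation of two sample fields.

    Strata with fewer than 3 samples are reported as skipped rather than
    failing the whole analysis.
    """
    df = records[[stratum_col, x_col, y_col]].dropna()
    pooled = spearman_correlation(df[x_col], df[y_col])
    by: dict[str, SpearmanResult] = {}
    skipped: list[str] = []
    for label, grp in df.groupby(stratum_col, sort=True):
        if len(grp) < 3:
            skipped.append(str(label))
            continue
        by[str(label)] = spearman_correlation(grp[x_col], grp[y_col])
    return StratifiedCorrelation(pooled=pooled, by_stratum=by, skipped=tuple(skipped))


# ---------------------------------------------------------------------------
# twin-pair analysis


@dataclass(frozen=True)
class TwinReport:
    n_pairs: int
    paired_tests: Mapping[str, WilcoxonResult | None]
    notes: Mapping[str, str]
    delta_cn_vs_age: SpearmanResult | None
    delta_cn_vs_bmi_discordance: SpearmanResult | None


def twin_pair_analysis(records: pd.DataFrame,
                       traits: Sequence[str] = ("bmi", "cn", "methylation"),
                       cn_col: str = "cn", bmi_col: str = "bmi",
                       age_col: str = "age") -> TwinReport:
    """Within-pair tests for the BMI-discordant monozygotic twin design.

    For each trait, co-twins are ordered heavier-first by BMI and compared
    with the paired Wilcoxon test; a trait with no within-pair differences
    is reported with a note instead of a p-value (the discordance null is
    then not merely retained but undetectable).  Also correlates the
    absolute within-pair copy-number difference against pair age and BMI
    discordance.
    """
    if "twin_pair_id" not in records.columns:
        raise ValueError("records must carry a twin_pair_id column")
    heavier_rows, leaner_rows = [], []
    for pid, grp in records.groupby("twin_pair_id", sort=True):
        if len(grp) != 2:
            raise ValueError(f"twin pair {pid!r} has {len(grp)} members; need exactly 2")
        grp = grp.sort_values(bmi_col, ascending=False, kind="mergesort")
        heavier_rows.append(grp.iloc[0])
        leaner_rows.append(grp.iloc[1])
    heavier = pd.DataFrame(heavier_rows).reset_index(drop=True)
    leaner = pd.DataFrame(leaner_rows).reset_index(drop=True)
    n_pairs = len(heavier)
    tests: dict[str, WilcoxonResult | None] = {}
    notes: dict[str, str] = {}
    for trait in traits:
        try:
            tests[trait] = wilcoxon_signed_rank_paired(heavier[trait], leaner[trait])
        except ValueError as exc:
            tests[trait] = None
            notes[trait] = f"no difference detectable: {exc}"
    delta_cn = np.abs(heavier[cn_col].to_numpy() - leaner[cn_col].to_numpy())
    delta_bmi = np.abs(heavier[bmi_col].to_numpy() - leaner[bmi_col].to_numpy())
    vs_age = None
    if age_col in records.columns:
        pair_age = (heavier[age_col].to_numpy() + leaner[age_col].to_numpy()) / 2
        try:
            vs_age = spearman_correlation(delta_cn, pair_age)
        except ValueError:
            vs_age = None
    try:
        vs_bmi = spearman_correlation(delta_cn, delta_bmi)
    except ValueError:
        vs_bmi = None
    return TwinReport(n_pairs=n_pairs, paired_tests=tests, notes=notes,
                      delta_cn_vs_age=vs_age, delta_cn_vs_bmi_discordance=vs_bmi)


# ---------------------------------------------------------------------------
# exponential plateau growth model


@dataclass(frozen=True)
class GrowthFit:
    """Fit of ``W(t) = YM - (YM - Y0) * exp(-k t)``.

    ``ym`` is the plateau weight, ``y0`` the weight at t = 0, ``k`` the
    approach rate per week.
    """

    ym: float
    y0: float
    k: float
    r_squared: float
    sse: float
    n: int

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.ym - (self.ym - self.y0) * np.exp(-self.k * t)


_K_GRID = (0.05, 0.2, 0.5, 1.0)
_YM_GRID = (1.1, 1.5, 2.0)


def fit_exponential_plateau(weeks, weights) -> GrowthFit:
    """Deterministic multi-start least-squares fit of the plateau model.

    Positivity of ``k`` and of the growth span ``YM - Y0`` is enforced by
    reparameterising as ``(Y0, delta, k)`` with lower bounds.  Starts are a
    fixed grid (Y0 = first observation; YM at 1.1/1.5/2 times the maximum;
    k in {0.05, 0.2, 0.5, 1} per week); the lowest-SSE solution wins, ties
    resolved toward the smallest k.  Time is used as given, so callers with
    observations starting at week 8 should pass ``week - 8`` if Y0 is to
    mean the first-week weight.
    """
    t = _as_finite(weeks, "weeks")
    w = _as_finite(weights, "weights")
    if t.shape != w.shape or len(t) < 4:
        raise ValueError("need >= 4 paired observations")
    if len(np.unique(t)) < 4:
        raise ValueError("need >= 4 distinct time points")
    order = np.argsort(t, kind="mergesort")  # pooled cohort fits may repeat weeks
    t, w = t[order], w[order]
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if np.ptp(w) == 0:
        raise ValueError("constant series: no growth to fit")

    def model(tt, y0, delta, k):
        return y0 + delta * (1.0 - np.exp(-k * tt))

    y0_init = float(w[0])
    wmax = float(w.max())
    best = None  # (sse, k, params)
    for ym_mult in _YM_GRID:
        for k0 in _K_GRID:
            p0 = (y0_init, max(ym_mult * wmax - y0_init, 1e-6), k0)
            try:
                popt, _ = optimize.curve_fit(
                    model, t, w, p0=p0,
                    bounds=([0.0, 1e-12, 1e-12], [np.inf, np.inf, np.inf]),
                    maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14)
            except (RuntimeError, ValueError):
                continue
            resid = w - model(t, *popt)
            sse = float(resid @ resid)
            if best is None or sse < best[0] - 1e-12 * max(best[0], 1.0) or (
                    abs(sse - best[0]) <= 1e-12 * max(best[0], 1.0) and popt[2] < best[1]):
                best = (sse, popt[2], popt)
    if best is None:
        raise RuntimeError("plateau fit failed to converge from any start")
    sse, _, (y0, delta, k) = best
    ss_tot = float(((w - w.mean()) ** 2).sum())
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else float("nan")
    return GrowthFit(ym=float(y0 + delta), y0=float(y0), k=float(k),
                     r_squared=float(min(max(r2, 0.0), 1.0)), sse=sse, n=len(t))


# ---------------------------------------------------------------------------
# cross-sectional growth correlations


@dataclass(frozen=True)
class GrowthCorrelationReport:
    per_week: pd.DataFrame  # week, r, p, p_holm, n
    gain: SpearmanResult
    first_week: float
    last_week: float


def cross_sectional_growth_correlation(weights: pd.DataFrame,
                                       cn_by_sample: Mapping[str, float]
                                       ) -> GrowthCorrelationReport:
    """Per-week Spearman of weight vs copy number, plus the weight-gain
    (last minus first week) correlation.

    ``weights`` is long-format with columns ``sample_id, week, weight``.
    Every sample shared with ``cn_by_sample`` must be observed at the first
    and last week; raw p-values are primary, with a Holm-adjusted column
    alongside.
    """
    df = weights[weights["sample_id"].isin(cn_by_sample)].copy()
    if df.empty:
        raise ValueError("no overlapping sample ids")
    first_w = float(df["week"].min())
    last_w = float(df["week"].max())
    for wk, label in ((first_w, "first"), (last_w, "last")):
        present = set(df.loc[df["week"] == wk, "sample_id"])
        missing = sorted(set(df["sample_id"]) - present)
        if missing:
            raise ValueError(f"samples missing the {label}-week observation: {missing}")
    rows = []
    for wk, grp in df.groupby("week", sort=True):
        cn_vals = grp["sample_id"].map(cn_by_sample)
        res = spearman_correlation(grp["weight"], cn_vals)
        rows.append({"week": float(wk), "r": res.r, "p": res.p, "n": res.n})
    per_week = pd.DataFrame(rows)
    per_week["p_holm"] = multipletests(per_week["p"], method="holm")[1]
    wide = df.pivot_table(index="sample_id", columns="week", values="weight")
    gain = wide[last_w] - wide[first_w]
    cn_vec = gain.index.map(cn_by_sample)
    gain_res = spearman_correlation(gain.to_numpy(), np.asarray(cn_vec, dtype=float))
    return GrowthCorrelationReport(per_week=per_week, gain=gain_res,
                                   first_week=first_w, last_week=last_w)
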