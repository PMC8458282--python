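"""Cohort statistics: RD/AR normalization, cell-death-rate regression,
group comparisons, the a-priori degeneration criteria, and three case
studies illustrating regional pitfalls.

Conventions follow the study design this package models: one-way ANOVA with
Tukey HSD for multi-group comparisons, Student t-tests for two groups
(Welch available), Shapiro–Wilk normality reported but not gating, alpha =
0.050.  The photoreceptor death rate is the OLS slope of a metric on day;
its p-value is the regression F-test, which for a single regressor equals
the slope's two-sided t-test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateVarianceError,
    IncompleteDesignError,
    InsufficientDesignError,
)

ALPHA = 0.050
ATTACHED_REGIONS = ("attached_central", "attached_paracentral")
DETACHED_REGIONS = ("detached_apex", "detached_base")
METRICS = ("onl_count", "onl_inl_ratio")
CRITERIA_KEYS = ("1a", "1b", "2a", "2b", "3a", "3b", "4a", "4b")


# ---------------------------------------------------------------------------
# records and normalization
# ---------------------------------------------------------------------------


@dataclass
class MorphometryRecord:
    """Per-(animal, day, region) measurements of one tile."""

    animal_id: str
    day: int
    region: str
    onl_count: float
    onl_thickness_um: float | None = None
    inl_thickness_um: float | None = None
    onl_inl_ratio: float | None = None
    rd_height_um: float | None = None

    def __post_init__(self) -> None:
        if self.onl_count < 0:
            raise ValueError("counts must be non-negative")
        if (
            self.onl_inl_ratio is not None
            and self.onl_thickness_um is not None
            and self.inl_thickness_um not in (None, 0)
        ):
            implied = self.onl_thickness_um / self.inl_thickness_um
            if abs(implied - self.onl_inl_ratio) > 1e-6 * max(abs(implied), 1):
                raise ValueError("ratio inconsistent with thicknesses")


def records_to_frame(records: list[MorphometryRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def normalize_to_attached(
    cohort: pd.DataFrame, reference_region: str = "attached_central"
) -> pd.DataFrame:
    """Divide each tile's metrics by the same tile's attached-central values.

    Adds ``rd_ar_count`` and ``rd_ar_ratio`` columns; tiles without a
    reference record are dropped with a warning.  The reference region
    normalizes to exactly 1.0.
    """
    ref = cohort[cohort.region == reference_region].set_index("animal_id")
    out = cohort.copy()
    missing = sorted(set(out.animal_id) - set(ref.index))
    if missing:
        warnings.warn(
            f"skipping tiles without an {reference_region} record: {missing}",
            stacklevel=2,
        )
        out = out[~out.animal_id.isin(missing)].copy()
    out["rd_ar_count"] = (
        out.onl_count.values
        / ref.loc[out.animal_id, "onl_count"].values
    )
    out["rd_ar_ratio"] = (
        out.onl_inl_ratio.values
        / ref.loc[out.animal_id, "onl_inl_ratio"].values
    )
    return out


def normalized_group_mean(
    group_mean: float, reference_mean: float
) -> float:
    """Worked-example normalization: ratio of two printed group means."""
    if reference_mean == 0:
        raise ZeroDivisionError("reference mean is zero")
    return group_mean / reference_mean


# ---------------------------------------------------------------------------
# rate regression
# ---------------------------------------------------------------------------


@dataclass
class RateEstimate:
    region: str
    metric: str
    slope_per_day: float
    intercept: float
    p_value: float
    n_obs: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope_per_day):
            raise ValueError("slope must be finite")


def fit_rate(cohort: pd.DataFrame, region: str, metric: str) -> RateEstimate:
    """OLS of a metric on day over per-sample observations of one region.

    The slope is the change per day; the p-value is the regression F-test
    (identical to the slope's two-sided t-test for a single regressor).
    Needs observations on at least three distinct days.
    """
    sub = cohort[cohort.region == region]
    if sub.day.nunique() < 3:
        raise InsufficientDesignError(
            f"{region}: need >= 3 distinct days, have {sorted(sub.day.unique())}"
        )
    import statsmodels.api as sm

    x = sm.add_constant(sub.day.to_numpy(dtype=float))
    y = sub[metric].to_numpy(dtype=float)
    fit = sm.OLS(y, x).fit()
    return RateEstimate(
        region=region,
        metric=metric,
        slope_per_day=float(fit.params[1]),
        intercept=float(fit.params[0]),
        p_value=float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else 1.0,
        n_obs=int(len(y)),
    )


def ols_slope_closed_form(x: np.ndarray, y: np.ndarray) -> float:
    """Independent closed-form slope: sum((x-x̄)(y-ȳ)) / sum((x-x̄)^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = x - x.mean()
    return float(np.sum(dx * (y - y.mean())) / np.sum(dx * dx))


def rate_from_day_means(day_means: dict[int, float]) -> float:
    """Rate per day from a printed table of day means (equal weighting)."""
    days = np.array(sorted(day_means), dtype=float)
    means = np.array([day_means[int(d)] for d in days], dtype=float)
    return ols_slope_closed_form(days, means)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    label: str
    test: str          # ANOVA, Tukey, Student t, Welch t, Shapiro–Wilk
    statistic: float
    p_value: float
    group_means: dict[str, float] = field(default_factory=dict)
    group_sds: dict[str, float] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _tukey_q(groups: dict[str, np.ndarray]):
    """Studentized-range statistics for every pair (Tukey–Kramer).

    Returns ({(a, b): q}, {name: mean}, k, df).  Raises when every group
    has zero within-group variance (the studentized range is undefined).
    """
    names = list(groups)
    arrs = [np.asarray(groups[k], dtype=float) for k in names]
    ns = np.array([len(a) for a in arrs])
    if (ns < 2).any():
        raise ValueError("each group needs n >= 2")
    means = np.array([a.mean() for a in arrs])
    sse = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df = int(ns.sum() - len(arrs))
    mse = sse / df
    if mse == 0:
        raise DegenerateVarianceError("zero within-group variance in all groups")
    qs = {}
    k = len(arrs)
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(mse / 2 * (1 / ns[i] + 1 / ns[j]))
        qs[(names[i], names[j])] = float(abs(means[i] - means[j]) / se)
    return qs, dict(zip(names, means)), k, df


@lru_cache(maxsize=128)
def _tukey_critical(k: int, df: int, alpha: float) -> float:
    return float(sps.studentized_range.isf(alpha, k, df))


def _tukey_p(q: float, k: int, df: int) -> float:
    p = float(sps.studentized_range.sf(q, k, df))
    return min(max(p, 0.0), 1.0)


def tukey_hsd(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], tuple[float, float]]:
    """Tukey–Kramer pairwise comparisons: {(a, b): (q statistic, p value)}."""
    qs, _, k, df = _tukey_q(groups)
    return {pair: (q, _tukey_p(q, k, df)) for pair, q in qs.items()}


def compare_groups(
    groups: dict[str, np.ndarray],
    design: str = "auto",
    welch: bool = False,
) -> list[GroupComparison]:
    """Shapiro–Wilk per group plus ANOVA/Tukey or a t-test.

    ``design``: "auto" picks two-group vs multi-group from the input;
    normality results are reported, never used to switch the test family.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrs = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, a in arrs.items():
        if len(a) < 2:
            raise ValueError(f"group {k!r} has n < 2")
    if all(np.ptp(a) == 0 for a in arrs.values()):
        raise DegenerateVarianceError("zero within-group variance in all groups")

    means = {k: float(a.mean()) for k, a in arrs.items()}
    sds = {k: float(a.std(ddof=1)) for k, a in arrs.items()}
    out: list[GroupComparison] = []
    for k, a in arrs.items():
        if len(a) >= 3 and np.ptp(a) > 0:
            w, p = sps.shapiro(a)
            out.append(GroupComparison(f"normality:{k}", "Shapiro–Wilk",
                                       float(w), float(p)))
    multi = len(arrs) > 2 if design == "auto" else design == "multi-group"
    if multi:
        f, p = sps.f_oneway(*arrs.values())
        out.append(GroupComparison("omnibus", "ANOVA", float(f), float(p),
                                   means, sds))
        for (a, b), (q, p) in tukey_hsd(arrs).items():
            out.append(GroupComparison(f"{a} vs {b}", "Tukey", q, p,
                                       {a: means[a], b: means[b]},
                                       {a: sds[a], b: sds[b]}))
    else:
        (ka, va), (kb, vb) = arrs.items()
        t, p = sps.ttest_ind(va, vb, equal_var=not welch)
        out.append(GroupComparison(
            f"{ka} vs {kb}", "Welch t" if welch else "Student t",
            float(t), float(p),
            {ka: means[ka], kb: means[kb]}, {ka: sds[ka], kb: sds[kb]},
        ))
    return out


# ---------------------------------------------------------------------------
# degeneration criteria
# ---------------------------------------------------------------------------


@dataclass
class CriterionResult:
    passed: bool
    p_value: float | None
    detail: str

    def __post_init__(self) -> None:
        self.passed = bool(self.passed)
        if self.p_value is not None:
            self.p_value = float(self.p_value)


@dataclass
class CriteriaReport:
    """Pass/fail of criteria 1a–4b per detached region, plus verdicts.

    Criteria 1/2: at day 0 the detached region shows no significant
    reduction of the ONL count (1) or ONL/INL ratio (2) relative to the
    attached regions.  Criteria 3/4: the region shows progressive reduction
    over time — a significant day-0 vs day-14 decrease with no significant
    increase between any earlier and later timepoint.  (a) absolute values,
    (b) normalized to the attached central retina of the same tile.  A
    region is fit to determine progressive degeneration iff all eight
    sub-criteria pass.
    """

    regions: dict[str, dict[str, CriterionResult]]
    alpha: float = ALPHA

    @property
    def verdicts(self) -> dict[str, bool]:
        return {
            r: all(c.passed for c in crit.values())
            for r, crit in self.regions.items()
        }

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "regions": {
                r: {k: asdict(v) for k, v in crit.items()}
                for r, crit in self.regions.items()
            },
            "verdicts": self.verdicts,
        }

    def to_text(self) -> str:
        lines = []
        for r, crit in self.regions.items():
            lines.append(f"{r}:")
            for k in CRITERIA_KEYS:
                c = crit[k]
                p = "n/a" if c.p_value is None else f"p={c.p_value:.4g}"
                lines.append(
                    f"  {k}: {'PASS' if c.passed else 'FAIL'} ({p}; {c.detail})"
                )
            verdict = "fit" if self.verdicts[r] else "unfit"
            lines.append(f"  -> {verdict} to determine progressive degeneration")
        return "\n".join(lines)


def _require_complete(cohort: pd.DataFrame, days, regions) -> None:
    gaps = [
        (r, d)
        for r in regions
        for d in days
        if not len(cohort[(cohort.region == r) & (cohort.day == d)])
    ]
    if gaps:
        raise IncompleteDesignError(f"missing (region, day) cells: {gaps}")


def _pair(qs, a, b):
    return qs[(a, b)] if (a, b) in qs else qs[(b, a)]


def _baseline_criterion(cohort, region, col, alpha) -> CriterionResult:
    """No significant day-0 reduction vs either attached region (Tukey)."""
    day0 = cohort[cohort.day == cohort.day.min()]
    groups = {
        r: day0[day0.region == r][col].to_numpy()
        for r in (*ATTACHED_REGIONS, *DETACHED_REGIONS)
    }
    qs, means, k, df = _tukey_q(groups)
    q_crit = _tukey_critical(k, df, alpha)
    passed = True
    q_worst = -np.inf
    detail = []
    for att in ATTACHED_REGIONS:
        q = _pair(qs, att, region)
        if q > q_crit and means[region] < means[att]:
            passed = False
        if q > q_worst:
            q_worst = q
        detail.append(f"vs {att}: q={q:.3g}")
    worst_p = _tukey_p(q_worst, k, df)  # smallest p among attached contrasts
    return CriterionResult(passed, worst_p, "; ".join(detail))


def _progressive_criterion(cohort, region, col, alpha) -> CriterionResult:
    """Significant day-0 vs last-day decrease, no significant increase."""
    sub = cohort[cohort.region == region]
    days = sorted(sub.day.unique())
    groups = {str(int(d)): sub[sub.day == d][col].to_numpy() for d in days}
    qs, means, k, df = _tukey_q(groups)
    q_crit = _tukey_critical(k, df, alpha)
    d0, dlast = str(days[0]), str(days[-1])
    q_end = _pair(qs, d0, dlast)
    p_end = _tukey_p(q_end, k, df)
    decreased = means[dlast] < means[d0]
    ok = p_end < alpha and decreased
    detail = [f"day {d0} vs {dlast}: p={p_end:.4g}"]
    for i, j in itertools.combinations(days, 2):
        q = _pair(qs, str(i), str(j))
        if q > q_crit and means[str(j)] > means[str(i)]:
            ok = False
            detail.append(
                f"significant increase day {i}->{j} (p={_tukey_p(q, k, df):.4g})"
            )
    return CriterionResult(ok, p_end, "; ".join(detail))


def evaluate_criteria(
    cohort: pd.DataFrame,
    normalized: pd.DataFrame | None = None,
    alpha: float = ALPHA,
) -> CriteriaReport:
    """Score the a-priori degeneration criteria on a cohort table.

    ``cohort`` needs columns animal_id, day, region, onl_count,
    onl_inl_ratio covering all four regions at every day; ``normalized`` is
    computed with :func:`normalize_to_attached` when not supplied.
    """
    days = sorted(cohort.day.unique())
    _require_complete(cohort, days, (*ATTACHED_REGIONS, *DETACHED_REGIONS))
    if normalized is None:
        normalized = normalize_to_attached(cohort)

    report: dict[str, dict[str, CriterionResult]] = {}
    for region in DETACHED_REGIONS:
        crit = {
            "1a": _baseline_criterion(cohort, region, "onl_count", alpha),
            "1b": _baseline_criterion(normalized, region, "rd_ar_count", alpha),
            "2a": _baseline_criterion(cohort, region, "onl_inl_ratio", alpha),
            "2b": _baseline_criterion(normalized, region, "rd_ar_ratio", alpha),
            "3a": _progressive_criterion(cohort, region, "onl_count", alpha),
            "3b": _progressive_criterion(normalized, region, "rd_ar_count", alpha),
            "4a": _progressive_criterion(cohort, region, "onl_inl_ratio", alpha),
            "4b": _progressive_criterion(normalized, region, "rd_ar_ratio", alpha),
        }
        report[region] = crit
    return CriteriaReport(report, alpha)


# ---------------------------------------------------------------------------
# case studies
# ---------------------------------------------------------------------------


def run_case_study(case: int, cohort: pd.DataFrame, seed: int = 0) -> dict:
    """One of three analysis strategies an investigator might choose.

    Case 1: per detached region, normalized metrics compared across days
    (ANOVA + Tukey vs day 0).  Case 2: per detached region, Student t-tests
    of day 0 vs day 7 and day 0 vs day 14 on the absolute metrics.  Case 3:
    apex and base tiles pooled at day 7 and day 14 and randomly shuffled
    into groups I/II (seeded), then compared by t-test — the design that
    masks regional differences.  Non-significant results where the model
    truly degenerates are annotated as type II errors.
    """
    if case == 1:
        return _case1(cohort)
    if case == 2:
        return _case2(cohort)
    if case == 3:
        return _case3(cohort, seed)
    raise ValueError("case must be 1, 2 or 3")


def _case1(cohort: pd.DataFrame) -> dict:
    norm = normalize_to_attached(cohort)
    out = {"case": 1, "regions": {}}
    for region in DETACHED_REGIONS:
        sub = norm[norm.region == region]
        days = sorted(sub.day.unique())
        entry = {}
        for col, label in (("rd_ar_count", "normalized_count"),
                           ("rd_ar_ratio", "normalized_ratio")):
            groups = {str(int(d)): sub[sub.day == d][col].to_numpy() for d in days}
            pairs = tukey_hsd(groups)
            vs_day0 = {
                f"day0_vs_day{j}": pairs[k if (k := ("0", str(j))) in pairs else k[::-1]][1]
                for j in days[1:]
            }
            detected = any(p < ALPHA for p in vs_day0.values())
            entry[label] = {
                "p_values": vs_day0,
                "significant": detected,
                "error_type": None if detected else "type II",
            }
        out["regions"][region] = entry
    return out


def _case2(cohort: pd.DataFrame) -> dict:
    out = {"case": 2, "regions": {}}
    for region in DETACHED_REGIONS:
        sub = cohort[cohort.region == region]
        entry = {}
        for col in METRICS:
            tests = {}
            for day in (7, 14):
                a = sub[sub.day == 0][col].to_numpy()
                b = sub[sub.day == day][col].to_numpy()
                t, p = sps.ttest_ind(a, b, equal_var=True)
                tests[f"day0_vs_day{day}"] = float(p)
            detected = any(p < ALPHA for p in tests.values())
            entry[col] = {
                "p_values": tests,
                "significant": detected,
                "error_type": None if detected else "type II",
            }
        out["regions"][region] = entry
    return out


def _case3(cohort: pd.DataFrame, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    out = {"case": 3, "seed": int(seed), "days": {}}
    for day in (7, 14):
        pooled = cohort[
            cohort.region.isin(DETACHED_REGIONS) & (cohort.day == day)
        ].reset_index(drop=True)
        perm = rng.permutation(len(pooled))
        half = len(pooled) // 2  # sizes differ by at most 1 for odd n
        gi = pooled.iloc[perm[:half]]
        gii = pooled.iloc[perm[half:]]
        entry = {"allocation": {
            "I": sorted(gi.animal_id + "/" + gi.region),
            "II": sorted(gii.animal_id + "/" + gii.region),
        }}
        for col in METRICS:
            t, p = sps.ttest_ind(
                gi[col].to_numpy(), gii[col].to_numpy(), equal_var=True
            )
            detected = bool(p < ALPHA)
            entry[col] = {
                "group_I_mean": float(gi[col].mean()),
                "group_I_sd": float(gi[col].std(ddof=1)),
                "group_II_mean": float(gii[col].mean()),
                "group_II_sd": float(gii[col].std(ddof=1)),
                "p_value": float(p),
                "significant": detected,
                "error_type": None if detected else "type II",
            }
        out["days"][int(day)] = entry
    return out
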