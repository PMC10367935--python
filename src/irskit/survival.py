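"""Survival and categorical statistics behind the validation analyses.

Thin, typed wrappers around the standard fitters (lifelines for Cox /
Kaplan–Meier / RMST / proportional-hazards checks, statsmodels for the
stratified Mantel–Haenszel machinery and logistic propensity models, scipy
for Fisher exact), plus the Schoenfeld events-based power formula and the
overlap-weighting propensity analysis.

Cox models use Efron tie handling (lifelines' default), appropriate for the
heavily tied month-scale durations produced by real-world records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import proportional_hazard_test
from lifelines.utils import restricted_mean_survival_time
from scipy import stats

__all__ = [
    "CoxFit",
    "KMSummary",
    "PowerSpec",
    "km_estimate",
    "fit_cox",
    "lrt_nested",
    "rmst_compare",
    "schoenfeld_ph_check",
    "power_two_group_cox",
    "cmh_ratio_test",
    "fisher_frequency_compare",
    "overlap_weight_analysis",
]


# ---------------------------------------------------------------------------
# Kaplan–Meier


@dataclass(frozen=True)
class KMSummary:
    median: float  # np.inf when not reached
    median_ci: tuple[float, float]
    curve: pd.DataFrame  # columns: time, survival
    n: int
    n_events: int


def km_estimate(durations, events, label: str = "KM") -> KMSummary:
    """Product-limit estimate with log-log median CI.

    All-censored input yields a not-reached median (inf), not an error.
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    if durations.size == 0:
        raise ValueError("empty survival data")
    if (durations <= 0).any():
        raise ValueError("durations must be positive")
    kmf = KaplanMeierFitter(label=label)
    kmf.fit(durations, events)
    from lifelines.utils import median_survival_times

    med = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    curve = kmf.survival_function_.reset_index()
    curve.columns = ["time", "survival"]
    return KMSummary(med, (lo, hi), curve, int(durations.size), int(events.sum()))


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxFit:
    term_estimates: pd.Series  # log-hazard coefficients
    term: str
    ahr: float
    ci95: tuple[float, float]
    p_value: float
    log_likelihood: float
    n: int
    n_events: int
    n_params: int
    penalized: bool = False
    fitter: CoxPHFitter = field(repr=False, default=None)
    data: pd.DataFrame = field(repr=False, default=None)
    duration_col: str = "duration"
    event_col: str = "event"

    def summary_row(self, term: str) -> tuple[float, tuple[float, float], float]:
        s = self.fitter.summary.loc[term]
        return (
            float(s["exp(coef)"]),
            (float(s["exp(coef) lower 95%"]), float(s["exp(coef) upper 95%"])),
            float(s["p"]),
        )


def _prepare_design(
    df: pd.DataFrame, covariates: list[str], references: dict[str, str] | None = None
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Expand categorical covariates to treatment-coded dummies.

    The reference level is the most frequent category unless overridden.
    Constant covariates are dropped (a single-level factor carries no
    information).
    """
    references = references or {}
    cols = {}
    expansion: dict[str, list[str]] = {}
    for c in covariates:
        s = df[c]
        if s.dtype == bool:
            cols[c] = s.astype(float)
            expansion[c] = [c]
        elif pd.api.types.is_numeric_dtype(s):
            cols[c] = s.astype(float)
            expansion[c] = [c]
        else:
            counts = s.value_counts()
            if len(counts) <= 1:
                expansion[c] = []
                continue
            ref = references.get(c, str(counts.index[0]))
            names = []
            for lvl in counts.index:
                if str(lvl) == ref:
                    continue
                name = f"{c}[{lvl}]"
                cols[name] = (s == lvl).astype(float)
                names.append(name)
            expansion[c] = names
    design = pd.DataFrame(cols, index=df.index)
    # drop constants
    for name in list(design.columns):
        if design[name].nunique() <= 1:
            design = design.drop(columns=name)
            for k, v in expansion.items():
                expansion[k] = [x for x in v if x != name]
    return design, expansion


def fit_cox(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str],
    term: str,
    references: dict[str, str] | None = None,
    strata: list[str] | None = None,
    weights_col: str | None = None,
    cluster_col: str | None = None,
    robust: bool = False,
) -> CoxFit:
    """Fit a Cox proportional-hazards model (Efron ties).

    ``term`` names the covariate of interest; for a categorical covariate
    expanded to a single dummy, the dummy's hazard ratio is reported.
    Complete separation is retried with a small ridge penalty and flagged
    via ``penalized=True``.
    """
    events = df[event_col].astype(bool)
    if events.sum() < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    design, expansion = _prepare_design(df, covariates, references)
    data = design.copy()
    data[duration_col] = df[duration_col].astype(float)
    data[event_col] = events.astype(int)
    extra = {}
    if strata:
        for s in strata:
            data[s] = df[s].values
        extra["strata"] = strata
    if weights_col:
        data[weights_col] = df[weights_col].astype(float).values
        extra["weights_col"] = weights_col
    if cluster_col:
        data[cluster_col] = df[cluster_col].values
        extra["cluster_col"] = cluster_col

    penalized = False
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(data, duration_col=duration_col, event_col=event_col,
                    robust=robust, **extra)
        except ConvergenceError:
            penalized = True
            cph = CoxPHFitter(penalizer=0.1)
            cph.fit(data, duration_col=duration_col, event_col=event_col,
                    robust=robust, **extra)

    term_cols = expansion.get(term, [term] if term in design.columns else [])
    if len(term_cols) != 1:
        term_name = term_cols[0] if term_cols else term
        if term_name not in cph.summary.index:
            raise ValueError(
                f"term {term!r} expands to {term_cols}; pass the specific dummy name"
            )
    else:
        term_name = term_cols[0]
    s = cph.summary.loc[term_name]
    return CoxFit(
        term_estimates=cph.params_.copy(),
        term=term_name,
        ahr=float(s["exp(coef)"]),
        ci95=(float(s["exp(coef) lower 95%"]), float(s["exp(coef) upper 95%"])),
        p_value=float(s["p"]),
        log_likelihood=float(cph.log_likelihood_),
        n=int(len(data)),
        n_events=int(events.sum()),
        n_params=int(len(cph.params_)),
        penalized=penalized,
        fitter=cph,
        data=data,
        duration_col=duration_col,
        event_col=event_col,
    )


def lrt_nested(full: CoxFit, reduced: CoxFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested Cox models: (statistic, df, p)."""
    same_records = (
        full.n == reduced.n
        and full.n_events == reduced.n_events
        and full.data is not None
        and reduced.data is not None
        and np.array_equal(
            full.data[full.duration_col].to_numpy(),
            reduced.data[reduced.duration_col].to_numpy(),
        )
        and np.array_equal(
            full.data[full.event_col].to_numpy(),
            reduced.data[reduced.event_col].to_numpy(),
        )
    )
    if not same_records:
        raise ValueError("nested LRT requires identical record sets")
    df_diff = full.n_params - reduced.n_params
    if df_diff < 0:
        raise ValueError("'full' model has fewer parameters than 'reduced'")
    stat = max(0.0, 2.0 * (full.log_likelihood - reduced.log_likelihood))
    if df_diff == 0:
        return stat, 0, 1.0
    return stat, df_diff, float(stats.chi2.sf(stat, df_diff))


# ---------------------------------------------------------------------------
# RMST


def rmst_compare(
    groups: dict[str, tuple[np.ndarray, np.ndarray]], tau: float | None = None
) -> pd.DataFrame:
    """Restricted mean survival time per group up to tau, with differences.

    tau defaults to the minimum of the per-group largest observed times so
    the restriction window is supported everywhere. A tau beyond a group's
    follow-up is an error unless that group's curve has already reached
    zero (the area is then exact). Returns one row per group (rmst, se)
    and rows ``<g> - <ref>`` with difference, se and normal CI, where the
    reference is the first group.
    """
    maxima = {g: float(np.max(d)) for g, (d, _) in groups.items()}
    if tau is None:
        tau = min(maxima.values())
    for g, m in maxima.items():
        dur, ev = groups[g]
        exhausted = KaplanMeierFitter().fit(
            np.asarray(dur, float), np.asarray(ev, bool)
        ).survival_function_.iloc[-1, 0] == 0.0
        if tau > m and not exhausted:
            raise ValueError(f"tau={tau} exceeds follow-up in group {g!r} (max {m})")
    rows = {}
    for g, (dur, ev) in groups.items():
        kmf = KaplanMeierFitter().fit(np.asarray(dur, float), np.asarray(ev, bool))
        r, var = restricted_mean_survival_time(kmf, t=tau, return_variance=True)
        rows[g] = (float(r), float(np.sqrt(var)))
    out = pd.DataFrame(rows, index=["rmst", "se"]).T
    names = list(groups)
    ref = names[0]
    for g in names[1:]:
        diff = rows[g][0] - rows[ref][0]
        se = float(np.hypot(rows[g][1], rows[ref][1]))
        out.loc[f"{g} - {ref}"] = [diff, se]
    out["ci_low"] = out["rmst"] - 1.96 * out["se"]
    out["ci_high"] = out["rmst"] + 1.96 * out["se"]
    out.attrs["tau"] = tau
    return out


# ---------------------------------------------------------------------------
# proportional hazards diagnostics


def schoenfeld_ph_check(fit: CoxFit, time_transform: str = "rank") -> pd.DataFrame:
    """Scaled-Schoenfeld-residual proportional-hazards test per term.

    Returns a frame indexed by term with ``chi2``, ``df`` and ``p``, plus a
    ``GLOBAL`` row (sum of per-term chi2 with summed df — an omnibus
    approximation; per-term rows are the exact score tests).
    """
    if fit.fitter is None or fit.data is None or fit.n_events < 2:
        raise ValueError("need a fitted model with >= 2 events")
    res = proportional_hazard_test(fit.fitter, fit.data, time_transform=time_transform)
    table = res.summary[["test_statistic", "p"]].copy()
    table.columns = ["chi2", "p"]
    table["df"] = 1
    total = float(table["chi2"].sum())
    k = int(len(table))
    table.loc["GLOBAL"] = [total, float(stats.chi2.sf(total, k)), k]
    return table


# ---------------------------------------------------------------------------
# power


@dataclass(frozen=True)
class PowerSpec:
    n_total: int
    hr_alt: float
    event_rate: float
    allocation_ratio: float = 1.0  # exposed : unexposed
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.event_rate <= 1:
            raise ValueError("event_rate must be in (0, 1]")
        if self.hr_alt <= 0:
            raise ValueError("hr_alt must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def power_two_group_cox(spec: PowerSpec) -> float:
    """Schoenfeld events-based power for a two-group log-rank/Cox comparison.

    D = n * event_rate expected events; with allocation fraction p,
    power = Phi(|log HR| * sqrt(D * p * (1-p)) - z_{1-alpha/2}).
    """
    d = spec.n_total * spec.event_rate
    p = spec.allocation_ratio / (1.0 + spec.allocation_ratio)
    z_alpha = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    return float(stats.norm.cdf(abs(np.log(spec.hr_alt)) * np.sqrt(d * p * (1 - p)) - z_alpha))


# ---------------------------------------------------------------------------
# categorical comparisons


def cmh_ratio_test(
    strata_tables: list[np.ndarray] | np.ndarray, correction: bool = False
) -> tuple[float, tuple[float, float], float]:
    """Mantel–Haenszel common odds ratio across 2x2 strata.

    Each stratum is [[exposed_success, exposed_failure],
    [unexposed_success, unexposed_failure]]. Returns (OR, RBG 95% CI, CMH
    test p). With one stratum the OR equals the plain cross-product ratio.
    Strata with an all-zero margin are dropped with a warning.
    """
    from statsmodels.stats.contingency_tables import StratifiedTable

    arrs = [np.asarray(t, dtype=float) for t in np.asarray(strata_tables).reshape(-1, 2, 2)]
    kept = []
    for i, t in enumerate(arrs):
        if (t < 0).any():
            raise ValueError(f"stratum {i}: negative counts")
        if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
            warnings.warn(f"dropping degenerate stratum {i} (zero margin)")
            continue
        kept.append(t)
    if not kept:
        raise ValueError("no informative strata")
    st = StratifiedTable(np.stack(kept, axis=-1))
    or_mh = float(st.oddsratio_pooled)
    lo, hi = (float(x) for x in st.oddsratio_pooled_confint())
    p = float(st.test_null_odds(correction=correction).pvalue)
    return or_mh, (lo, hi), p


def fisher_frequency_compare(
    group_counts: dict[str, tuple[int, int]], reference: str
) -> pd.DataFrame:
    """Two-sided Fisher exact test of each group vs a reference.

    ``group_counts`` maps group name -> (positives, total). Zero-total
    groups are skipped with a warning.
    """
    if reference not in group_counts:
        raise ValueError(f"reference group {reference!r} missing")
    ref_pos, ref_tot = group_counts[reference]
    rows = []
    for g, (pos, tot) in group_counts.items():
        if tot == 0:
            warnings.warn(f"skipping zero-total group {g!r}")
            continue
        if g == reference:
            p = 1.0
            odds = 1.0
        else:
            table = [[pos, tot - pos], [ref_pos, ref_tot - ref_pos]]
            odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({"group": g, "positive": pos, "total": tot,
                     "fraction": pos / tot, "odds_ratio_vs_ref": float(odds),
                     "p_value": float(p)})
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# overlap weighting


@dataclass
class OverlapWeightResult:
    weights: pd.Series
    balance: pd.DataFrame  # weighted covariate means per arm + abs diff
    cox: CoxFit
    km: dict[str, KMSummary]
    unweighted_cox: CoxFit


def overlap_weight_analysis(
    df: pd.DataFrame,
    treatment_col: str,
    covariates: list[str],
    duration_col: str,
    event_col: str,
    references: dict[str, str] | None = None,
) -> OverlapWeightResult:
    """Overlap-weighting propensity comparison of two treatment arms.

    Fits a logistic propensity model e(x) (maximum likelihood, no
    regularization), assigns weights 1−e(x) to treated and e(x) to control
    subjects, and reruns the KM and Cox comparisons with those weights.
    With a logistic model containing an intercept, overlap weights balance
    every covariate mean exactly at the MLE.
    """
    import statsmodels.api as sm

    t = df[treatment_col]
    arms = sorted(t.unique(), key=str)
    if len(arms) != 2:
        raise ValueError(f"overlap weighting requires exactly 2 arms, got {list(arms)}")
    z = (t == arms[1]).astype(float)  # arms[1] = "treated"
    design, _ = _prepare_design(df, covariates, references)
    X = sm.add_constant(design.to_numpy(float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fitres = sm.Logit(z.to_numpy(float), X).fit(disp=0, method="newton",
                                                    tol=1e-12, maxiter=200)
    if not fitres.mle_retvals.get("converged", True):
        raise RuntimeError("propensity model did not converge")
    e = pd.Series(fitres.predict(X), index=df.index)
    w = z * (1.0 - e) + (1.0 - z) * e

    bal = {}
    for name in design.columns:
        x = design[name]
        m1 = float(np.average(x[z == 1], weights=w[z == 1]))
        m0 = float(np.average(x[z == 0], weights=w[z == 0]))
        bal[name] = {"treated_mean": m1, "control_mean": m0, "abs_diff": abs(m1 - m0)}
    balance = pd.DataFrame(bal).T

    work = df.copy()
    work["_ow"] = w
    cox_w = fit_cox(work, duration_col, event_col, [treatment_col], treatment_col,
                    references={treatment_col: str(arms[0])},
                    weights_col="_ow", robust=True)
    cox_u = fit_cox(work, duration_col, event_col, [treatment_col], treatment_col,
                    references={treatment_col: str(arms[0])})
    km = {}
    for arm in arms:
        mask = t == arm
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # non-integer weights are expected here
            kmf = KaplanMeierFitter().fit(
                work.loc[mask, duration_col].astype(float),
                work.loc[mask, event_col].astype(bool),
                weights=work.loc[mask, "_ow"].astype(float),
            )
        curve = kmf.survival_function_.reset_index()
        curve.columns = ["time", "survival"]
        km[str(arm)] = KMSummary(
            float(kmf.median_survival_time_), (np.nan, np.nan), curve,
            int(mask.sum()), int(work.loc[mask, event_col].astype(bool).sum()),
        )
    return OverlapWeightResult(weights=w, balance=balance, cox=cox_w, km=km,
                               unweighted_cox=cox_u)
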