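"""SM-INVIGOR: prognostic selection of a growth-rate index and stratification.

The serial-mammography in vivo growth rate index is built in three steps:

1. Every shape x growth-law combination yields per-patient rates; each is
   evaluated prognostically in a univariate Cox model of 10-year BCSS,
   both as a continuous covariate and dichotomised at the log-rank-optimal
   cutpoint, and the grid is ranked by AIC (lowest wins).
2. The fast/slow cutpoint is the candidate threshold (midpoints between
   consecutive distinct sorted rates, each side holding at least a
   configured fraction of patients) maximising the two-group log-rank
   chi-square. Ties break to the smaller threshold. The maximally selected
   p-value is reported raw, matching common practice for this index, with
   an optional permutation-adjusted p available as an extension.
3. Patients with rate strictly greater than the threshold are labelled
   ``fast``, the rest ``slow``; group survival is summarised by
   Kaplan-Meier, log-rank and Cox fits, optionally adjusted for
   clinicopathological confounders (grade, age, ER status).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry, growth, survival
from .cohort_io import CohortTable, complete_case_subset
from .errors import DataError

#: default minimum fraction of patients on each side of a candidate cutpoint
MIN_GROUP_FRAC = 0.10

#: default analysis horizon for univariate ranking (10-year BCSS, months)
HORIZON_MONTHS = 120.0

DEFAULT_ADJUSTERS = ("grade", "age_years", "er_status")


@dataclass
class CutpointResult:
    threshold: float
    chi_square: float
    p_value: float
    n_slow: int
    n_fast: int
    labels: np.ndarray  # 'slow' / 'fast' per patient, input order
    n_candidates: int
    permutation_p: float | None = None


@dataclass
class ModelGridResult:
    """Ranked grid of (shape, law, form) prognostic fits.

    ``table`` has one row per combination, ascending by AIC with failures
    (rates domain-invalid for >10% of patients, or an unfittable model)
    at the bottom and marked; ``best`` is the winning row. ``volume_fits``
    reports continuous univariate fits of the screening and diagnostic
    volumes themselves, for comparison against the change-based index.
    """

    table: pd.DataFrame
    best: pd.Series
    n_patients: int
    volume_fits: pd.DataFrame | None = None

    @property
    def best_shape(self) -> str:
        return str(self.best["shape"])

    @property
    def best_spec(self) -> growth.GrowthModelSpec:
        return _spec_from_label(str(self.best["law"]))


def _spec_from_label(label: str) -> growth.GrowthModelSpec:
    for spec in growth.default_law_grid():
        if spec.label == label:
            return spec
    if label.startswith("power_"):
        return growth.power_law(float(label.split("_", 1)[1]))
    raise ValueError(f"unknown law label {label!r}")


def candidate_thresholds(rates, min_group_frac: float = MIN_GROUP_FRAC) -> np.ndarray:
    """Admissible cutpoints: midpoints between consecutive distinct rates
    leaving at least ``min_group_frac`` of patients on each side."""
    rates = np.asarray(rates, dtype=float)
    n = rates.size
    distinct = np.unique(rates)
    if distinct.size < 2:
        raise DataError("all rates identical: no admissible cutpoint")
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    min_count = min_group_frac * n
    keep = []
    for thr in mids:
        n_fast = int(np.sum(rates > thr))
        if n_fast >= min_count and (n - n_fast) >= min_count:
            keep.append(thr)
    if not keep:
        raise DataError("no cutpoint satisfies the minimum group-size constraint")
    return np.asarray(keep)


def optimise_cutpoint(
    rates,
    time,
    event,
    min_group_frac: float = MIN_GROUP_FRAC,
) -> CutpointResult:
    """Log-rank-optimal fast/slow threshold over admissible midpoints.

    Deterministic: exact ties in the chi-square break to the smaller
    threshold. The reported p-value is the raw chi-square(1) tail at the
    optimum and is optimistic under maximal selection; see
    :func:`permutation_adjusted_p`.
    """
    rates = np.asarray(rates, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if np.isnan(rates).any():
        raise DataError("rates contain missing values; filter before cutpoint search")
    thresholds = candidate_thresholds(rates, min_group_frac)
    chi2 = survival.logrank_scan(time, event, rates, thresholds)
    best = int(np.argmax(chi2))  # argmax returns the first (smallest) maximiser
    thr = float(thresholds[best])
    labels = np.where(rates > thr, "fast", "slow")
    from scipy import stats

    return CutpointResult(
        threshold=thr,
        chi_square=float(chi2[best]),
        p_value=float(stats.chi2.sf(chi2[best], df=1)),
        n_slow=int(np.sum(labels == "slow")),
        n_fast=int(np.sum(labels == "fast")),
        labels=labels,
        n_candidates=int(thresholds.size),
    )


def permutation_adjusted_p(
    rates,
    time,
    event,
    min_group_frac: float = MIN_GROUP_FRAC,
    n_permutations: int = 1000,
    seed: int = 0,
) -> float:
    """Selection-adjusted p: permutation null of the maximised chi-square.

    Survival pairs are permuted against the rates; the adjusted p is the
    fraction of permutations whose maximal chi-square reaches the observed
    one (add-one estimator). Labelled an extension: the raw maximally
    selected p remains the primary report.
    """
    rng = np.random.default_rng(seed)
    observed = optimise_cutpoint(rates, time, event, min_group_frac).chi_square
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(time.size)
        null = optimise_cutpoint(rates, time[perm], event[perm], min_group_frac)
        if null.chi_square >= observed:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


def cross_validated_criterion(
    rates,
    time,
    event,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Optional alternative to plain AIC: out-of-fold partial likelihood.

    Fits the univariate Cox model on each training fold and evaluates the
    held-out mean partial log-likelihood; returns -2 x the total held-out
    log-likelihood (lower is better, AIC-like scale). Provided behind its
    own function rather than as the primary ranking, which uses plain AIC
    on the full cohort.
    """
    from lifelines import CoxPHFitter

    rates = np.asarray(rates, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    n = rates.size
    if event.sum() < folds:
        raise DataError(f"need at least {folds} events for {folds}-fold validation")
    rng = np.random.default_rng(seed)
    # stratify folds on the event indicator so every fold holds events
    assignment = np.empty(n, dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(event == cls)
        rng.shuffle(idx)
        assignment[idx] = np.arange(idx.size) % folds
    total = 0.0
    for f in range(folds):
        test = assignment == f
        train = pd.DataFrame(
            {"time": time[~test], "event": event[~test], "rate": rates[~test]}
        )
        held = pd.DataFrame(
            {"time": time[test], "event": event[test], "rate": rates[test]}
        )
        cph = CoxPHFitter()
        cph.fit(train, duration_col="time", event_col="event")
        total += float(cph.score(held, scoring_method="log_likelihood")) * len(held)
    return -2.0 * total


def rank_models(
    cohort: CohortTable,
    horizon_months: float = HORIZON_MONTHS,
    min_group_frac: float = MIN_GROUP_FRAC,
    shapes=geometry.SHAPES,
    laws=None,
    sphere_rule: str = "mean",
    max_invalid_frac: float = 0.10,
) -> ModelGridResult:
    """Rank every shape x law x {continuous, dichotomised} fit by AIC.

    Survival is administratively censored at the horizon before both the
    cutpoint search and the Cox fits. A combination whose rates are
    domain-invalid for more than ``max_invalid_frac`` of patients is
    marked failed and excluded from the ranking. Fully deterministic.
    """
    laws = list(laws) if laws is not None else growth.default_law_grid()
    cohort = complete_case_subset(
        cohort,
        [
            "screen_dim_major",
            "screen_dim_minor",
            "diag_dim_major",
            "diag_dim_minor",
            "interval_days",
            "bcss_months",
            "event",
        ],
    )
    df = cohort.df
    if len(df) == 0:
        raise DataError("no complete-case records with dimensions, interval and survival")
    if df["event"].sum() == 0:
        raise DataError("no events in the cohort: prognostic ranking impossible")
    time, event = survival.administrative_censor(df["bcss_months"], df["event"], horizon_months)
    if event.sum() == 0:
        raise DataError("no events inside the analysis horizon")

    # rates for every combination first; AIC is only comparable across fits of
    # the same subjects, so non-failed combinations share one common subset
    all_rates: dict[tuple[str, str], pd.DataFrame] = {}
    failed: dict[tuple[str, str], str] = {}
    common_ok = np.ones(len(df), dtype=bool)
    for shape in shapes:
        for spec in laws:
            rates_df = growth.cohort_rates(cohort, shape, spec, sphere_rule)
            invalid_frac = 1.0 - rates_df["valid"].mean()
            if invalid_frac > max_invalid_frac:
                failed[(shape, spec.label)] = (
                    f"rates invalid for {invalid_frac:.0%} of patients"
                )
            else:
                all_rates[(shape, spec.label)] = rates_df
                common_ok &= rates_df["valid"].to_numpy()
    if not common_ok.any():
        raise DataError("no patient has valid rates under every usable combination")

    rows = []
    vol_rows = []
    for shape in shapes:
        for spec in laws:
            base = {"shape": shape, "law": spec.label, "n_valid": int(common_ok.sum())}
            if (shape, spec.label) in failed:
                for form in ("continuous", "dichotomised"):
                    rows.append(
                        {
                            **base,
                            "form": form,
                            "aic": np.nan,
                            "coef": np.nan,
                            "hazard_ratio": np.nan,
                            "p_value": np.nan,
                            "cutpoint": np.nan,
                            "chi_square": np.nan,
                            "failed": True,
                            "message": failed[(shape, spec.label)],
                        }
                    )
                continue
            r = all_rates[(shape, spec.label)]["rate"].to_numpy()[common_ok]
            rows.extend(
                _fit_forms(base, r, time[common_ok], event[common_ok], min_group_frac)
            )
        # continuous univariate prognostic fits of the volumes themselves
        rates_df = growth.cohort_rates(cohort, shape, laws[0], sphere_rule)
        ok = rates_df["valid"].to_numpy() & common_ok
        for col, label in (("v_screen", "screening_volume"), ("v_diag", "diagnostic_volume")):
            try:
                fit = survival.fit_cox(
                    pd.DataFrame({"time": time[ok], "event": event[ok], "v": rates_df[col].to_numpy()[ok]}),
                    ["v"],
                )
                vol_rows.append(
                    {
                        "shape": shape,
                        "variable": label,
                        "aic": fit.aic,
                        "coef": float(fit.coefficients["v"]),
                        "p_value": float(fit.p_values["v"]),
                    }
                )
            except DataError as exc:
                vol_rows.append(
                    {"shape": shape, "variable": label, "aic": np.nan, "coef": np.nan, "p_value": np.nan}
                )

    table = pd.DataFrame(rows)
    ranked = table.sort_values(
        by=["failed", "aic", "shape", "law", "form"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    usable = ranked[~ranked["failed"] & ranked["aic"].notna()]
    if usable.empty:
        raise DataError("every shape x law combination failed")
    best = usable.iloc[0]
    return ModelGridResult(
        table=ranked,
        best=best,
        n_patients=len(df),
        volume_fits=pd.DataFrame(vol_rows),
    )


def _fit_forms(base, rates, time, event, min_group_frac):
    rows = []
    # continuous form
    try:
        fit = survival.fit_cox(
            pd.DataFrame({"time": time, "event": event, "rate": rates}), ["rate"]
        )
        rows.append(
            {
                **base,
                "form": "continuous",
                "aic": fit.aic,
                "coef": float(fit.coefficients["rate"]),
                "hazard_ratio": float(fit.hazard_ratios["rate"]),
                "p_value": float(fit.p_values["rate"]),
                "cutpoint": np.nan,
                "chi_square": np.nan,
                "failed": False,
                "message": "; ".join(fit.warnings),
            }
        )
    except Exception as exc:  # constant rates, non-convergence, ...
        rows.append(
            {
                **base,
                "form": "continuous",
                "aic": np.nan,
                "coef": np.nan,
                "hazard_ratio": np.nan,
                "p_value": np.nan,
                "cutpoint": np.nan,
                "chi_square": np.nan,
                "failed": True,
                "message": str(exc),
            }
        )
    # dichotomised form at the log-rank-optimal cutpoint
    try:
        cut = optimise_cutpoint(rates, time, event, min_group_frac)
        fast = (cut.labels == "fast").astype(float)
        fit = survival.fit_cox(
            pd.DataFrame({"time": time, "event": event, "fast": fast}), ["fast"]
        )
        rows.append(
            {
                **base,
                "form": "dichotomised",
                "aic": fit.aic,
                "coef": float(fit.coefficients["fast"]),
                "hazard_ratio": float(fit.hazard_ratios["fast"]),
                "p_value": float(fit.p_values["fast"]),
                "cutpoint": cut.threshold,
                "chi_square": cut.chi_square,
                "failed": False,
                "message": "; ".join(fit.warnings),
            }
        )
    except Exception as exc:
        rows.append(
            {
                **base,
                "form": "dichotomised",
                "aic": np.nan,
                "coef": np.nan,
                "hazard_ratio": np.nan,
                "p_value": np.nan,
                "cutpoint": np.nan,
                "chi_square": np.nan,
                "failed": True,
                "message": str(exc),
            }
        )
    return rows


def compute_sm_invigor(
    cohort: CohortTable,
    shape: str,
    spec: growth.GrowthModelSpec,
    threshold: float,
    sphere_rule: str = "mean",
    horizon_months: float | None = None,
) -> dict:
    """Label each patient fast/slow at a fixed threshold and report survival.

    ``fast`` means rate strictly greater than the threshold (a rate exactly
    at the threshold is slow). Returns a dict with the labelled rates table
    and, when both groups are populated and survival is available, KM
    summaries, the log-rank test and a univariate Cox fit of the label.
    """
    if not math.isfinite(threshold):
        raise DataError("threshold must be finite")
    rates_df = growth.cohort_rates(cohort, shape, spec, sphere_rule)
    labels = np.where(
        rates_df["rate"].notna() & (rates_df["rate"] > threshold), "fast", "slow"
    ).astype(object)
    labels[rates_df["rate"].isna().to_numpy()] = None
    rates_df = rates_df.assign(label=labels)
    report: dict = {
        "shape": shape,
        "law": spec.label,
        "threshold": float(threshold),
        "rate_unit": spec.rate_unit,
        "n_slow": int(np.sum(labels == "slow")),
        "n_fast": int(np.sum(labels == "fast")),
    }
    df = cohort.df
    have_survival = df["bcss_months"].notna() & df["event"].notna() & rates_df["valid"]
    if report["n_slow"] == 0 or report["n_fast"] == 0:
        warnings.warn("single growth group at this threshold: no group comparison performed")
        report["survival"] = None
        return {"rates": rates_df, "report": report}
    if not have_survival.any():
        report["survival"] = None
        return {"rates": rates_df, "report": report}

    sub = df[have_survival]
    lab = rates_df.loc[have_survival, "label"].to_numpy()
    time = sub["bcss_months"].to_numpy(dtype=float)
    event = sub["event"].to_numpy(dtype=float)
    if horizon_months is not None:
        time, event = survival.administrative_censor(time, event, horizon_months)
    surv_report: dict = {}
    for grp in ("slow", "fast"):
        mask = lab == grp
        curve = survival.km_estimate(time[mask], event[mask])
        surv_report[f"km_{grp}"] = {
            "n": int(mask.sum()),
            "events": int(event[mask].sum()),
            "survival_at_120m": curve.survival_at(120.0),
        }
    if event.sum() > 0 and (lab == "fast").any() and (lab == "slow").any():
        lr = survival.logrank_test(time, event, lab == "fast")
        surv_report["logrank"] = {"chi_square": lr.chi_square, "p_value": lr.p_value}
        fit = survival.fit_cox(
            pd.DataFrame({"time": time, "event": event, "fast": (lab == "fast").astype(float)}),
            ["fast"],
        )
        surv_report["cox_univariate"] = {
            "hazard_ratio_fast": float(fit.hazard_ratios["fast"]),
            "p_value": float(fit.p_values["fast"]),
            "aic": fit.aic,
        }
    report["survival"] = surv_report
    return {"rates": rates_df, "report": report}


def encode_covariates(df: pd.DataFrame, fields) -> pd.DataFrame:
    """Numeric design matrix for Cox adjustment.

    Numeric fields pass through; receptor statuses become 1 (positive) /
    0 (negative); lymphovascular invasion is coded 0/1/2 for
    negative/probable/definite. Missing stays missing (complete-case at
    fit time).
    """
    out = {}
    lvi_code = {"negative": 0.0, "probable": 1.0, "definite": 2.0}
    for f in fields:
        if f not in df.columns:
            raise KeyError(f"unknown covariate '{f}'")
        col = df[f]
        if f in ("er_status", "pr_status", "her2_status"):
            out[f] = col.map({"positive": 1.0, "negative": 0.0})
        elif f == "lvi":
            out[f] = col.map(lvi_code)
        else:
            out[f] = pd.to_numeric(col, errors="coerce")
    return pd.DataFrame(out, index=df.index)


def multivariate_adjustment(
    cohort: CohortTable,
    labels,
    adjusters=DEFAULT_ADJUSTERS,
    horizon_months: float | None = None,
) -> survival.CoxFit:
    """Cox fit of the fast/slow label alongside clinicopathological adjusters.

    With no adjusters this reduces to the univariate fit of the label.
    Collinear adjusters surface as fitter warnings on the returned fit;
    a constant label raises :class:`DataError`.
    """
    df = cohort.df
    labels = np.asarray(labels, dtype=object)
    if labels.shape[0] != len(df):
        raise DataError("labels must align with the cohort")
    fast = pd.Series(
        [1.0 if l == "fast" else 0.0 if l == "slow" else np.nan for l in labels],
        index=df.index,
    )
    design = pd.DataFrame({"fast": fast})
    if adjusters:
        design = pd.concat([design, encode_covariates(df, adjusters)], axis=1)
    design["time"] = pd.to_numeric(df["bcss_months"], errors="coerce")
    design["event"] = pd.to_numeric(df["event"], errors="coerce")
    return survival.fit_cox(
        design,
        [c for c in design.columns if c not in ("time", "event")],
        horizon_months=horizon_months,
    )
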