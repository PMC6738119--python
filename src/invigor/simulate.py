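"""Synthetic missed-cancer cohorts with known ground truth.

Real serial-mammography missed-cancer cohorts are rare and not publicly
deposited, so every pipeline stage is exercised on generated cohorts that
reproduce the statistical structure the analysis assumes:

* screening tumour volumes: log-normal, moment-matched to a mean of
  2742 mm^3 with SD 7619 mm^3 (range roughly 50-56,000 mm^3 at n≈92);
* inter-mammogram interval: scaled Beta on [4, 37] months solved for
  mean 18 and mode 17.5 months;
* true growth rates: half-normal (truncated at zero) scaled to mean
  0.08 mm^3/day, which puts essentially no mass above the observed
  maximum 0.53;
* diagnostic volume: forward simulation of the true growth law
  (default power law, alpha = 0.5) from the screening volume;
* mammogram dimensions: back-computed from each volume and a drawn
  aspect ratio in [1, 2] under the configured shape, so the geometry
  stage is exercised non-trivially and the pipeline's inverted rates
  reproduce the generator's true rates exactly;
* survival: a step hazard in the true growth group (rate above/below a
  true threshold, default 0.045 mm^3/day) with exponential baselines set
  by 10-year BCSS of ~92% (slow) and ~72% (fast), i.e. a fast:slow
  hazard ratio of ~3.9; administrative censoring uniform on
  [60, 180] months;
* clinicopathological features drawn conditionally on the growth group:
  Ki67 (fast mean 24% vs slow 11%), mitotic score, histological size,
  grade, nodal stage (then NPI from its formula), with the remaining
  features near-uninformative marginals.

A ground-truth sidecar (true rate, group, volumes, latent times) is
returned separately and written to a separate file; pipeline stages
never read it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry
from .cohort_io import CohortTable, cohort_from_frame
from .errors import DataError
from .growth import DAYS_PER_MONTH, GrowthModelSpec, forward_volume, power_law

#: printed-cohort summaries the default generator is calibrated to
CALIBRATION_TARGETS = {
    "screening_volume_mean_mm3": 2742.0,
    "screening_volume_sd_mm3": 7619.0,
    "diagnostic_volume_mean_mm3": 5573.0,
    "interval_mean_months": 18.0,
    "interval_median_months": 17.5,
    "interval_range_months": (4.0, 37.0),
    "rate_mean_mm3_per_day": 0.08,
    "rate_max_mm3_per_day": 0.53,
    "ki67_mean_fast_percent": 24.0,
    "ki67_mean_slow_percent": 11.0,
    "bcss_10yr_slow": 0.92,
    "bcss_10yr_fast": 0.72,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort generator (seed-deterministic)."""

    n: int = 92
    seed: int = 0
    # screening volume: log-normal moment-matched to (mean, sd) in mm^3
    volume_mean: float = 2742.0
    volume_sd: float = 7619.0
    # interval: scaled Beta on [lo, hi] months with given mean and mode
    interval_range: tuple[float, float] = (4.0, 37.0)
    interval_mean: float = 18.0
    interval_mode: float = 17.5
    # true growth law and half-normal rate scale (mean rate, conventional units)
    true_law: GrowthModelSpec = field(default_factory=lambda: power_law(0.5))
    rate_mean: float = 0.08
    # geometry used to back-compute dimensions
    shape_for_dims: str = "sphere"
    sphere_rule: str = "mean"
    aspect_range: tuple[float, float] = (1.0, 2.0)
    # step-hazard survival model
    true_threshold: float = 0.045
    bcss_10yr_slow: float = 0.92
    bcss_10yr_fast: float = 0.72
    censor_range_months: tuple[float, float] = (60.0, 180.0)
    # feature model (group-conditional)
    ki67_mean_fast: float = 24.0
    ki67_mean_slow: float = 11.0
    ki67_sd_fast: float = 15.0
    ki67_sd_slow: float = 9.0
    her2_missing_rate: float = 0.065
    subtype_missing_rate: float = 0.065

    def validate(self):
        if self.n < 0:
            raise DataError("n must be non-negative")
        if self.volume_mean <= 0 or self.volume_sd < 0:
            raise DataError("volume parameters must be positive")
        lo, hi = self.interval_range
        if not (lo < self.interval_mode < hi and lo < self.interval_mean < hi):
            raise DataError("interval mean/mode must lie inside the range")
        if self.rate_mean < 0:
            raise DataError("rate_mean must be non-negative")
        if not (0 < self.bcss_10yr_fast <= self.bcss_10yr_slow < 1):
            raise DataError("need 0 < fast 10-year BCSS <= slow < 1")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and SD."""
    cv2 = (sd / mean) ** 2
    sigma2 = np.log1p(cv2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _beta_params(lo, hi, mean, mode) -> tuple[float, float]:
    """Shape parameters of a Beta on [lo, hi] with given mean and mode."""
    m = (mean - lo) / (hi - lo)
    c = (mode - lo) / (hi - lo)
    if not 0 < c < 1 or not 0 < m < 1:
        raise DataError("interval mean/mode outside the open range")
    s = (1 - 2 * c) / (m - c) if m != c else None
    if s is None or s <= 2:
        raise DataError("no valid Beta shape for the requested interval mean/mode")
    return m * s, (1 - m) * s


def generate_cohort(config: GeneratorConfig) -> tuple[CohortTable, pd.DataFrame]:
    """Draw a cohort plus its ground-truth sidecar. Deterministic given seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n
    if n == 0:
        empty = cohort_from_frame(pd.DataFrame({"patient_id": pd.Series([], dtype=object)}))
        return empty, pd.DataFrame()

    mu, sigma = _lognormal_params(config.volume_mean, config.volume_sd)
    v0 = rng.lognormal(mu, sigma, size=n)

    a, b = _beta_params(*config.interval_range, config.interval_mean, config.interval_mode)
    lo, hi = config.interval_range
    interval_months = lo + (hi - lo) * rng.beta(a, b, size=n)
    dt_days = interval_months * DAYS_PER_MONTH

    if config.rate_mean == 0:
        rate = np.zeros(n)
    else:
        scale = config.rate_mean * np.sqrt(np.pi / 2.0)
        rate = np.abs(rng.normal(0.0, scale, size=n))
    v1 = forward_volume(config.true_law, v0, rate, dt_days)
    if not np.all(np.isfinite(v1)):
        raise DataError("volume/rate parameters produced non-finite diagnostic volumes")

    aspect0 = rng.uniform(*config.aspect_range, size=n)
    aspect1 = rng.uniform(*config.aspect_range, size=n)
    s_maj, s_min = geometry.dimensions_from_volume(
        v0, aspect0, config.shape_for_dims, config.sphere_rule
    )
    d_maj, d_min = geometry.dimensions_from_volume(
        v1, aspect1, config.shape_for_dims, config.sphere_rule
    )

    fast = rate > config.true_threshold
    lam_slow = -np.log(config.bcss_10yr_slow) / 120.0  # per month
    lam_fast = -np.log(config.bcss_10yr_fast) / 120.0
    lam = np.where(fast, lam_fast, lam_slow)
    event_time = rng.exponential(1.0 / lam)
    censor_time = rng.uniform(*config.censor_range_months, size=n)
    bcss = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(float)

    feats = _draw_features(rng, fast, config)

    df = pd.DataFrame(
        {
            "patient_id": [f"SYN{i:05d}" for i in range(n)],
            "screen_dim_major": s_maj,
            "screen_dim_minor": s_min,
            "diag_dim_major": d_maj,
            "diag_dim_minor": d_min,
            "interval_days": dt_days,
            "bcss_months": bcss,
            "event": event,
            **feats,
        }
    )
    truth = pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "true_rate": rate,
            "true_group": np.where(fast, "fast", "slow"),
            "true_v_screen": v0,
            "true_v_diag": v1,
            "hazard_per_month": lam,
            "latent_event_time_months": event_time,
            "censor_time_months": censor_time,
        }
    )
    cohort = cohort_from_frame(df, provenance=f"synthetic(seed={config.seed}, n={n})")
    return cohort, truth


def _draw_features(rng: np.random.Generator, fast: np.ndarray, config: GeneratorConfig):
    n = fast.size

    def by_group(fast_vals, slow_vals):
        return np.where(fast, fast_vals, slow_vals)

    ki67 = by_group(
        rng.normal(config.ki67_mean_fast, config.ki67_sd_fast, n),
        rng.normal(config.ki67_mean_slow, config.ki67_sd_slow, n),
    ).clip(0.0, 100.0)

    def ordinal(p_slow, p_fast):
        u = rng.random(n)
        cdf_slow = np.cumsum(p_slow)
        cdf_fast = np.cumsum(p_fast)
        out = np.empty(n)
        for i in range(n):
            cdf = cdf_fast if fast[i] else cdf_slow
            out[i] = 1 + np.searchsorted(cdf, u[i])
        return out

    mitotic = ordinal((0.50, 0.35, 0.15), (0.15, 0.35, 0.50))
    grade = ordinal((0.25, 0.50, 0.25), (0.08, 0.37, 0.55))
    nodal = ordinal((0.70, 0.23, 0.07), (0.55, 0.32, 0.13))
    size = by_group(
        rng.lognormal(np.log(24.0), 0.45, n), rng.lognormal(np.log(16.0), 0.45, n)
    ).clip(3.0, 120.0)
    npi = 0.2 * size / 10.0 + grade + nodal
    age = rng.normal(60.3, 5.5, n).clip(50.0, 73.0)

    def tri_state(p_pos, missing_rate=0.0):
        u = rng.random(n)
        vals = np.where(u < p_pos, "positive", "negative").astype(object)
        if missing_rate:
            vals[rng.random(n) < missing_rate] = np.nan
        return vals

    er = tri_state(0.848)
    pr = tri_state(0.641)
    her2 = tri_state(0.058, config.her2_missing_rate)

    lvi_levels = np.array(["negative", "probable", "definite"], dtype=object)
    lvi_p_slow = np.array([0.75, 0.11, 0.14])
    lvi_p_fast = np.array([0.50, 0.12, 0.38])
    u = rng.random(n)
    lvi = np.empty(n, dtype=object)
    for i in range(n):
        p = lvi_p_fast if fast[i] else lvi_p_slow
        lvi[i] = lvi_levels[np.searchsorted(np.cumsum(p), u[i])]

    subtype_levels = np.array(["luminal A", "luminal B", "HER2", "TNBC", "BLBC"], dtype=object)
    sub_p = np.array([0.44, 0.33, 0.06, 0.12, 0.05])
    u = rng.random(n)
    subtype = subtype_levels[np.searchsorted(np.cumsum(sub_p), np.minimum(u, 0.999999))]
    subtype = subtype.astype(object)
    subtype[rng.random(n) < config.subtype_missing_rate] = np.nan

    return {
        "age_years": age,
        "grade": grade,
        "histological_size_mm": size,
        "npi": npi,
        "mitotic_score": mitotic,
        "nodal_stage": nodal,
        "ki67_percent": ki67,
        "er_status": er,
        "pr_status": pr,
        "her2_status": her2,
        "lvi": lvi,
        "subtype": subtype,
    }


def make_feature_selection_problem(
    n: int = 200,
    n_informative: int = 3,
    n_noise: int = 4,
    effect: float = 1.0,
    label_noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """A labelled feature matrix where exactly the first ``n_informative``
    features determine the label.

    Labels are the sign of a linear score of the informative features
    (standard-normal columns, shared coefficient ``effect``), optionally
    blurred by Gaussian label noise; the remaining ``n_noise`` columns are
    independent standard normals. With the default ``label_noise_sd = 0``
    the label is a deterministic function of the informative features.
    ``effect = 0`` with positive label noise gives the null problem
    (labels independent of every feature). Used to check that sequential
    selection recovers the informative set and that null-label data
    cannot be overfit by the search harness.
    """
    rng = np.random.default_rng(seed)
    total = n_informative + n_noise
    X = rng.normal(size=(n, total))
    score = effect * X[:, :n_informative].sum(axis=1)
    if label_noise_sd:
        score = score + label_noise_sd * rng.normal(size=n)
    y = np.where(score > 0, "fast", "slow").astype(object)
    names = [f"signal_{i + 1}" for i in range(n_informative)] + [
        f"noise_{i + 1}" for i in range(n_noise)
    ]
    return pd.DataFrame(X, columns=names), y


def calibration_report(cohort: CohortTable, shape: str = "sphere", sphere_rule: str = "mean") -> pd.DataFrame:
    """Observed cohort summaries side-by-side with the calibration targets.

    Volumes and rates are recomputed through the pipeline's own geometry
    and growth stages (power law, alpha = 0.5) so the report reflects what
    the analysis sees, not generator internals.
    """
    from .growth import cohort_rates

    if len(cohort) == 0:
        return pd.DataFrame(columns=["statistic", "observed", "reference"])
    rates = cohort_rates(cohort, shape, power_law(0.5), sphere_rule)
    ok = rates["valid"]
    interval_months = cohort.df["interval_days"] / DAYS_PER_MONTH
    rows = [
        ("screening_volume_mean_mm3", rates.loc[ok, "v_screen"].mean()),
        ("screening_volume_sd_mm3", rates.loc[ok, "v_screen"].std()),
        ("screening_volume_min_mm3", rates.loc[ok, "v_screen"].min()),
        ("screening_volume_max_mm3", rates.loc[ok, "v_screen"].max()),
        ("diagnostic_volume_mean_mm3", rates.loc[ok, "v_diag"].mean()),
        ("interval_mean_months", interval_months.mean()),
        ("interval_median_months", interval_months.median()),
        ("interval_min_months", interval_months.min()),
        ("interval_max_months", interval_months.max()),
        ("rate_mean_mm3_per_day", rates.loc[ok, "rate"].mean()),
        ("rate_max_mm3_per_day", rates.loc[ok, "rate"].max()),
        ("ki67_mean_percent", cohort.df["ki67_percent"].mean()),
    ]
    refs = {
        "screening_volume_min_mm3": 53.0,
        "screening_volume_max_mm3": 56115.0,
        "interval_min_months": 4.0,
        "interval_max_months": 37.0,
        **{k: v for k, v in CALIBRATION_TARGETS.items() if not isinstance(v, tuple)},
    }
    return pd.DataFrame(
        [{"statistic": k, "observed": float(v), "reference": refs.get(k, np.nan)} for k, v in rows]
    )
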