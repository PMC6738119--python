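"""Tumour growth laws: forward simulation, rate inversion, back-dating.

Three growth laws are supported, each a one-parameter ODE in tumour
volume V (mm^3) with per-patient rate r:

* exponential   dV/dt = r V            V(t) = V0 exp(r t)
* power law     dV/dt = r V^alpha      V(t) = (V0^(1-a) + (1-a) r t)^(1/(1-a))
* Gompertz      dV/dt = r V ln(K/V)    V(t) = K (V0/K)^exp(-r t)

alpha = 2/3 is the classic surface-limited exponent; alpha = 1/2 is an
empirically supported alternative. K is the Gompertz carrying capacity,
defaulting to 1e6 mm^3 (~1e12 cells at 1e9 cells/cm^3, the conventional
lethal-burden bound).

A patient contributes one observation (v0 at screening, v1 at diagnosis,
dt days between mammograms); inverting the closed form gives the exact
per-patient rate. Power-law rates formally carry units mm^(3(1-alpha))/day
but are conventionally labelled mm^3/day; the numeric value is stored
exactly as the closed form yields it and a unit descriptor travels with it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geometry
from .errors import DomainError

LAWS = ("exponential", "power", "gompertz")

#: days per month used wherever month-denominated intervals are converted
DAYS_PER_MONTH = 30.44

#: default Gompertz carrying capacity, mm^3
DEFAULT_CARRYING_CAPACITY = 1e6


@dataclass(frozen=True)
class GrowthModelSpec:
    """A growth law plus the parameters it needs.

    ``alpha`` is required iff ``law == "power"`` (any value in (0, 1));
    ``carrying_capacity`` is required iff ``law == "gompertz"`` and must
    exceed every volume it is applied to.
    """

    law: str
    alpha: float | None = None
    carrying_capacity: float | None = None

    def __post_init__(self):
        if self.law not in LAWS:
            raise ValueError(f"unknown growth law {self.law!r}; choose from {LAWS}")
        if self.law == "power":
            if self.alpha is None:
                raise ValueError("power law requires alpha")
            if not 0 < self.alpha < 1:
                raise ValueError("power-law alpha must lie in (0, 1)")
        elif self.alpha is not None:
            raise ValueError(f"alpha is only meaningful for the power law, not {self.law}")
        if self.law == "gompertz":
            if self.carrying_capacity is None or self.carrying_capacity <= 0:
                raise ValueError("gompertz requires a positive carrying capacity")
        elif self.carrying_capacity is not None:
            raise ValueError("carrying_capacity is only meaningful for gompertz")

    @property
    def label(self) -> str:
        if self.law == "power":
            return f"power_{self.alpha:g}"
        return self.law

    @property
    def rate_unit(self) -> str:
        if self.law == "power":
            return f"mm^{3 * (1 - self.alpha):g}/day (conventional label: mm^3/day)"
        return "1/day (conventional label: mm^3/day)"


def exponential() -> GrowthModelSpec:
    return GrowthModelSpec("exponential")


def power_law(alpha: float) -> GrowthModelSpec:
    return GrowthModelSpec("power", alpha=alpha)


def gompertz(carrying_capacity: float = DEFAULT_CARRYING_CAPACITY) -> GrowthModelSpec:
    return GrowthModelSpec("gompertz", carrying_capacity=carrying_capacity)


def default_law_grid() -> list[GrowthModelSpec]:
    """The four laws evaluated in the model grid."""
    return [exponential(), power_law(0.5), power_law(2.0 / 3.0), gompertz()]


def forward_volume(spec: GrowthModelSpec, v0, r, t):
    """Volume after ``t`` days of growth from ``v0`` at rate ``r``."""
    v0 = np.asarray(v0, dtype=float)
    r = np.asarray(r, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(v0 <= 0):
        raise DomainError("initial volume must be positive")
    if np.any(t < 0):
        raise DomainError("time must be non-negative")
    if spec.law == "exponential":
        out = v0 * np.exp(r * t)
    elif spec.law == "power":
        a = spec.alpha
        base = v0 ** (1 - a) + (1 - a) * r * t
        if np.any(base <= 0):
            raise DomainError("power-law trajectory regresses past zero volume")
        out = base ** (1.0 / (1 - a))
    else:  # gompertz
        K = spec.carrying_capacity
        if np.any(v0 >= K):
            raise DomainError("gompertz requires v0 < carrying capacity")
        out = K * (v0 / K) ** np.exp(-r * t)
    return out if out.ndim else float(out)


def invert_rate(spec: GrowthModelSpec, v0, v1, dt):
    """Exact per-observation rate: forward_volume(spec, v0, r, dt) == v1.

    ``r == 0`` iff ``v1 == v0``; negative rates (shrinkage) are returned
    as-is and flagged downstream.
    """
    v0 = np.asarray(v0, dtype=float)
    v1 = np.asarray(v1, dtype=float)
    dt = np.asarray(dt, dtype=float)
    if np.any(v0 <= 0) or np.any(v1 <= 0):
        raise DomainError("volumes must be positive")
    if np.any(dt <= 0):
        raise DomainError("interval must be positive")
    if spec.law == "exponential":
        r = np.log(v1 / v0) / dt
    elif spec.law == "power":
        a = spec.alpha
        r = (v1 ** (1 - a) - v0 ** (1 - a)) / ((1 - a) * dt)
    else:  # gompertz
        K = spec.carrying_capacity
        if np.any(v0 >= K) or np.any(v1 >= K):
            raise DomainError("gompertz requires volumes below the carrying capacity")
        r = -np.log(np.log(K / v1) / np.log(K / v0)) / dt
    return r if r.ndim else float(r)


def tumour_age(spec: GrowthModelSpec, v_diag, r, v_inception):
    """Days needed to grow from ``v_inception`` to ``v_diag`` at rate ``r``.

    Back-dating: with a bounded rate for a subgroup this gives the latest
    time at which the tumour could have reached its inception size, i.e.
    the date after which it was definitely present. The power law admits
    ``v_inception = 0``; exponential and Gompertz growth never leave zero,
    so a positive inception volume is required there.
    """
    v_diag = float(v_diag)
    r = float(r)
    v_inception = float(v_inception)
    if r <= 0:
        raise DomainError("back-dating requires a strictly positive rate")
    if not 0 <= v_inception < v_diag:
        raise DomainError("need 0 <= v_inception < v_diag")
    if spec.law == "exponential":
        if v_inception == 0:
            raise DomainError("exponential growth never leaves zero volume")
        return np.log(v_diag / v_inception) / r
    if spec.law == "power":
        a = spec.alpha
        return (v_diag ** (1 - a) - v_inception ** (1 - a)) / ((1 - a) * r)
    # gompertz
    K = spec.carrying_capacity
    if v_inception == 0:
        raise DomainError("gompertz growth never leaves zero volume")
    if v_diag >= K:
        raise DomainError("diagnostic volume must lie below the carrying capacity")
    return -np.log(np.log(K / v_diag) / np.log(K / v_inception)) / r


def cohort_rates(
    cohort,
    shape: str,
    spec: GrowthModelSpec,
    sphere_rule: str = "mean",
) -> pd.DataFrame:
    """Per-patient rates for a cohort under one shape x law combination.

    Returns a DataFrame aligned with the cohort (one row per record, order
    preserved) with columns ``patient_id, v_screen, v_diag, rate, valid,
    note``. Records that cannot be inverted (missing dimensions, dt <= 0,
    volumes at/above the Gompertz capacity) get ``rate = NaN``,
    ``valid = False`` and a diagnostic note; they are never silently
    dropped. Negative rates are valid but carry a ``shrinkage`` note.
    """
    df = cohort.df if hasattr(cohort, "df") else cohort
    n = len(df)
    dim_cols = ["screen_dim_major", "screen_dim_minor", "diag_dim_major", "diag_dim_minor"]
    dims = df[dim_cols].to_numpy(dtype=float)
    dt = df["interval_days"].to_numpy(dtype=float)

    notes = np.full(n, "", dtype=object)
    missing_dim = np.isnan(dims).any(axis=1)
    notes[missing_dim] = "missing dimension"
    bad_dim = (~missing_dim) & (dims <= 0).any(axis=1)
    notes[bad_dim] = "non-positive dimension"
    bad_dt = (~missing_dim) & (~bad_dim) & (np.isnan(dt) | (dt <= 0))
    notes[bad_dt] = "non-positive or missing interval"
    ok = ~(missing_dim | bad_dim | bad_dt)

    v_screen = np.full(n, np.nan)
    v_diag = np.full(n, np.nan)
    rate = np.full(n, np.nan)
    if ok.any():
        v_screen[ok] = geometry.lesion_volume(dims[ok, 0], dims[ok, 1], shape, sphere_rule)
        v_diag[ok] = geometry.lesion_volume(dims[ok, 2], dims[ok, 3], shape, sphere_rule)
        if spec.law == "gompertz":
            over = ok & (
                (v_screen >= spec.carrying_capacity) | (v_diag >= spec.carrying_capacity)
            )
            notes[over] = "volume at/above gompertz carrying capacity"
            v_screen[over] = np.nan
            v_diag[over] = np.nan
            ok &= ~over
        if ok.any():
            rate[ok] = invert_rate(spec, v_screen[ok], v_diag[ok], dt[ok])
    shrink = ok & (rate < 0)
    notes[shrink] = "shrinkage (negative rate)"
    return pd.DataFrame(
        {
            "patient_id": df["patient_id"].to_numpy(),
            "v_screen": v_screen,
            "v_diag": v_diag,
            "rate": rate,
            "valid": ok,
            "note": notes,
        },
        index=df.index,
    )


def lesion_volume_pair(dim_major, dim_minor, shape, sphere_rule="mean"):
    """Scalar convenience wrapper around :func:`invigor.geometry.lesion_volume`."""
    return float(geometry.lesion_volume(float(dim_major), float(dim_minor), shape, sphere_rule))
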