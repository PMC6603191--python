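"""The integrated microdosimetric-kinetic (IMK) survival model.

Cell killing is the sum of two Poisson-distributed lethal-lesion loads:

* **Targeted effects (TE)** — lesions produced along radiation tracks in
  the hit cell.  For an arbitrary delivery schedule chopped into N
  sub-sections of width dT the expected lethal lesions per cell are

      w_T = sum_n [(alpha0 + gamma*beta0) d_n + beta0 d_n^2]
            + 2 beta0 sum_{n<m} d_n d_m exp(-(m-n)(a+c) dT)

  where d_n is the dose in sub-section n and (a+c) is the first-order
  sub-lethal damage repair (SLDR) rate.  In the continuum limit for a
  constant dose rate this collapses to the linear-quadratic form with the
  Lea-Catcheside protraction factor F:

      w_T = (alpha0 + gamma*beta0) D + F(a+c, T) beta0 D^2.

* **Non-targeted effects (NTE)** — killing of cells by signals released
  from hit cells.  A cell carries at least one signal-emitting activated
  target with probability f_h(D) = 1 - exp(-[(alpha_b + gamma*beta_b) D +
  beta_b D^2]); signal recipients are the non-hit cells, and the expected
  signal-induced lethal lesions are w_NT = delta * f_h(D_IF) * f_b(D_*),
  a function of cumulative dose only (fractionation-independent).

Survival is S = exp(-w_T - w_NT), i.e. exactly the product of the TE and
NTE survivals.  gamma (Gy) is the dose-mean specific energy per event in
a micron-scale domain, obtained from the dose-mean lineal energy y_D.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .errors import ValidationError
from .schedules import DeliverySchedule, DiscretizedSchedule, discretize

__all__ = [
    "KEV_PER_UM_TO_GY", "Y_D_IN_FIELD", "Y_D_OUT_OF_FIELD",
    "GAMMA_IN_FIELD", "GAMMA_OUT_OF_FIELD", "REGIONS",
    "Microdosimetry", "TEParams", "NTEParams", "FieldConfig", "LesionLoad",
    "MigrationModel", "DamageScaling",
    "gamma_from_yd", "lea_catcheside_f", "w_te_continuous", "w_te_schedule",
    "w_te_schedule_adaptive", "hit_fraction", "w_nte", "lesion_load",
    "survival", "survival_acute", "migration_adjusted_survival",
    "scale_by_damage_yield",
]

# 1 keV/um divided by (1 g/cm^3 * 1 um^2) expressed in Gy:
# 1.602e-16 J/keV over 1e-15 kg/um of domain mass per unit track length.
KEV_PER_UM_TO_GY = 0.1602

#: Dose-mean lineal energy of the 225 kVp X-ray field (keV/um).
Y_D_IN_FIELD = 4.393
#: Same quantity for the softer, scattered spectrum behind the shield.
Y_D_OUT_OF_FIELD = 4.769

#: Largest magnitude allowed in an exponent before exponentiation.
_EXP_CLIP = 700.0

REGIONS = ("in_field", "out_of_field", "uniform")


def gamma_from_yd(y_d: float, rho: float = 1.0, r_d: float = 0.5) -> float:
    """Microdosimetric conversion gamma = y_D / (rho * pi * r_d^2), in Gy.

    Parameters are the dose-mean lineal energy ``y_d`` (keV/um), medium
    density ``rho`` (g/cm^3) and domain radius ``r_d`` (um).  The unit
    conversion keV/um -> J/m over kg/m is folded into a single constant.
    """
    if y_d <= 0 or rho <= 0 or r_d <= 0:
        raise ValidationError("y_d, rho and r_d must all be positive")
    return KEV_PER_UM_TO_GY * y_d / (rho * math.pi * r_d ** 2)


GAMMA_IN_FIELD = gamma_from_yd(Y_D_IN_FIELD)
GAMMA_OUT_OF_FIELD = gamma_from_yd(Y_D_OUT_OF_FIELD)


@dataclass(frozen=True)
class Microdosimetry:
    """Domain-level energy-deposition summary for one radiation quality."""

    y_d: float            # keV/um
    rho: float = 1.0      # g/cm^3
    r_d: float = 0.5      # um

    def __post_init__(self) -> None:
        if self.y_d <= 0 or self.rho <= 0 or self.r_d <= 0:
            raise ValidationError("Microdosimetry fields must be positive")

    @property
    def gamma(self) -> float:
        return gamma_from_yd(self.y_d, self.rho, self.r_d)


@dataclass(frozen=True)
class TEParams:
    """Cell-line coefficients for DNA-targeted effects."""

    alpha0: float      # Gy^-1
    beta0: float       # Gy^-2
    a_plus_c: float    # h^-1, SLDR rate; 0 means no repair during delivery

    def __post_init__(self) -> None:
        for name in ("alpha0", "beta0", "a_plus_c"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValidationError(f"TEParams.{name} must be finite and >= 0")


@dataclass(frozen=True)
class NTEParams:
    """Cell-line coefficients for intercellular-communication killing."""

    alpha_b: float   # Gy^-1
    beta_b: float    # Gy^-2
    delta: float     # dimensionless ceiling on signal-induced lesions

    def __post_init__(self) -> None:
        for name in ("alpha_b", "beta_b", "delta"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValidationError(f"NTEParams.{name} must be finite and >= 0")


@dataclass(frozen=True)
class FieldConfig:
    """Spatial exposure geometry: in-field area fraction and radiation quality.

    ``scatter_fraction`` is the ratio of direct dose reaching the shielded
    region to the in-field dose; it defaults to 0 (out-of-field killing is
    then purely signal-mediated).
    """

    a_if: float = 1.0
    scatter_fraction: float = 0.0
    gamma_if: float = GAMMA_IN_FIELD
    gamma_of: float = GAMMA_OUT_OF_FIELD

    def __post_init__(self) -> None:
        if not (0.0 < self.a_if <= 1.0):
            raise ValidationError(f"a_if must be in (0, 1], got {self.a_if}")
        if self.scatter_fraction < 0:
            raise ValidationError("scatter_fraction must be >= 0")
        if self.gamma_if <= 0 or self.gamma_of <= 0:
            raise ValidationError("gamma values must be positive")

    def region_gamma_dose(self, d_if: float, region: str) -> tuple[float, float]:
        """(gamma, direct dose) seen by cells in ``region`` when the
        in-field (or uniform) delivered dose is ``d_if``."""
        if region in ("in_field", "uniform"):
            return self.gamma_if, d_if
        if region == "out_of_field":
            return self.gamma_of, self.scatter_fraction * d_if
        raise ValidationError(f"unknown region {region!r}; expected one of {REGIONS}")


@dataclass(frozen=True)
class LesionLoad:
    """Expected lethal lesions per cell, split by mechanism."""

    w_t: float
    w_nt: float

    @property
    def w(self) -> float:
        return self.w_t + self.w_nt

    @property
    def survival(self) -> float:
        return float(np.exp(-np.clip(self.w, -_EXP_CLIP, _EXP_CLIP)))


@dataclass(frozen=True)
class MigrationModel:
    """Mixture model: a fraction of scored cells migrated in unirradiated."""

    f_move: float
    s_m: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_move <= 1.0):
            raise ValidationError(f"f_move must be in [0, 1], got {self.f_move}")
        if not (0.0 < self.s_m <= 1.0):
            raise ValidationError(f"s_m must be in (0, 1], got {self.s_m}")


@dataclass(frozen=True)
class DamageScaling:
    """Ratio of initial potentially-lethal-lesion yields per Gy, k'/k."""

    k_ratio: float

    def __post_init__(self) -> None:
        if not (self.k_ratio > 0 and math.isfinite(self.k_ratio)):
            raise ValidationError("k_ratio must be finite and > 0")


# --- targeted effects -------------------------------------------------------

_F_SERIES_SWITCH = 1e-3


def lea_catcheside_f(a_plus_c, t):
    """Dose-protraction factor F(x) = 2[x + e^-x - 1]/x^2 with x = (a+c)T.

    F = 1 for acute delivery (x = 0) and decays towards 0 as the delivery
    stretches relative to the repair time.  Below x = 1e-3 a truncated
    Taylor series replaces the direct expression: there both are accurate
    to better than 1e-12, whereas much below that the direct form loses
    digits to cancellation.
    """
    a_plus_c = np.asarray(a_plus_c, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(a_plus_c < 0) or np.any(t < 0):
        raise ValidationError("a_plus_c and t must be >= 0")
    x = a_plus_c * t
    with np.errstate(divide="ignore", invalid="ignore"):
        direct = 2.0 * (x + np.expm1(-x)) / np.square(x)
    series = 1.0 - x / 3.0 + np.square(x) / 12.0 - x ** 3 / 60.0
    out = np.where(x < _F_SERIES_SWITCH, series, direct)
    return out if out.ndim else float(out)


def w_te_continuous(te: TEParams, gamma: float, dose, t) -> float:
    """Lethal lesions from targeted effects for constant-rate delivery.

    ``dose`` is the total absorbed dose (Gy) delivered over ``t`` hours;
    ``t = 0`` is the acute limit (F = 1).
    """
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValidationError("dose must be >= 0")
    f = lea_catcheside_f(te.a_plus_c, t)
    out = (te.alpha0 + gamma * te.beta0) * dose + f * te.beta0 * np.square(dose)
    return out if out.ndim else float(out)


def w_te_schedule(te: TEParams, gamma: float, disc: DiscretizedSchedule) -> float:
    """Targeted-effect lethal lesions for a discretized schedule.

    Evaluates the N-fraction double sum in O(N) by carrying the running
    exponentially-decayed dose history r_m = sum_{n<m} d_n q^(m-n) with
    q = exp(-(a+c) dT), via a first-order linear filter.
    """
    d = disc.segment_doses
    q = math.exp(-min(te.a_plus_c * disc.delta_t, _EXP_CLIP))
    history = lfilter([0.0, q], [1.0, -q], d)
    cross = 2.0 * te.beta0 * float(np.dot(d, history))
    return (
        (te.alpha0 + gamma * te.beta0) * float(d.sum())
        + te.beta0 * float(np.dot(d, d))
        + cross
    )


def _trim_idle_ends(schedule: DeliverySchedule) -> DeliverySchedule | None:
    """Drop zero-dose-rate segments at either end of the schedule.

    Beam-off time before the first or after the last delivered dose does
    not enter the lesion sum, so trimming it makes results exactly
    invariant to zero-dose padding (and shrinks the grid that must
    resolve the active part).  Returns None for an all-zero schedule.
    """
    segs = list(schedule.segments)
    while segs and segs[0].dose_rate == 0.0:
        segs.pop(0)
    while segs and segs[-1].dose_rate == 0.0:
        segs.pop()
    if not segs:
        return None
    return DeliverySchedule(tuple(segs), schedule.label)


def w_te_schedule_adaptive(te: TEParams, gamma: float,
                           schedule: DeliverySchedule, *,
                           rtol: float = 1e-6,
                           max_steps: int = 2 ** 20) -> float:
    """Discretized w_T refined by doubling N until it stops moving.

    N runs over powers of two; refinement stops when successive values
    agree to ``rtol`` relative, or at ``max_steps``.
    """
    trimmed = _trim_idle_ends(schedule)
    if trimmed is None:
        return 0.0
    schedule = trimmed
    n = 1
    prev = w_te_schedule(te, gamma, discretize(schedule, n))
    while n < max_steps:
        n *= 2
        cur = w_te_schedule(te, gamma, discretize(schedule, n))
        if abs(cur - prev) <= rtol * max(abs(cur), 1e-300):
            return cur
        prev = cur
    return prev


# --- non-targeted effects ---------------------------------------------------

def hit_fraction(nte: NTEParams, gamma: float, dose):
    """Probability f_h(D) that a cell has >= 1 activated signal-emitting target.

    Depends on cumulative absorbed dose only, irrespective of how the dose
    was fractionated in time.
    """
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValidationError("dose must be >= 0")
    exponent = (nte.alpha_b + gamma * nte.beta_b) * dose + nte.beta_b * np.square(dose)
    out = -np.expm1(-np.clip(exponent, 0.0, _EXP_CLIP))
    return out if out.ndim else float(out)


def w_nte(nte: NTEParams, field: FieldConfig, d_if, region: str):
    """Signal-mediated lethal lesions w_NT = delta * f_h(D_IF) * f_b(D_region).

    Hit cells anywhere in the flask emit signals; only the non-hit cells
    of the scored region can be killed by them, so w_NT is bounded by
    delta.  ``d_if`` is the dose delivered to the irradiated area.
    """
    gamma_r, d_region = field.region_gamma_dose(np.asarray(d_if, dtype=float), region)
    f_h = hit_fraction(nte, field.gamma_if, d_if)
    f_b = 1.0 - np.asarray(hit_fraction(nte, gamma_r, d_region))
    out = nte.delta * np.asarray(f_h) * f_b
    return out if out.ndim else float(out)


# --- combined survival ------------------------------------------------------

def lesion_load(te: TEParams, nte: NTEParams, field: FieldConfig,
                schedule: DeliverySchedule, region: str, *,
                rtol: float = 1e-6) -> LesionLoad:
    """Combined TE + NTE lethal-lesion load for one exposure region.

    Out-of-field cells receive the schedule scaled by the scatter fraction
    as direct dose; the NTE term uses the cumulative in-field dose.
    """
    gamma_r, _ = field.region_gamma_dose(schedule.total_dose, region)
    direct = schedule if region != "out_of_field" else schedule.scaled(field.scatter_fraction)
    if direct.total_dose == 0.0:
        w_t = 0.0
    else:
        w_t = w_te_schedule_adaptive(te, gamma_r, direct, rtol=rtol)
    w_nt = float(w_nte(nte, field, schedule.total_dose, region))
    return LesionLoad(w_t=w_t, w_nt=w_nt)


def survival(te: TEParams, nte: NTEParams, field: FieldConfig,
             schedule: DeliverySchedule, region: str, *,
             rtol: float = 1e-6) -> float:
    """Surviving fraction S = exp(-w_T - w_NT) in (0, 1]."""
    return lesion_load(te, nte, field, schedule, region, rtol=rtol).survival


def survival_acute(te: TEParams, nte: NTEParams, field: FieldConfig,
                   dose, region: str):
    """Closed-form survival for an acute exposure (F = 1); vectorized in dose."""
    dose = np.asarray(dose, dtype=float)
    gamma_r, d_region = field.region_gamma_dose(dose, region)
    w_t = w_te_continuous(te, gamma_r, d_region, 0.0)
    w = np.asarray(w_t) + np.asarray(w_nte(nte, field, dose, region))
    out = np.exp(-np.clip(w, -_EXP_CLIP, _EXP_CLIP))
    return out if out.ndim else float(out)


def migration_adjusted_survival(mig: MigrationModel, s_if) -> float:
    """Scored survival when a fraction f_move of colonies are immigrants.

    S = (1 - f_move) S_IF + f_move S_M: a convex combination whose
    high-dose asymptote is f_move * S_M.
    """
    s_if = np.asarray(s_if, dtype=float)
    if np.any(s_if <= 0) or np.any(s_if > 1):
        raise ValidationError("s_if must lie in (0, 1]")
    out = (1.0 - mig.f_move) * s_if + mig.f_move * mig.s_m
    return out if out.ndim else float(out)


def scale_by_damage_yield(te: TEParams, scaling: DamageScaling) -> TEParams:
    """Rescale TE coefficients for a changed initial lesion yield per Gy.

    alpha0 is proportional to the yield k and beta0 to k^2 (the linear
    term counts single lesions, the quadratic term lesion pairs), so a
    yield ratio k' / k maps (alpha0, beta0) -> (k_ratio * alpha0,
    k_ratio^2 * beta0) with the repair kinetics (a+c) untouched.
    """
    return TEParams(
        alpha0=te.alpha0 * scaling.k_ratio,
        beta0=te.beta0 * scaling.k_ratio ** 2,
        a_plus_c=te.a_plus_c,
    )
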