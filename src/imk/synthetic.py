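"""Synthetic clonogenic-survival data with the model's error structure.

The generator emulates the three experiment families of the reference
design — single-dose dose-response curves, split-dose (2 Gy + 2 Gy)
recovery curves, and four pulsed regimens delivering 4 Gy at average
rates of 0.59/0.2/0.1/0.05 Gy/min — for two cell lines under half-field
(A_IF = 0.5) or uniform (A_IF = 1.0) geometry.

Noise model: replicate-level additive Gaussian noise on -ln S with a
configurable standard deviation (default 0.1), matching the Gaussian
-lnS error assumed by the inference module.  Each record stores
exp(-mean of replicate -lnS values) as the surviving fraction and the
standard error of the replicate survivals as ``sd``.  The zero-dose
point is the normalization control and is recorded as exactly 1.  An
optional colony-count mode replaces the Gaussian draw with Poisson
colony statistics.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import presets
from .datasets import RecoveryCurve, SurvivalDataset, SURVIVAL_COLUMNS
from .errors import ValidationError
from .model import (
    FieldConfig, NTEParams, TEParams,
    survival as schedule_survival, survival_acute, w_nte, w_te_continuous,
)
from .schedules import DEFAULT_REGIMENS, make_split, regimen_schedule

__all__ = [
    "DEFAULT_DOSES", "DEFAULT_TAUS", "GeneratorConfig",
    "generate_dose_response", "generate_recovery_curve",
    "generate_doserate_regimen_dataset", "noiseless_recovery_curve",
]

DEFAULT_DOSES = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0)
DEFAULT_TAUS = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 24.0, 48.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic experiment.

    ``a_if`` selects the geometry: 0.5 yields in-field and out-of-field
    records, 1.0 yields uniform-field records; ``regions`` overrides that
    mapping explicitly.  ``te_condition`` forces one TE parameter set
    (``"half_field"`` or ``"uniform"``) for every region instead of the
    geometry-matched one — useful for controlled recovery experiments.
    """

    seed: int
    cell_line: str = "AGO1522"
    a_if: float = 0.5
    noise_sd: float = 0.1          # sd of Gaussian noise on -lnS per replicate
    n_replicates: int = 3
    doses: tuple[float, ...] = DEFAULT_DOSES
    taus: tuple[float, ...] = DEFAULT_TAUS
    regimens: tuple[str, ...] = tuple(DEFAULT_REGIMENS)
    regimen_total_dose: float = 4.0
    split_d1: float = 2.0
    split_d2: float = 2.0
    idealized: bool = True
    scatter_fraction: float = 0.0
    regions: tuple[str, ...] | None = None
    te_condition: str | None = None
    te_override: TEParams | None = None
    nte_override: NTEParams | None = None
    colony_mode: bool = False
    cells_plated: int = 500

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if any(d < 0 for d in self.doses):
            raise ValidationError("doses must be >= 0")

    @property
    def field(self) -> FieldConfig:
        return FieldConfig(a_if=self.a_if, scatter_fraction=self.scatter_fraction)

    @property
    def active_regions(self) -> tuple[str, ...]:
        if self.regions is not None:
            return self.regions
        return ("in_field", "out_of_field") if self.a_if < 1.0 else ("uniform",)

    def te_for_region(self, region: str) -> TEParams:
        if self.te_override is not None:
            return self.te_override
        condition = self.te_condition
        if condition is None:
            condition = "uniform" if region == "uniform" else "half_field"
        return presets.te_params(self.cell_line, condition,
                                 idealized=self.idealized)

    @property
    def nte(self) -> NTEParams:
        if self.nte_override is not None:
            return self.nte_override
        return presets.nte_params(self.cell_line)


def _observe(rng: np.random.Generator, s_true: float,
             config: GeneratorConfig) -> tuple[float, float]:
    """One recorded (surviving_fraction, sd) point from the noise model."""
    n = config.n_replicates
    if config.colony_mode:
        expected = s_true * config.cells_plated
        colonies = rng.poisson(expected, size=n)
        s_rep = np.maximum(colonies, 0.5) / config.cells_plated  # keep S > 0
        s_rep = np.minimum(s_rep, 1.0)
    elif config.noise_sd == 0.0:
        return s_true, 0.0
    else:
        w_true = -np.log(s_true)
        w_rep = np.maximum(rng.normal(w_true, config.noise_sd, size=n), 0.0)
        s_rep = np.exp(-w_rep)
    s_obs = float(np.exp(-np.mean(-np.log(s_rep))))
    sd = float(np.std(s_rep, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return s_obs, sd


def generate_dose_response(config: GeneratorConfig) -> SurvivalDataset:
    """Single acute-exposure dose-response records per dose and region."""
    rng = np.random.default_rng(config.seed)
    fieldcfg = config.field
    rows = []
    for region in config.active_regions:
        te = config.te_for_region(region)
        for dose in config.doses:
            s_true = survival_acute(te, config.nte, fieldcfg, dose, region)
            if dose == 0.0:
                s_obs, sd = 1.0, 0.0
            else:
                s_obs, sd = _observe(rng, s_true, config)
            rows.append(("dose_response", "acute", region, dose,
                         s_obs, sd, config.n_replicates))
    return SurvivalDataset(pd.DataFrame(rows, columns=SURVIVAL_COLUMNS))


def _split_true_survival(te: TEParams, nte: NTEParams, fieldcfg: FieldConfig,
                         d1: float, d2: float, tau: float, region: str) -> float:
    """Closed-form split-dose survival for two acute fractions."""
    gamma_r, _ = fieldcfg.region_gamma_dose(d1 + d2, region)
    scatter = fieldcfg.scatter_fraction if region == "out_of_field" else 1.0
    e1, e2 = d1 * scatter, d2 * scatter
    w_t = (
        w_te_continuous(te, gamma_r, e1, 0.0)
        + w_te_continuous(te, gamma_r, e2, 0.0)
        + 2.0 * te.beta0 * e1 * e2 * np.exp(-te.a_plus_c * tau)
    )
    w_nt = w_nte(nte, fieldcfg, d1 + d2, region)
    return float(np.exp(-(w_t + w_nt)))


def generate_recovery_curve(config: GeneratorConfig) -> dict[str, RecoveryCurve]:
    """Split-dose recovery curves over the tau grid, one per active region."""
    rng = np.random.default_rng(config.seed)
    fieldcfg = config.field
    out: dict[str, RecoveryCurve] = {}
    for region in config.active_regions:
        te = config.te_for_region(region)
        surv, sds = [], []
        for tau in config.taus:
            s_true = _split_true_survival(
                te, config.nte, fieldcfg,
                config.split_d1, config.split_d2, tau, region,
            )
            s_obs, sd = _observe(rng, s_true, config)
            surv.append(s_obs)
            sds.append(sd)
        out[region] = RecoveryCurve(
            d1=config.split_d1, d2=config.split_d2,
            tau=np.asarray(config.taus), survival=np.asarray(surv),
            sd=np.asarray(sds), n_replicates=config.n_replicates,
            label=f"{config.cell_line} {region} split-dose",
        )
    return out


def generate_doserate_regimen_dataset(config: GeneratorConfig) -> SurvivalDataset:
    """One record per pulsed dose-rate regimen and region (4 Gy total)."""
    rng = np.random.default_rng(config.seed)
    fieldcfg = config.field
    rows = []
    for name in config.regimens:
        sched = regimen_schedule(name, total_dose=config.regimen_total_dose)
        for region in config.active_regions:
            te = config.te_for_region(region)
            s_true = schedule_survival(te, config.nte, fieldcfg, sched, region)
            s_obs, sd = _observe(rng, s_true, config)
            rows.append(("dose_rate_regimens", name, region,
                         sched.total_dose, s_obs, sd, config.n_replicates))
    return SurvivalDataset(pd.DataFrame(rows, columns=SURVIVAL_COLUMNS))


def noiseless_recovery_curve(te: TEParams, nte: NTEParams,
                             fieldcfg: FieldConfig, *,
                             region: str = "in_field",
                             taus=DEFAULT_TAUS,
                             d1: float = 2.0, d2: float = 2.0,
                             engine: str = "schedule",
                             rtol: float = 1e-9) -> RecoveryCurve:
    """Deterministic model-generated recovery curve (no noise).

    ``engine="schedule"`` runs each split schedule through the discretized
    fractionation sum (the general path, refined to ``rtol``);
    ``engine="closed_form"`` uses the two-impulse algebraic expression.
    The tight default tolerance matters when the curve feeds the fine-step
    slope estimator, which differences survivals across tiny tau.
    """
    taus = np.asarray(taus, dtype=float)
    surv = []
    for tau in taus:
        if engine == "closed_form":
            s = _split_true_survival(te, nte, fieldcfg, d1, d2, float(tau), region)
        elif engine == "schedule":
            sched = make_split(d1, d2, float(tau))
            s = schedule_survival(te, nte, fieldcfg, sched, region, rtol=rtol)
        else:
            raise ValidationError(f"unknown engine {engine!r}")
        surv.append(s)
    return RecoveryCurve(d1=d1, d2=d2, tau=taus, survival=np.asarray(surv),
                         label=f"noiseless {region} split-dose")
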