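"""In-memory containers for clonogenic-survival data.

Survival datasets are thin wrappers around a pandas DataFrame with a fixed
column set; recovery curves hold the split-dose design explicitly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Column order of the survival-record table / CSV dialect.
SURVIVAL_COLUMNS = (
    "experiment_id", "schedule_label", "region", "dose_Gy",
    "surviving_fraction", "sd", "n_replicates",
)


@dataclass
class SurvivalDataset:
    """Clonogenic survival records, one row per (schedule, region, dose) point.

    ``sd`` is the standard error of the recorded surviving fraction (the
    replicate standard deviation divided by sqrt(n_replicates)); it is the
    sigma_exp entering chi-squared and, scaled by 1/S, the -lnS likelihood.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records).reset_index(drop=True)
        missing = [c for c in SURVIVAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"survival dataset missing columns: {missing}")
        self.records = df.loc[:, list(SURVIVAL_COLUMNS)]
        sf = self.records["surviving_fraction"].to_numpy(dtype=float)
        if np.any(~np.isfinite(sf)) or np.any(sf <= 0) or np.any(sf > 1):
            bad = self.records.index[(sf <= 0) | (sf > 1) | ~np.isfinite(sf)].tolist()
            raise ValidationError(
                f"surviving_fraction must lie in (0, 1]; bad rows: {bad}"
            )
        if np.any(self.records["sd"].to_numpy(dtype=float) < 0):
            raise ValidationError("sd must be >= 0")
        if np.any(self.records["dose_Gy"].to_numpy(dtype=float) < 0):
            raise ValidationError("dose_Gy must be >= 0")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, **equals) -> "SurvivalDataset":
        """Rows where every given column equals the given value."""
        mask = pd.Series(True, index=self.records.index)
        for col, val in equals.items():
            mask &= self.records[col] == val
        return SurvivalDataset(self.records[mask])

    def concat(self, other: "SurvivalDataset") -> "SurvivalDataset":
        return SurvivalDataset(
            pd.concat([self.records, other.records], ignore_index=True)
        )


@dataclass
class RecoveryCurve:
    """Split-dose recovery curve: survival vs inter-fraction time tau.

    Two fractions of ``d1`` and ``d2`` Gy are separated by each ``tau``;
    the curve rises from S(0) to the plateau S(inf) as sub-lethal damage
    accrued in the first fraction is repaired before the second.
    """

    d1: float
    d2: float
    tau: np.ndarray
    survival: np.ndarray
    sd: np.ndarray | None = None
    n_replicates: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.tau.shape or np.any(self.sd < 0):
                raise ValidationError("sd must match tau and be >= 0")
        if self.d1 < 0 or self.d2 < 0:
            raise ValidationError("fraction doses must be >= 0")
        if self.tau.ndim != 1 or self.tau.shape != self.survival.shape:
            raise ValidationError("tau and survival must be equal-length 1-D arrays")
        if np.any(self.tau < 0) or np.any(np.diff(self.tau) <= 0):
            raise ValidationError("tau values must be >= 0 and strictly increasing")
        if np.any(self.survival <= 0) or np.any(self.survival > 1):
            raise ValidationError("survival values must lie in (0, 1]")

    def survival_at(self, tau: float, *, atol: float = 1e-12) -> float:
        """Survival at an exactly sampled tau (no interpolation)."""
        idx = np.flatnonzero(np.isclose(self.tau, tau, rtol=0.0, atol=atol))
        if idx.size == 0:
            raise ValidationError(
                f"tau={tau} h not sampled; available: {self.tau.tolist()}"
            )
        return float(self.survival[idx[0]])
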