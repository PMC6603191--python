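"""File formats: survival/recovery CSVs, schedule and parameter YAML, manifests.

CSV dialect: comma-separated, UTF-8, "." decimal, mandatory header row,
metadata as ``# key=value`` comment lines before the header.  Doses are
Gy, times hours throughout.
"""
from __future__ import annotations

import json
from dataclasses import asdict
from io import StringIO
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import RecoveryCurve, SurvivalDataset, SURVIVAL_COLUMNS
from .errors import ParseError
from .model import NTEParams, TEParams
from .schedules import DeliverySchedule, DeliverySegment
from .sldr import SldrEstimate

__all__ = [
    "read_survival_csv", "write_survival_csv",
    "read_recovery_csv", "write_recovery_csv",
    "schedule_to_dict", "schedule_from_dict",
    "read_schedule_yaml", "write_schedule_yaml",
    "read_parameter_file", "packaged_parameter_file",
    "write_sldr_report", "write_manifest",
]


def _read_csv_lines(path) -> tuple[pd.DataFrame, dict[str, str], list[int]]:
    """Parse a CSV with ``# key=value`` metadata; return (df, meta, line numbers).

    The returned line numbers map data rows (header first) back to the
    physical file for error messages.
    """
    meta: dict[str, str] = {}
    data_lines: list[str] = []
    line_nums: list[int] = []
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    for i, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            key, sep, val = s.lstrip("#").strip().partition("=")
            if sep:
                meta[key.strip()] = val.strip()
            continue
        data_lines.append(line)
        line_nums.append(i)
    if len(data_lines) < 1:
        raise ParseError(f"{path}: no header row found")
    try:
        df = pd.read_csv(StringIO("\n".join(data_lines)))
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise ParseError(f"{path}: malformed CSV ({exc})") from exc
    return df, meta, line_nums


def _require_numeric(df: pd.DataFrame, columns, line_nums, path) -> pd.DataFrame:
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()].tolist()
        if bad or coerced.isna().any():
            bad_rows = df.index[coerced.isna()].tolist()
            lines = [line_nums[r + 1] for r in bad_rows]
            raise ParseError(f"{path}: non-numeric {col!r} on line(s) {lines}")
        df[col] = coerced
    return df


def read_survival_csv(path) -> SurvivalDataset:
    """Read the survival CSV dialect into a validated dataset.

    Rows whose surviving fraction lies outside (0, 1] are rejected with a
    ParseError naming the physical line numbers.
    """
    df, _, line_nums = _read_csv_lines(path)
    missing = [c for c in SURVIVAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: header missing column(s) {missing}")
    df = _require_numeric(df, ["dose_Gy", "surviving_fraction", "sd", "n_replicates"],
                          line_nums, path)
    sf = df["surviving_fraction"].to_numpy(dtype=float)
    bad = df.index[(sf <= 0) | (sf > 1) | ~np.isfinite(sf)].tolist()
    if bad:
        lines = [line_nums[r + 1] for r in bad]
        raise ParseError(
            f"{path}: surviving_fraction outside (0, 1] on line(s) {lines}"
        )
    return SurvivalDataset(df)


def write_survival_csv(dataset: SurvivalDataset, path, *,
                       metadata: dict | None = None) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}={val}\n")
        dataset.records.to_csv(fh, index=False)


def read_recovery_csv(path) -> RecoveryCurve:
    """Read a split-dose recovery CSV (columns tau_h, surviving_fraction,
    sd, n_replicates; fraction doses in ``# d1_Gy=`` / ``# d2_Gy=`` metadata)."""
    df, meta, line_nums = _read_csv_lines(path)
    for key in ("d1_Gy", "d2_Gy"):
        if key not in meta:
            raise ParseError(f"{path}: missing '# {key}=' metadata line")
    required = ["tau_h", "surviving_fraction"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: header missing column(s) {missing}")
    numeric = [c for c in ("tau_h", "surviving_fraction", "sd", "n_replicates")
               if c in df.columns]
    df = _require_numeric(df, numeric, line_nums, path)
    sf = df["surviving_fraction"].to_numpy(dtype=float)
    bad = df.index[(sf <= 0) | (sf > 1) | ~np.isfinite(sf)].tolist()
    if bad:
        lines = [line_nums[r + 1] for r in bad]
        raise ParseError(
            f"{path}: surviving_fraction outside (0, 1] on line(s) {lines}"
        )
    n_rep = int(df["n_replicates"].iloc[0]) if "n_replicates" in df.columns else 1
    return RecoveryCurve(
        d1=float(meta["d1_Gy"]), d2=float(meta["d2_Gy"]),
        tau=df["tau_h"].to_numpy(dtype=float),
        survival=sf,
        sd=df["sd"].to_numpy(dtype=float) if "sd" in df.columns else None,
        n_replicates=n_rep,
        label=meta.get("label", ""),
    )


def write_recovery_csv(curve: RecoveryCurve, path) -> None:
    path = Path(path)
    df = pd.DataFrame({
        "tau_h": curve.tau,
        "surviving_fraction": curve.survival,
        "sd": curve.sd if curve.sd is not None else np.zeros_like(curve.tau),
        "n_replicates": curve.n_replicates,
    })
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# d1_Gy={curve.d1!r}\n# d2_Gy={curve.d2!r}\n")
        if curve.label:
            fh.write(f"# label={curve.label}\n")
        df.to_csv(fh, index=False)


# --- schedules --------------------------------------------------------------

def schedule_to_dict(schedule: DeliverySchedule) -> dict:
    return {
        "label": schedule.label,
        "segments": [
            {"start_h": s.start_time, "duration_h": s.duration,
             "dose_rate_Gy_per_h": s.dose_rate}
            for s in schedule.segments
        ],
    }


def schedule_from_dict(payload: dict) -> DeliverySchedule:
    try:
        segments = tuple(
            DeliverySegment(
                start_time=float(seg["start_h"]),
                duration=float(seg["duration_h"]),
                dose_rate=float(seg["dose_rate_Gy_per_h"]),
            )
            for seg in payload["segments"]
        )
    except (KeyError, TypeError) as exc:
        raise ParseError(f"malformed schedule mapping: {exc}") from exc
    return DeliverySchedule(segments, str(payload.get("label", "")))


def read_schedule_yaml(path) -> DeliverySchedule:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict):
        raise ParseError(f"{path}: expected a mapping with 'segments'")
    return schedule_from_dict(payload)


def write_schedule_yaml(schedule: DeliverySchedule, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(schedule_to_dict(schedule), fh, sort_keys=False)


# --- parameter files --------------------------------------------------------

def packaged_parameter_file():
    """Path-like handle to the parameter file shipped with the package."""
    return resources.files("imk.data") / "parameters.yaml"


def read_parameter_file(path=None) -> dict[str, dict]:
    """Cell-line parameter mapping -> {cell: {half_field/uniform: TEParams, nte: NTEParams}}."""
    source = packaged_parameter_file() if path is None else Path(path)
    payload = yaml.safe_load(source.read_text(encoding="utf-8"))
    if not isinstance(payload, dict):
        raise ParseError("parameter file must be a mapping of cell lines")
    out: dict[str, dict] = {}
    for cell, sections in payload.items():
        entry: dict[str, object] = {}
        for section, values in sections.items():
            try:
                if section == "nte":
                    entry["nte"] = NTEParams(**values)
                else:
                    entry[section] = TEParams(**values)
            except TypeError as exc:
                raise ParseError(
                    f"parameter file: bad section {cell}/{section}: {exc}"
                ) from exc
        out[str(cell)] = entry
    return out


# --- reports & manifests ----------------------------------------------------

def write_sldr_report(estimates: dict[str, SldrEstimate], path) -> None:
    """One row per curve: the split-dose estimates and their inputs."""
    rows = []
    for name, est in estimates.items():
        row = {"curve": name, **asdict(est)}
        row["window"] = f"({est.window[0]}, {est.window[1]}]"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_manifest(path, *, seed: int | None, command: str,
                   config: dict) -> None:
    """Record the exact configuration and seed behind an output artifact."""
    payload = {"command": command, "seed": seed, "config": config}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n",
                          encoding="utf-8")
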