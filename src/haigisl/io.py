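"""Cohort CSV I/O and run configuration.

The cohort interchange format is a plain CSV with a mandatory header, `.`
decimal points, empty cells for missing values, and units fixed by the
column names.  Unknown columns are preserved untouched (tolerant reader).
The ``true_pe_d`` column exists only on synthetic cohorts: it is the
generator's injected error, never a measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import SchemaError
from .formulas import EyeBiometry, PEModel, SurgeryCase
from .optics import IOLConstants, OpticalConfig

REQUIRED_COLUMNS = ("eye_id", "axial_length_mm", "acd_mm", "mean_corneal_radius_mm")
OPTIONAL_COLUMNS = (
    "sa8_um",
    "sa6_um",
    "q6",
    "q8",
    "ecc6",
    "ecc8",
    "implanted_power_d",
    "postop_se_d",
    "true_pe_d",
)
NUMERIC_COLUMNS = REQUIRED_COLUMNS[1:] + OPTIONAL_COLUMNS


def read_cohort(path: Union[str, Path]) -> pd.DataFrame:
    """Read a cohort CSV, validating schema and numeric cells.

    Raises SchemaError naming the first missing required column, or naming
    the column and 1-based file line of the first unparseable cell.
    """
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"cohort file {path} is missing required column {col!r}")
    for col in table.columns:
        if col not in NUMERIC_COLUMNS:
            continue
        raw = table[col].str.strip()
        vals = pd.to_numeric(raw.mask(raw == ""), errors="coerce")
        bad = vals.isna() & (raw != "")
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"column {col!r}, line {idx + 2}: cannot parse {raw.iloc[idx]!r} as a number"
            )
        table[col] = vals
    return table


def write_cohort(table: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a cohort table as CSV, preserving numeric values to full precision."""
    table.to_csv(path, index=False, float_format="%.12g")


def cases_to_table(cases: Sequence[SurgeryCase]) -> pd.DataFrame:
    """Flatten surgery cases into the cohort CSV schema."""
    rows = []
    for c in cases:
        b = c.biometry
        rows.append(
            {
                "eye_id": c.eye_id,
                "axial_length_mm": b.axial_length,
                "acd_mm": b.acd,
                "mean_corneal_radius_mm": b.mean_corneal_radius,
                "sa8_um": b.sa8,
                "sa6_um": b.sa6,
                "q6": b.q6,
                "q8": b.q8,
                "ecc6": b.ecc6,
                "ecc8": b.ecc8,
                "implanted_power_d": c.implanted_power,
                "postop_se_d": c.postop_se,
                "true_pe_d": c.true_pe,
            }
        )
    cols = list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS)
    return pd.DataFrame(rows, columns=cols)


def _opt(row: pd.Series, col: str) -> Optional[float]:
    if col not in row.index:
        return None
    v = row[col]
    return None if pd.isna(v) else float(v)


def table_to_cases(table: pd.DataFrame) -> list[SurgeryCase]:
    """Build surgery cases from a validated cohort table."""
    cases = []
    for _, row in table.iterrows():
        biometry = EyeBiometry(
            axial_length=float(row["axial_length_mm"]),
            acd=float(row["acd_mm"]),
            mean_corneal_radius=float(row["mean_corneal_radius_mm"]),
            sa8=_opt(row, "sa8_um"),
            sa6=_opt(row, "sa6_um"),
            q6=_opt(row, "q6"),
            q8=_opt(row, "q8"),
            ecc6=_opt(row, "ecc6"),
            ecc8=_opt(row, "ecc8"),
        )
        cases.append(
            SurgeryCase(
                eye_id=str(row["eye_id"]),
                biometry=biometry,
                implanted_power=_opt(row, "implanted_power_d"),
                postop_se=_opt(row, "postop_se_d"),
                true_pe=_opt(row, "true_pe_d"),
            )
        )
    return cases


@dataclass(frozen=True)
class RunConfig:
    """Flat run configuration; the documented defaults reproduce the
    published formulas bit-exactly."""

    a0: float = -1.302
    a1: float = 0.210
    a2: float = 0.251
    vertex_distance_mm: float = 12.0
    keratometric_index: float = 1.3315
    pe_slope: float = 0.583
    pe_intercept: float = -2.3488
    round_step: Optional[float] = None  # display rounding of IOL power, e.g. 0.5

    def iol_constants(self) -> IOLConstants:
        return IOLConstants(self.a0, self.a1, self.a2)

    def optical_config(self) -> OpticalConfig:
        return OpticalConfig(self.vertex_distance_mm, self.keratometric_index)

    def pe_model(self) -> PEModel:
        return PEModel(self.pe_slope, self.pe_intercept)


def read_config(path: Union[str, Path]) -> RunConfig:
    """Read a flat ``key = value`` config file; unknown keys are rejected."""
    known = {f.name for f in dc_fields(RunConfig)}
    values: dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise SchemaError(f"config {path}, line {lineno}: expected key = value")
        key, _, raw = line.partition("=")
        key = key.strip()
        if key not in known:
            raise SchemaError(f"config {path}, line {lineno}: unknown key {key!r}")
        try:
            values[key] = float(raw.strip())
        except ValueError as exc:
            raise SchemaError(f"config {path}, line {lineno}: {exc}") from None
    return RunConfig(**values)


def write_config(config: RunConfig, path: Union[str, Path]) -> None:
    lines = []
    for f in dc_fields(RunConfig):
        v = getattr(config, f.name)
        if v is not None:
            lines.append(f"{f.name} = {v!r}")
    Path(path).write_text("\n".join(lines) + "\n")
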