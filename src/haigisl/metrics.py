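"""Refractive prediction-error summary statistics and formula comparison.

Conventions: SD is the n-1 sample standard deviation; quantiles interpolate
linearly between order statistics; the percentage-within thresholds count
|PE| equal to the threshold as within (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import formulas, optics
from .errors import MissingFieldError
from .formulas import PEModel, SurgeryCase


@dataclass(frozen=True)
class ErrorSummary:
    """Cohort-level prediction-error statistics, all in dioptres.

    ``sd`` and ``sd_ae`` are NaN for a single-case cohort, where a sample SD
    is undefined.
    """

    n: int
    me: float
    sd: float
    median_error: float
    mae: float
    sd_ae: float
    median_ae: float
    iqr: float
    pct_within_05: float
    pct_within_10: float
    pct_within_15: float


def summarize_errors(pe: Sequence[float]) -> ErrorSummary:
    """Summarise a series of prediction errors (observed minus predicted SE)."""
    arr = np.asarray(pe, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("pe must be a non-empty one-dimensional series")
    if np.any(~np.isfinite(arr)):
        raise ValueError("pe must be finite")
    ae = np.abs(arr)
    n = arr.size
    sd = float(np.std(arr, ddof=1)) if n >= 2 else float("nan")
    sd_ae = float(np.std(ae, ddof=1)) if n >= 2 else float("nan")
    q1, q3 = np.percentile(arr, [25, 75])
    return ErrorSummary(
        n=n,
        me=float(np.mean(arr)),
        sd=sd,
        median_error=float(np.median(arr)),
        mae=float(np.mean(ae)),
        sd_ae=sd_ae,
        median_ae=float(np.median(ae)),
        iqr=float(q3 - q1),
        pct_within_05=100.0 * float(np.mean(ae <= 0.5)),
        pct_within_10=100.0 * float(np.mean(ae <= 1.0)),
        pct_within_15=100.0 * float(np.mean(ae <= 1.5)),
    )


def prediction_errors(
    cases: Sequence[SurgeryCase],
    formula_id: str,
    constants: optics.IOLConstants = optics.ZCB00,
    config: optics.OpticalConfig = optics.OpticalConfig(),
    model: PEModel = PEModel(),
) -> np.ndarray:
    """Per-case prediction errors under one formula variant."""
    pe = []
    for case in cases:
        pred = formulas.predict_case(case, formula_id, constants, config, model)
        if pred.pe is None:
            raise MissingFieldError(f"case {case.eye_id}: postop_se is required")
        pe.append(pred.pe)
    return np.asarray(pe, dtype=float)


def compare_formulas(
    cases: Sequence[SurgeryCase],
    formula_ids: Sequence[str] = ("haigis-l", "modified-haigis-l"),
    constants: optics.IOLConstants = optics.ZCB00,
    config: optics.OpticalConfig = optics.OpticalConfig(),
    model: PEModel = PEModel(),
) -> dict[str, ErrorSummary]:
    """One ErrorSummary per requested formula, on the same cohort."""
    return {
        fid: summarize_errors(prediction_errors(cases, fid, constants, config, model))
        for fid in formula_ids
    }


def summary_table(summaries: dict[str, ErrorSummary]) -> pd.DataFrame:
    """Comparison report: one row per statistic, one column per formula."""
    rows = [
        ("Eyes", lambda s: s.n),
        ("ME (D)", lambda s: s.me),
        ("SD of ME (D)", lambda s: s.sd),
        ("Median error (D)", lambda s: s.median_error),
        ("MAE (D)", lambda s: s.mae),
        ("SD of AE (D)", lambda s: s.sd_ae),
        ("Median absolute error (D)", lambda s: s.median_ae),
        ("Interquartile range (D)", lambda s: s.iqr),
        ("Within 0.5 D (%)", lambda s: s.pct_within_05),
        ("Within 1.0 D (%)", lambda s: s.pct_within_10),
        ("Within 1.5 D (%)", lambda s: s.pct_within_15),
    ]
    data = {fid: [fn(s) for _, fn in rows] for fid, s in summaries.items()}
    return pd.DataFrame(data, index=[name for name, _ in rows])
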