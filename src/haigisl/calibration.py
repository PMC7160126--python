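"""Deriving the SA correction from data.

Given a training cohort with implanted powers and observed postoperative
refractions, the Haigis-L prediction error per eye is regressed on the
anterior-corneal spherical aberration at 8.0 mm, yielding the coefficients
of the correction applied by the modified formula.  A Pearson screen over
all candidate biometric predictors reproduces the model-selection step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import formulas, optics
from .errors import DegenerateSeriesError
from .formulas import PEModel, SurgeryCase

#: Candidate predictors screened against the prediction error, keyed by the
#: EyeBiometry attribute that holds them.
PREDICTOR_FIELDS = {
    "AL": "axial_length",
    "ACD": "acd",
    "r": "mean_corneal_radius",
    "Q6": "q6",
    "Q8": "q8",
    "SA6": "sa6",
    "SA8": "sa8",
    "ecc6": "ecc6",
    "ecc8": "ecc8",
}


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of prediction error on a single predictor."""

    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int


def _as_clean_array(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-test p-value (n-2 df)."""
    xa, ya = _as_clean_array(x, "x"), _as_clean_array(y, "y")
    if len(xa) != len(ya):
        raise ValueError("x and y must have equal length")
    if len(xa) < 3:
        raise DegenerateSeriesError(f"need at least 3 points, got {len(xa)}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise DegenerateSeriesError("constant series has undefined correlation")
    res = stats.pearsonr(xa, ya)
    return float(res.statistic), float(res.pvalue)


def fit_pe_regression(sa: Sequence[float], pe: Sequence[float]) -> RegressionFit:
    """OLS of prediction error on spherical aberration (normal equations)."""
    sa_a, pe_a = _as_clean_array(sa, "sa"), _as_clean_array(pe, "pe")
    if len(sa_a) != len(pe_a):
        raise ValueError("sa and pe must have equal length")
    if len(sa_a) < 3:
        raise DegenerateSeriesError(f"need at least 3 points, got {len(sa_a)}")
    if np.ptp(sa_a) == 0:
        raise DegenerateSeriesError("constant predictor cannot be regressed on")
    res = stats.linregress(sa_a, pe_a)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=len(sa_a),
    )


def correlate_predictors(
    cases: Sequence[SurgeryCase],
    pe: Sequence[float],
    predictors: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Pearson screen of biometric predictors against the prediction error.

    Returns one row per predictor with columns ``predictor``, ``r``, ``p``,
    ``degenerate``, sorted by |r| descending; degenerate predictors (constant
    or with missing values) are flagged rather than fatal and sort last.
    """
    pe_a = _as_clean_array(pe, "pe")
    if len(pe_a) != len(cases):
        raise ValueError("pe must align with cases")
    if np.any(~np.isfinite(pe_a)):
        raise ValueError("pe must be finite for every case")
    names = list(predictors) if predictors is not None else list(PREDICTOR_FIELDS)
    rows = []
    for name in names:
        attr = PREDICTOR_FIELDS[name]
        vals = [getattr(c.biometry, attr) for c in cases]
        try:
            if any(v is None for v in vals):
                raise DegenerateSeriesError(f"predictor {name} missing for some cases")
            r, p = pearson(vals, pe_a)
            rows.append({"predictor": name, "r": r, "p": p, "degenerate": False})
        except DegenerateSeriesError:
            rows.append(
                {"predictor": name, "r": np.nan, "p": np.nan, "degenerate": True}
            )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        "r", key=lambda s: s.abs(), ascending=False, na_position="last"
    )
    return table.reset_index(drop=True)


def recalibrate(
    cases: Sequence[SurgeryCase],
    constants: optics.IOLConstants = optics.ZCB00,
    config: optics.OpticalConfig = optics.OpticalConfig(),
) -> tuple[PEModel, RegressionFit]:
    """Refit the SA correction on a training cohort.

    Computes the Haigis-L prediction error for every case, regresses it on
    SA8, and returns the fitted PEModel together with the fit diagnostics.
    The caller owns any training/test split; no held-out data are touched.
    """
    sa, pe = [], []
    for case in cases:
        pred = formulas.predict_case(case, "haigis-l", constants, config)
        if pred.pe is None:
            raise ValueError(f"case {case.eye_id}: postop_se is required to recalibrate")
        if case.biometry.sa8 is None:
            raise ValueError(f"case {case.eye_id}: sa8 is required to recalibrate")
        sa.append(case.biometry.sa8)
        pe.append(pred.pe)
    fit = fit_pe_regression(sa, pe)
    return PEModel(slope=fit.slope, intercept=fit.intercept), fit
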