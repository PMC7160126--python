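"""Corneal-power formulas and per-case refraction prediction.

Three formula variants share the same thin-lens chassis and differ only in
the effective corneal power Z they feed it:

``haigis``
    Keratometric power from the measured anterior radius,
    D = (n - 1) * 1000 / r.  Biased after myopic ablation, kept as the
    baseline comparator.
``haigis-l``
    Regression-corrected effective power for post-myopic-laser corneas,
    Z = -5.6125 * r + 82.2603 - 0.35.
``modified-haigis-l``
    Haigis-L power further corrected by the expected prediction error,
    itself a linear function of the anterior-corneal spherical aberration
    over the 8.0 mm zone:  Z' = Z - REFc(0.583 * SA8 - 2.3488).  A cornea
    made more oblate by a larger myopic ablation carries more positive SA8
    and would otherwise leave a hyperopic surprise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math
from typing import Optional

from . import optics
from .errors import MissingFieldError

FORMULA_IDS = ("haigis", "haigis-l", "modified-haigis-l")


@dataclass(frozen=True)
class EyeBiometry:
    """One eye's preoperative measurements.

    axial_length, acd, mean_corneal_radius in mm; spherical aberration
    (sa6, sa8) in µm over the stated zone diameter; Q-values and
    eccentricities dimensionless.  Optional fields default to None.
    """

    axial_length: float
    acd: float
    mean_corneal_radius: float
    sa8: Optional[float] = None
    sa6: Optional[float] = None
    q6: Optional[float] = None
    q8: Optional[float] = None
    ecc6: Optional[float] = None
    ecc8: Optional[float] = None

    def __post_init__(self) -> None:
        if not 15.0 < self.axial_length < 40.0:
            raise ValueError(f"axial_length {self.axial_length} mm outside (15, 40)")
        if not 1.5 < self.acd < 6.0:
            raise ValueError(f"acd {self.acd} mm outside (1.5, 6)")
        if not 6.0 < self.mean_corneal_radius < 12.0:
            raise ValueError(
                f"mean_corneal_radius {self.mean_corneal_radius} mm outside (6, 12)"
            )
        if self.sa8 is not None and not math.isfinite(self.sa8):
            raise ValueError("sa8 must be finite when present")


@dataclass(frozen=True)
class SurgeryCase:
    """Biometry plus the implanted IOL power and observed outcome.

    ``true_pe`` is generator bookkeeping on synthetic cohorts (the noise-free
    error injected at construction); it is absent in real data.
    """

    eye_id: str
    biometry: EyeBiometry
    implanted_power: Optional[float] = None
    postop_se: Optional[float] = None
    true_pe: Optional[float] = None


@dataclass(frozen=True)
class PEModel:
    """Linear model of Haigis-L prediction error on SA8: PE = slope*SA8 + intercept.

    Defaults are the published training-cohort regression coefficients
    (slope in D/µm, intercept in D).
    """

    slope: float = 0.583
    intercept: float = -2.3488

    def __post_init__(self) -> None:
        if not (math.isfinite(self.slope) and math.isfinite(self.intercept)):
            raise ValueError("PEModel coefficients must be finite")


@dataclass(frozen=True)
class Prediction:
    formula_id: str
    predicted_se: float
    pe: Optional[float] = None


def corneal_power_haigis_l(r: float) -> float:
    """Haigis-L effective equivalent corneal power: -5.6125*r + 82.2603 - 0.35.

    The regression corrects both the radius-measurement bias and the
    keratometric-index error on post-myopic-ablation corneas; the extra
    -0.35 D offsets the residual lens-position prediction error.
    """
    if not 6.0 < r < 12.0:
        raise ValueError(f"corneal radius {r} mm outside (6, 12)")
    return -5.6125 * r + 82.2603 - 0.35


def pe_from_sa(sa8: float, model: PEModel = PEModel()) -> float:
    """Expected Haigis-L prediction error (D, spectacle plane) at a given SA8."""
    if not math.isfinite(sa8):
        raise ValueError("sa8 must be finite")
    return model.slope * sa8 + model.intercept


def corneal_power_modified(
    r: float,
    sa8: float,
    vd: float = 12.0,
    model: PEModel = PEModel(),
) -> float:
    """SA-corrected effective corneal power Z'.

    The expected prediction error is moved from the spectacle plane to the
    corneal plane and subtracted from the Haigis-L power, so an expected
    hyperopic surprise (positive PE) lowers Z' and raises the computed IOL
    power.
    """
    pe = pe_from_sa(sa8, model)
    return corneal_power_haigis_l(r) - optics.spectacle_to_corneal(pe, vd)


def effective_corneal_power(
    biometry: EyeBiometry,
    formula_id: str,
    config: optics.OpticalConfig = optics.OpticalConfig(),
    model: PEModel = PEModel(),
) -> float:
    """Dispatch the effective corneal power Z for a formula variant."""
    if formula_id == "haigis":
        return optics.keratometric_power(
            biometry.mean_corneal_radius, config.keratometric_index
        )
    if formula_id == "haigis-l":
        return corneal_power_haigis_l(biometry.mean_corneal_radius)
    if formula_id == "modified-haigis-l":
        if biometry.sa8 is None:
            raise MissingFieldError(
                "sa8 (spherical aberration at 8.0 mm) is required by the "
                "modified Haigis-L formula"
            )
        return corneal_power_modified(
            biometry.mean_corneal_radius, biometry.sa8, config.vertex_distance, model
        )
    raise ValueError(f"unknown formula_id {formula_id!r}; expected one of {FORMULA_IDS}")


def iol_power(
    biometry: EyeBiometry,
    formula_id: str,
    target_se: float = 0.0,
    constants: optics.IOLConstants = optics.ZCB00,
    config: optics.OpticalConfig = optics.OpticalConfig(),
    model: PEModel = PEModel(),
) -> float:
    """IOL power for a target spectacle refraction under one formula variant."""
    z = effective_corneal_power(biometry, formula_id, config, model)
    elp = optics.elp_haigis(biometry.acd, biometry.axial_length, constants)
    return optics.iol_power_for_target(
        biometry.axial_length, elp, z, target_se, config.vertex_distance
    )


def predict_case(
    case: SurgeryCase,
    formula_id: str,
    constants: optics.IOLConstants = optics.ZCB00,
    config: optics.OpticalConfig = optics.OpticalConfig(),
    model: PEModel = PEModel(),
) -> Prediction:
    """Predicted spectacle refraction for the implanted power, plus the
    prediction error (observed minus predicted) when the outcome is known."""
    if case.implanted_power is None:
        raise MissingFieldError(f"case {case.eye_id}: implanted_power is required")
    z = effective_corneal_power(case.biometry, formula_id, config, model)
    elp = optics.elp_haigis(case.biometry.acd, case.biometry.axial_length, constants)
    predicted_se = optics.predicted_refraction(
        case.implanted_power,
        case.biometry.axial_length,
        elp,
        z,
        config.vertex_distance,
    )
    pe = None if case.postop_se is None else case.postop_se - predicted_se
    return Prediction(formula_id=formula_id, predicted_se=predicted_se, pe=pe)
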