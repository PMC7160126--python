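"""Corneal-power formulas and per-case prediction."""

import itertools
import math

import numpy as np
import pytest

from haigisl import (
    EyeBiometry,
    MissingFieldError,
    OpticalConfig,
    PEModel,
    SurgeryCase,
    corneal_power_haigis_l,
    corneal_power_modified,
    effective_corneal_power,
    iol_power,
    keratometric_power,
    pe_from_sa,
    predict_case,
)

SA_ROOT = 2.3488 / 0.583  # SA8 at which the default error model predicts zero


@pytest.mark.parametrize(
    "r, expected",
    [(8.79, 32.57643), (8.00, 37.0103)],
)
def test_corneal_power_haigis_l(r, expected):
    assert corneal_power_haigis_l(r) == pytest.approx(expected, abs=1e-4)


def test_corneal_power_haigis_l_is_affine_in_radius():
    # slope -5.6125 D/mm, offset 82.2603 - 0.35 D
    for r in np.linspace(6.5, 11.5, 7):
        assert corneal_power_haigis_l(r) + 5.6125 * r == pytest.approx(
            82.2603 - 0.35, abs=1e-9
        )


def test_corneal_power_haigis_l_rejects_out_of_range_radius():
    with pytest.raises(ValueError):
        corneal_power_haigis_l(5.0)


@pytest.mark.parametrize(
    "sa8, expected",
    [(0.0, -2.3488), (SA_ROOT, 0.0), (3.69, -0.19753)],
)
def test_pe_from_sa(sa8, expected):
    assert pe_from_sa(sa8) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize(
    "sa8, expected",
    [
        (SA_ROOT, 32.57643),  # zero predicted error leaves Haigis-L power unchanged
        (3.69, 32.77349),
        (0.0, 34.86084),  # REFc(-2.3488) = -2.28441 subtracted
    ],
)
def test_corneal_power_modified(sa8, expected):
    assert corneal_power_modified(8.79, sa8, 12.0) == pytest.approx(expected, abs=1e-3)


def test_modified_with_null_model_equals_haigis_l():
    null = PEModel(slope=0.0, intercept=0.0)
    for r in np.linspace(7.0, 10.5, 8):
        for sa8 in np.linspace(0.0, 6.0, 5):
            assert corneal_power_modified(r, sa8, 12.0, null) == corneal_power_haigis_l(r)


def test_haigis_baseline_uses_keratometric_power(mean_eye):
    z = effective_corneal_power(mean_eye, "haigis", OpticalConfig())
    assert z == pytest.approx(keratometric_power(8.79, 1.3315))


def test_unknown_formula_rejected(mean_eye):
    with pytest.raises(ValueError, match="unknown formula_id"):
        effective_corneal_power(mean_eye, "srk-t")


def test_modified_formula_requires_sa8():
    eye = EyeBiometry(axial_length=28.43, acd=3.62, mean_corneal_radius=8.79)
    with pytest.raises(MissingFieldError, match="sa8"):
        effective_corneal_power(eye, "modified-haigis-l")


def test_predict_case_worked_chain(mean_eye):
    case = SurgeryCase("w", mean_eye, implanted_power=20.0, postop_se=1.418)
    pred = predict_case(case, "haigis-l")
    assert pred.predicted_se == pytest.approx(1.618, abs=1e-3)
    assert pred.pe == pytest.approx(-0.200, abs=1e-3)


def test_predict_case_without_outcome_has_no_pe(mean_eye):
    pred = predict_case(SurgeryCase("w", mean_eye, implanted_power=20.0), "haigis-l")
    assert pred.pe is None


def test_predict_case_requires_implanted_power(mean_eye):
    with pytest.raises(MissingFieldError, match="implanted_power"):
        predict_case(SurgeryCase("w", mean_eye), "haigis-l")


@pytest.mark.parametrize("formula_id", ["haigis", "haigis-l", "modified-haigis-l"])
def test_emmetropic_power_predicts_plano(mean_eye, formula_id):
    power = iol_power(mean_eye, formula_id, target_se=0.0)
    pred = predict_case(
        SurgeryCase("w", mean_eye, implanted_power=power), formula_id
    )
    assert pred.predicted_se == pytest.approx(0.0, abs=1e-9)


def test_sa_correction_shifts_prediction_toward_expected_error():
    """The modified formula moves the predicted SE by (approximately) the
    SA-expected error, so the shift always carries that error's sign."""
    grid = itertools.product(
        np.linspace(25.0, 33.0, 3),
        np.linspace(3.0, 4.3, 3),
        np.linspace(8.0, 10.0, 3),
        np.linspace(1.0, 6.0, 5),
    )
    for al, acd, r, sa8 in grid:
        eye = EyeBiometry(axial_length=al, acd=acd, mean_corneal_radius=r, sa8=sa8)
        case = SurgeryCase("g", eye, implanted_power=18.0)
        d_pred = (
            predict_case(case, "modified-haigis-l").predicted_se
            - predict_case(case, "haigis-l").predicted_se
        )
        expected = pe_from_sa(sa8)
        if abs(expected) > 1e-9:
            assert math.copysign(1, d_pred) == math.copysign(1, expected)


def test_biometry_invariants_enforced():
    with pytest.raises(ValueError):
        EyeBiometry(axial_length=50.0, acd=3.6, mean_corneal_radius=8.8)
    with pytest.raises(ValueError):
        EyeBiometry(axial_length=28.0, acd=0.5, mean_corneal_radius=8.8)
    with pytest.raises(ValueError):
        EyeBiometry(axial_length=28.0, acd=3.6, mean_corneal_radius=8.8, sa8=float("nan"))
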