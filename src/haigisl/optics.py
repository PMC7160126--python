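"""Thin-lens model-eye vergence arithmetic.

The pseudophakic eye is reduced to two refracting planes: an effective
corneal power Z at the corneal vertex and a thin intraocular lens at the
effective lens position (ELP).  Vergences travel in an aqueous medium whose
refractive index enters through the fixed numerator 1336 (n = 1.336 with
distances in mm).  Refractions are exchanged between the spectacle plane and
the corneal plane through the standard vertex-distance transform.

All distances are millimetres, all powers dioptres.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

from .errors import GeometryError, SingularVergenceError

#: Aqueous vergence numerator (n = 1.336, distances in mm).  Fixed, not
#: configurable: it is part of the thin-lens formula itself.
AQUEOUS_VERGENCE_CONSTANT = 1336.0

#: Denominators smaller than this (in their natural units) are treated as
#: singular and raise, rather than producing astronomically large powers.
SINGULAR_TOL = 1e-9


@dataclass(frozen=True)
class IOLConstants:
    """Haigis lens constants: ELP = a0 + a1*ACD + a2*AL.

    Defaults are the ULIB-optimised constants for the Tecnis ZCB00.
    """

    a0: float = -1.302
    a1: float = 0.210
    a2: float = 0.251

    def __post_init__(self) -> None:
        for name in ("a0", "a1", "a2"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"IOL constant {name} must be finite")


ZCB00 = IOLConstants()


@dataclass(frozen=True)
class OpticalConfig:
    """Global optical configuration.

    Parameters
    ----------
    vertex_distance : float
        Spectacle-to-cornea distance in mm (clinical convention: 12.0).
    keratometric_index : float
        Fictitious refractive index used only by the plain-Haigis baseline
        to convert an anterior corneal radius to keratometric power,
        D = (n - 1) * 1000 / r.  Default 1.3315 (Haigis convention).
    """

    vertex_distance: float = 12.0
    keratometric_index: float = 1.3315

    def __post_init__(self) -> None:
        if not (self.vertex_distance > 0 and math.isfinite(self.vertex_distance)):
            raise ValueError("vertex_distance must be positive and finite")
        if not (1.0 < self.keratometric_index < 2.0):
            raise ValueError("keratometric_index must lie in (1, 2)")


def spectacle_to_corneal(ref_s: float, vd: float = 12.0) -> float:
    """Transform a refraction from the spectacle plane to the corneal plane.

    REFc = 1000 * REFs / (1000 - REFs * vd), with vd in mm.
    """
    den = 1000.0 - ref_s * vd
    if abs(den) < SINGULAR_TOL or den <= 0:
        raise SingularVergenceError(
            f"spectacle-to-corneal transform singular: 1000 - {ref_s}*{vd} = {den}"
        )
    return 1000.0 * ref_s / den


def corneal_to_spectacle(ref_c: float, vd: float = 12.0) -> float:
    """Inverse vertex transform: REFs = 1000 * REFc / (1000 + REFc * vd)."""
    den = 1000.0 + ref_c * vd
    if abs(den) < SINGULAR_TOL or den <= 0:
        raise SingularVergenceError(
            f"corneal-to-spectacle transform singular: 1000 + {ref_c}*{vd} = {den}"
        )
    return 1000.0 * ref_c / den


def elp_haigis(acd: float, al: float, constants: IOLConstants = ZCB00) -> float:
    """Effective lens position d = a0 + a1*ACD + a2*AL (mm)."""
    if not acd > 0:
        raise ValueError(f"anterior chamber depth must be positive, got {acd}")
    if not al > 0:
        raise ValueError(f"axial length must be positive, got {al}")
    return constants.a0 + constants.a1 * acd + constants.a2 * al


def keratometric_power(r: float, index: float = 1.3315) -> float:
    """Corneal power from the anterior radius: D = (index - 1) * 1000 / r."""
    if not r > 0:
        raise ValueError(f"corneal radius must be positive, got {r}")
    return (index - 1.0) * 1000.0 / r


def iol_power_for_target(
    al: float,
    elp: float,
    z: float,
    target_ref_s: float = 0.0,
    vd: float = 12.0,
) -> float:
    """IOL power producing the target spectacle refraction.

    With a plano target this is exactly

        P = 1336/(AL - ELP) - 1336/(1336/Z - ELP).

    A nonzero target is handled by adding its corneal-plane vergence to Z
    before applying the same formula.
    """
    if not al > elp:
        raise GeometryError(f"axial length {al} must exceed ELP {elp}")
    z_eff = z + spectacle_to_corneal(target_ref_s, vd)
    if z_eff <= 0 or abs(z_eff) < SINGULAR_TOL:
        raise SingularVergenceError(f"effective corneal power {z_eff} not positive")
    den = AQUEOUS_VERGENCE_CONSTANT / z_eff - elp
    if abs(den) < SINGULAR_TOL:
        raise SingularVergenceError("corneal focal distance coincides with lens plane")
    return AQUEOUS_VERGENCE_CONSTANT / (al - elp) - AQUEOUS_VERGENCE_CONSTANT / den


def predicted_refraction(
    implanted_power: float,
    al: float,
    elp: float,
    z: float,
    vd: float = 12.0,
) -> float:
    """Predicted spectacle-plane refraction for an implanted IOL power.

    Closed-form inversion of the thin-lens formula: the aqueous vergence the
    cornea must supply is A = 1336/(AL - ELP) - P; the corneal power that
    supplies it is z_req = 1336/(1336/A + ELP); the residual refraction at
    the corneal plane is z_req - Z, transformed back to the spectacle plane.
    """
    if not al > elp:
        raise GeometryError(f"axial length {al} must exceed ELP {elp}")
    a_verg = AQUEOUS_VERGENCE_CONSTANT / (al - elp) - implanted_power
    if abs(a_verg) < SINGULAR_TOL:
        raise SingularVergenceError("zero vergence behind the lens plane")
    den = AQUEOUS_VERGENCE_CONSTANT / a_verg + elp
    if abs(den) < SINGULAR_TOL:
        raise SingularVergenceError("required corneal focal distance is zero")
    z_req = AQUEOUS_VERGENCE_CONSTANT / den
    return corneal_to_spectacle(z_req - z, vd)
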