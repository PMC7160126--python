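"""Synthetic post-refractive-surgery cohorts.

No patient-level data accompany the published training/test cohorts, so this
module generates eyes whose marginal biometry matches the training-set
summary statistics and whose outcomes follow the published error structure:
the Haigis-L prediction error is a linear function of SA8 plus Gaussian
residual noise.  Biometric variables are drawn independently (only marginals
are published); truncation is by rejection resampling, which preserves a
proper distribution instead of piling mass at the bounds.

Each variable draws from its own deterministic substream of the root seed,
so adding or removing a variable does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import formulas, optics
from .formulas import EyeBiometry, PEModel, SurgeryCase

#: Fixed substream key per random source; never renumber existing entries.
_STREAM_KEYS = {
    "axial_length": 0,
    "acd": 1,
    "mean_corneal_radius": 2,
    "sa8": 3,
    "sa6": 4,
    "q6": 5,
    "q8": 6,
    "ecc6": 7,
    "ecc8": 8,
    "residual": 100,
}


@dataclass(frozen=True)
class VariableSpec:
    """Marginal distribution of one biometric variable: a (possibly
    range-truncated) Gaussian."""

    mean: float
    sd: float
    trunc: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.trunc is not None:
            lo, hi = self.trunc
            if not lo <= self.mean <= hi:
                raise ValueError(f"truncation range {self.trunc} excludes mean {self.mean}")


@dataclass(frozen=True)
class CohortParams:
    """Generator parameters for a synthetic cohort.

    ``pe_model`` is the ground-truth error regression; ``residual_sd`` the
    SD (D) of error left after the SA trend; ``target_se`` the refraction
    each implant aims for (plano by default — per-case targets are unknown).
    """

    axial_length: VariableSpec
    acd: VariableSpec
    mean_corneal_radius: VariableSpec
    sa8: VariableSpec
    sa6: Optional[VariableSpec] = None
    q6: Optional[VariableSpec] = None
    q8: Optional[VariableSpec] = None
    ecc6: Optional[VariableSpec] = None
    ecc8: Optional[VariableSpec] = None
    pe_model: PEModel = field(default_factory=PEModel)
    residual_sd: float = 0.45
    target_se: float = 0.0
    n: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")
        if self.n < 0:
            raise ValueError("n must be non-negative")

    def without_truncation(self, *names: str) -> "CohortParams":
        """Copy of the params with truncation ranges dropped for ``names``
        (all truncated variables if none given)."""
        fields = list(names) if names else [k for k in _STREAM_KEYS if k != "residual"]
        updates = {}
        for name in fields:
            spec = getattr(self, name, None)
            if isinstance(spec, VariableSpec) and spec.trunc is not None:
                updates[name] = replace(spec, trunc=None)
        return replace(self, **updates)


def default_params_training(n: int = 80, seed: int = 0) -> CohortParams:
    """Parameters emulating the published training cohort of post-myopic-
    LASIK/PRK eyes: long, flat-cornea eyes with strongly positive SA8."""
    return CohortParams(
        axial_length=VariableSpec(28.43, 2.29, (24.47, 33.45)),
        acd=VariableSpec(3.62, 0.37, (2.28, 4.73)),
        mean_corneal_radius=VariableSpec(8.79, 0.53, (7.82, 10.28)),
        sa8=VariableSpec(3.69, 0.87, (1.20, 5.49)),
        sa6=VariableSpec(1.16, 0.39, (0.24, 2.08)),
        q6=VariableSpec(1.57, 0.70, (0.03, 3.44)),
        q8=VariableSpec(0.82, 0.58, (-0.10, 2.66)),
        ecc6=VariableSpec(-1.22, 0.31, (-1.85, -0.17)),
        ecc8=VariableSpec(-0.82, 0.39, (-1.63, 0.32)),
        pe_model=PEModel(),
        residual_sd=0.45,
        target_se=0.0,
        n=n,
        seed=seed,
    )


def _draw(spec: VariableSpec, n: int, seed: int, key: int) -> np.ndarray:
    rng = np.random.default_rng([int(seed), int(key)])
    x = rng.normal(spec.mean, spec.sd, size=n)
    if spec.trunc is not None:
        lo, hi = spec.trunc
        if lo > spec.mean + 6 * spec.sd or hi < spec.mean - 6 * spec.sd:
            raise ValueError(
                f"truncation range {spec.trunc} lies outside mean ± 6 sd; infeasible"
            )
        bad = (x < lo) | (x > hi)
        while np.any(bad):
            x[bad] = rng.normal(spec.mean, spec.sd, size=int(bad.sum()))
            bad = (x < lo) | (x > hi)
    return x


def generate_cohort(
    params: CohortParams,
    constants: optics.IOLConstants = optics.ZCB00,
    config: optics.OpticalConfig = optics.OpticalConfig(),
) -> list[SurgeryCase]:
    """Generate a cohort of surgery cases.

    Per eye: biometry is drawn from the marginal specs; the implanted power
    is the (continuous) Haigis-L power for the target refraction; the true
    prediction error is pe_model(SA8) plus Gaussian residual noise; and the
    observed postoperative SE is the Haigis-L predicted SE plus that error.
    Identical (params, seed) give bit-identical cohorts.
    """
    n, seed = params.n, params.seed
    draws: dict[str, Optional[np.ndarray]] = {}
    for name, key in _STREAM_KEYS.items():
        if name == "residual":
            continue
        spec = getattr(params, name)
        draws[name] = None if spec is None else _draw(spec, n, seed, key)
    resid_rng = np.random.default_rng([int(seed), _STREAM_KEYS["residual"]])
    resid = resid_rng.normal(0.0, params.residual_sd, size=n)

    def opt(name: str, i: int) -> Optional[float]:
        arr = draws[name]
        return None if arr is None else float(arr[i])

    cases = []
    for i in range(n):
        biometry = EyeBiometry(
            axial_length=float(draws["axial_length"][i]),
            acd=float(draws["acd"][i]),
            mean_corneal_radius=float(draws["mean_corneal_radius"][i]),
            sa8=float(draws["sa8"][i]),
            sa6=opt("sa6", i),
            q6=opt("q6", i),
            q8=opt("q8", i),
            ecc6=opt("ecc6", i),
            ecc8=opt("ecc8", i),
        )
        power = formulas.iol_power(
            biometry, "haigis-l", params.target_se, constants, config
        )
        z = formulas.corneal_power_haigis_l(biometry.mean_corneal_radius)
        elp = optics.elp_haigis(biometry.acd, biometry.axial_length, constants)
        pred_se = optics.predicted_refraction(
            power, biometry.axial_length, elp, z, config.vertex_distance
        )
        true_pe = formulas.pe_from_sa(biometry.sa8, params.pe_model) + float(resid[i])
        cases.append(
            SurgeryCase(
                eye_id=f"syn{i:05d}",
                biometry=biometry,
                implanted_power=power,
                postop_se=pred_se + true_pe,
                true_pe=true_pe,
            )
        )
    return cases
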