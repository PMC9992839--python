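"""Passive force–SL and fluidity–SL behaviour of the resting half-sarcomere.

The canonical passive curve is the exponential form used to describe the
measured passive force of the intact frog fiber, zero at and below the slack
length and rising steeply as the tandem Ig segment approaches its contour
length.  An optional freely-jointed-chain-style alternative is exposed
behind the same interface; it is an approximation, not a fitted supplement
model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .mech_model import DomainError, MechModelError, TitinMechParams

__all__ = [
    "PassiveCurveParams",
    "passive_force",
    "passive_stiffness",
    "straightened_fraction",
]


@dataclass(frozen=True)
class EntropicChainParams:
    """Parameters of the approximate freely-jointed-chain alternative."""

    n_elements: int = 50
    element_length_nm: float = 9.0
    pevk_contour_fraction: float = 0.25


@dataclass(frozen=True)
class PassiveCurveParams:
    """Exponential passive force curve ``A (exp(r (SL - SL_slack)) - 1)``.

    Defaults are calibrated so that the passive force at SL 3.0 um equals
    24.9 pN per half-thick-filament (the restoring force measured at that
    length) with the curve negligible below ~2.6 um.
    """

    exp_amplitude: float = 24.9 / math.expm1(18.0 * (3.0 - 2.2))
    exp_rate: float = 18.0
    SL_slack: float = 2.2
    chain: Optional[EntropicChainParams] = None

    def __post_init__(self) -> None:
        if not self.exp_rate > 0:
            raise MechModelError("exp_rate must be > 0")
        if not self.exp_amplitude >= 0:
            raise MechModelError("exp_amplitude must be >= 0")

    @classmethod
    def calibrated(
        cls,
        force_at_SL: float = 24.9,
        SL: float = 3.0,
        exp_rate: float = 18.0,
        SL_slack: float = 2.2,
    ) -> "PassiveCurveParams":
        """Choose the amplitude so the curve passes through ``force_at_SL``."""
        amp = force_at_SL / math.expm1(exp_rate * (SL - SL_slack))
        return cls(exp_amplitude=amp, exp_rate=exp_rate, SL_slack=SL_slack)


def passive_force(params: PassiveCurveParams, SL) -> np.ndarray | float:
    """Passive force at sarcomere length ``SL`` (um), pN per half-thick-filament.

    Zero at and below the slack length; exponential and monotone
    non-decreasing above it.  If ``params.chain`` is set, an approximate
    freely-jointed-chain curve is used instead of the exponential.
    """
    SL_arr = np.asarray(SL, dtype=float)
    if np.any(SL_arr < 2.0):
        raise DomainError("passive curve defined for SL >= 2.0 um")
    if params.chain is not None:
        value = _chain_force(params, SL_arr)
    else:
        value = params.exp_amplitude * np.expm1(
            params.exp_rate * np.maximum(SL_arr - params.SL_slack, 0.0)
        )
    return float(value) if np.isscalar(SL) else value


def _chain_force(params: PassiveCurveParams, SL: np.ndarray) -> np.ndarray:
    """Approximate inverse-Langevin entropic chain (labelled approximate).

    The I-band extension per half-sarcomere is mapped to a fractional chain
    extension and the force follows the Pade inverse of the Langevin
    function; the amplitude is rescaled to preserve the calibration point of
    the exponential curve at SL 3.0 um.
    """
    chain = params.chain
    assert chain is not None
    contour_nm = chain.n_elements * chain.element_length_nm
    ext = np.clip((SL - params.SL_slack) * 1e3 / 2.0 / contour_nm, 0.0, 0.999)
    # Cohen's Pade approximant of the inverse Langevin function
    raw = ext * (3.0 - ext**2) / (1.0 - ext**2)
    ref = passive_force(
        PassiveCurveParams(
            exp_amplitude=params.exp_amplitude,
            exp_rate=params.exp_rate,
            SL_slack=params.SL_slack,
        ),
        3.0,
    )
    ext_ref = np.clip((3.0 - params.SL_slack) * 1e3 / 2.0 / contour_nm, 0.0, 0.999)
    raw_ref = ext_ref * (3.0 - ext_ref**2) / (1.0 - ext_ref**2)
    return ref * raw / raw_ref


def passive_stiffness(params: PassiveCurveParams, SL: float, dx_nm: float = 0.5) -> float:
    """Numerical passive stiffness at ``SL``, pN per nm of half-sarcomere.

    Central difference of the passive curve with respect to half-sarcomere
    length (1 nm per half-sarcomere = 2e-3 um of SL).
    """
    dSL = 2e-3 * dx_nm
    hi = passive_force(params, SL + dSL)
    lo = passive_force(params, max(SL - dSL, params.SL_slack))
    return float((hi - lo) / (2 * dx_nm))


def straightened_fraction(params: TitinMechParams, SL) -> np.ndarray | float:
    """Fraction ``k/(m-1)`` of straightened inter-Ig elements at ``SL``.

    Zero at the slack/reference length, one at the contour length, linear in
    between, and complementary to the resting fluidity:
    ``resting_fluidity(SL)/fluidity_max + straightened_fraction(SL) = 1``.
    """
    SL_arr = np.asarray(SL, dtype=float)
    if np.any(SL_arr < params.SL_ref) or np.any(SL_arr > params.SL_c):
        raise DomainError(
            f"SL outside [{params.SL_ref}, {params.SL_c}]: fraction undefined"
        )
    value = (SL_arr - params.SL_ref) / (params.SL_c - params.SL_ref)
    return float(value) if np.isscalar(SL) else value
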