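"""OFF/ON viscoelastic model of I-band titin in the half-sarcomere.

The half-sarcomere is represented by an equivalent mechanical circuit with
two activation states:

* **OFF (rest)** — I-band titin is a PEVK spring (stiffness ``e_pevk``) in
  series with the tandem-Ig segment, whose straightening under load behaves
  as a dashpot with an SL-dependent fluidity ``1/eta_i``.  The fluidity is
  proportional to the number of still-bent inter-Ig elements and therefore
  falls linearly with sarcomere length, reaching zero at the contour length
  ``SL_c`` where the tandem Ig segment is fully straight.
* **ON (stimulated)** — a titin–actin link short-circuits the tandem Ig
  segment.  The response to a force step is an instantaneous elasticity
  ``e1``, a fast viscoelastic phase relaxing with time constant ``tau2``
  toward the equilibrium stiffness ``e2``, and a slow drift through a
  *mechanical rectifier*: a dashpot whose viscosity is ``eta3`` for
  lengthening loads but ``eta_sh`` (three orders of magnitude smaller) for
  shortening loads.

Conventions: forces in pN per half-thick-filament, lengths in nm per
half-sarcomere (lengthening positive), times in s, sarcomere length (SL) in
um.  A length change ``x`` nm per half-sarcomere changes SL by
``2e-3 * x`` um (both halves lengthen).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "TitinMechParams",
    "ForceStepProtocol",
    "Transient",
    "TABLE1_PARAMS",
    "THICK_FILAMENT_DENSITY",
    "resting_fluidity",
    "rectifier_viscosity",
    "simulate_on",
    "simulate_off",
    "stress_to_force_per_htf",
    "MechModelError",
    "DomainError",
]


class MechModelError(ValueError):
    """Invalid parameter or protocol for the half-sarcomere model."""


class DomainError(MechModelError):
    """Operating point outside the model's domain of validity."""


#: thick filaments per m^2 of cross section in the frog muscle lattice
THICK_FILAMENT_DENSITY = 5.87e14


@dataclass(frozen=True)
class TitinMechParams:
    """Lumped mechanical constants of the OFF/ON half-sarcomere model.

    Parameters
    ----------
    e1 : float
        Instantaneous half-sarcomere stiffness, pN/nm per half-thick-filament.
    e2 : float
        ON-state equilibrium stiffness (from the phase-2 amplitude), pN/nm.
    tau2 : float
        Phase-2 relaxation time constant, s.
    eta3 : float
        ON-state lengthening viscosity of the rectifier, pN s/nm.
    eta_sh : float
        ON-state shortening viscosity of the rectifier, pN s/nm.
    fluidity_max : float
        OFF-state fluidity ``(1/eta_s)*(m-1)`` at ``SL_ref``, nm/(s pN).
    SL_ref : float
        Sarcomere length of maximal fluidity (full overlap, slack), um.
    SL_c : float
        Contour sarcomere length at which the OFF fluidity is zero, um.
    e_pevk : float
        PEVK spring stiffness, pN/nm.
    e_M, e_A : float
        Optional explicit thick/thin filament stiffnesses, pN/nm.  Default
        infinite (rigid): their compliance is lumped into ``e1``.
    """

    e1: float = 7.30
    e2: float = 3.02
    tau2: float = 0.5e-3
    eta3: float = 6.25
    eta_sh: float = 1.60e-3
    fluidity_max: float = 1e3 * (3.15 - 2.2) / (3.15 - 2.7)
    SL_ref: float = 2.2
    SL_c: float = 3.15
    e_pevk: float = 1.0 / 0.65
    e_M: float = math.inf
    e_A: float = math.inf

    def __post_init__(self) -> None:
        positive = {
            "e1": self.e1,
            "e2": self.e2,
            "tau2": self.tau2,
            "eta3": self.eta3,
            "eta_sh": self.eta_sh,
            "fluidity_max": self.fluidity_max,
            "e_pevk": self.e_pevk,
            "e_M": self.e_M,
            "e_A": self.e_A,
        }
        for name, value in positive.items():
            if not value > 0 or math.isnan(value):
                raise MechModelError(f"{name} must be strictly positive, got {value!r}")
        if not self.e2 < self.e1:
            raise MechModelError(
                f"equilibrium stiffness e2={self.e2} must be below instantaneous e1={self.e1}"
            )
        if not self.eta_sh < self.eta3:
            raise MechModelError(
                f"shortening viscosity eta_sh={self.eta_sh} must be below eta3={self.eta3}"
            )
        if not self.SL_ref < self.SL_c:
            raise MechModelError(
                f"SL_ref={self.SL_ref} must be below the contour length SL_c={self.SL_c}"
            )

    @property
    def e_b(self) -> float:
        """Stiffness of the phase-2 spring (series complement of e1 and e2)."""
        return self.e1 * self.e2 / (self.e1 - self.e2)

    @property
    def eta_b(self) -> float:
        """Viscosity of the phase-2 dashpot, ``e_b * tau2``."""
        return self.e_b * self.tau2

    def with_(self, **kwargs) -> "TitinMechParams":
        return replace(self, **kwargs)


def _table1(e1, e2, eta3, eta_sh=1.60e-3) -> TitinMechParams:
    return TitinMechParams(e1=e1, e2=e2, eta3=eta3, eta_sh=eta_sh)


#: per-SL parameter sets measured on the active fiber (SL in um).  eta_sh was
#: measured only at SL 3.0; the same value is carried at the other lengths.
TABLE1_PARAMS: dict[float, TitinMechParams] = {
    2.5: _table1(6.90, 2.69, 6.85),
    2.7: _table1(7.30, 3.02, 6.25),
    3.0: _table1(7.35, 3.51, 3.94),
}


@dataclass(frozen=True)
class ForceStepProtocol:
    """Force-clamp step protocol.

    The force ramps linearly from ``baseline_force`` to
    ``baseline_force + delta_T`` over ``rise_time`` starting at ``t_step``.
    The step half-time (reference time for back-extrapolated amplitudes) is
    the midpoint of the ramp.
    """

    delta_T: float
    baseline_force: float = 0.0
    rise_time: float = 150e-6
    t_step: float = 5e-3
    duration: float = 0.25
    dt: float = 1e-5
    stim_window: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.rise_time < 0:
            raise MechModelError("rise_time must be >= 0")
        if not self.dt > 0:
            raise MechModelError("dt must be > 0")
        if not self.t_step + self.rise_time < self.duration:
            raise MechModelError("step must complete before the end of the record")

    @property
    def t_half(self) -> float:
        """Half-time of the step (midpoint of the force ramp), s."""
        return self.t_step + self.rise_time / 2.0

    @property
    def t_end(self) -> float:
        """End of the force ramp, s."""
        return self.t_step + self.rise_time

    def time_grid(self) -> np.ndarray:
        n = int(round(self.duration / self.dt)) + 1
        return np.arange(n) * self.dt

    def force(self, t: np.ndarray) -> np.ndarray:
        """Clamped force at times ``t``, pN per half-thick-filament."""
        t = np.asarray(t, dtype=float)
        if self.rise_time == 0:
            ramp = (t >= self.t_step).astype(float)
        else:
            ramp = np.clip((t - self.t_step) / self.rise_time, 0.0, 1.0)
        return self.baseline_force + self.delta_T * ramp


@dataclass
class Transient:
    """One simulated or recorded force-clamp record."""

    time: np.ndarray
    force: np.ndarray
    x: np.ndarray
    SL0: float
    state: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if not (len(self.time) == len(self.force) == len(self.x)):
            raise MechModelError("time, force and x must have equal length")
        dts = np.diff(self.time)
        if len(dts) and (np.any(dts <= 0) or not np.allclose(dts, dts[0], rtol=1e-6)):
            raise MechModelError("time must be strictly increasing with uniform spacing")
        if self.state not in ("OFF", "ON"):
            raise MechModelError(f"state must be 'OFF' or 'ON', got {self.state!r}")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


def resting_fluidity(params: TitinMechParams, SL) -> np.ndarray | float:
    """OFF-state tandem-Ig fluidity ``1/eta_i`` at sarcomere length ``SL``.

    Linear in SL: equals ``fluidity_max`` at ``SL_ref`` and zero at the
    contour length ``SL_c`` (clipped to zero beyond).  Units nm/(s pN).
    """
    SL_arr = np.asarray(SL, dtype=float)
    if np.any(SL_arr < params.SL_ref):
        raise DomainError(
            f"SL below the slack length SL_ref={params.SL_ref}: model undefined"
        )
    value = params.fluidity_max * (params.SL_c - SL_arr) / (params.SL_c - params.SL_ref)
    value = np.maximum(value, 0.0)
    return float(value) if np.isscalar(SL) else value


def rectifier_viscosity(params: TitinMechParams, delta_T: float) -> float:
    """Viscosity of the ON-state titin link for a step of sign ``delta_T``.

    Positive (lengthening) steps see ``eta3``; negative (shortening) steps
    see ``eta_sh``.  At ``delta_T == 0`` no flow occurs and the branch choice
    is inert; ``eta3`` is returned.
    """
    return params.eta_sh if delta_T < 0 else params.eta3


def stress_to_force_per_htf(
    stress_kpa: float, filament_density: float = THICK_FILAMENT_DENSITY
) -> float:
    """Convert an axial stress (kPa) to force per half-thick-filament (pN)."""
    if not filament_density > 0:
        raise MechModelError("filament_density must be > 0")
    if stress_kpa < 0:
        raise MechModelError("stress must be >= 0")
    # kPa = 1e3 N/m^2 ; divide by filaments/m^2 -> N per filament ; 1e12 pN/N
    return stress_kpa * 1e15 / filament_density


def _validate_finite(params: TitinMechParams) -> None:
    for name in ("e1", "e2", "tau2", "eta3", "eta_sh"):
        if not math.isfinite(getattr(params, name)):
            raise MechModelError(f"parameter {name} must be finite")


def _series_filament_compliance(params: TitinMechParams) -> float:
    c = 0.0
    if math.isfinite(params.e_M):
        c += 1.0 / params.e_M
    if math.isfinite(params.e_A):
        c += 1.0 / params.e_A
    return c


def simulate_on(
    params: TitinMechParams, protocol: ForceStepProtocol, SL0: float
) -> Transient:
    """Simulate the ON-state (stimulated) response to a force step.

    The length change is the sum of three elements driven by the force
    change ``dF(t)`` relative to baseline (the baseline is assumed
    pre-equilibrated):

    * instantaneous spring: ``dF/e1``;
    * phase-2 Voigt element: ``dx_kv/dt = (dF - e_b x_kv)/eta_b`` with
      ``e_b = e1 e2/(e1-e2)`` and ``eta_b = e_b tau2``, so the elastic
      extension equilibrates at ``dF/e2`` overall;
    * rectifier dashpot: ``dx_d/dt = dF/eta`` with ``eta`` selected by the
      sign of the step.

    The Voigt element is advanced with an exponential update that is exact
    for the piecewise-linear clamped force, so the integrator error is at
    machine level for any ``dt``; ``dt <= tau2/10`` is nevertheless enforced
    so that the sampled trace resolves phase 2.

    If ``protocol.stim_window`` is set and ends before the record does, the
    model switches instantaneously to the OFF state at that time and the
    remainder of the record follows the resting dynamics (continuous in x).
    """
    _validate_finite(params)
    t = protocol.time_grid()
    dF = protocol.force(t) - protocol.baseline_force
    if protocol.dt > params.tau2 / 10:
        raise MechModelError(
            f"dt={protocol.dt} too coarse: must be <= tau2/10 = {params.tau2 / 10}"
        )

    eta = rectifier_viscosity(params, protocol.delta_T)

    # exact exponential update of the Voigt element for piecewise-linear dF
    tau = params.tau2
    a = math.exp(-protocol.dt / tau)
    u = dF / params.e_b
    s = np.diff(u) / protocol.dt
    b = u[1:] - s * tau - a * (u[:-1] - s * tau)
    x_kv = np.empty_like(u)
    x_kv[0] = 0.0
    if len(b):
        x_kv[1:] = lfilter([1.0], [1.0, -a], b)

    # rectifier dashpot: trapezoid is exact for piecewise-linear dF
    x_d = np.concatenate(
        [[0.0], np.cumsum((dF[1:] + dF[:-1]) / (2.0 * eta)) * protocol.dt]
    )

    x = dF / params.e1 + dF * _series_filament_compliance(params) + x_kv + x_d

    if protocol.stim_window is not None and protocol.stim_window[1] < protocol.duration:
        i_off = int(np.searchsorted(t, protocol.stim_window[1]))
        if i_off < len(t) - 1:
            x_el_off = dF[i_off:] / params.e_pevk
            x_ig0 = x[i_off] - x_el_off[0]
            x_ig = _integrate_ig(
                params, dF[i_off:], protocol.dt, SL0, x_el_off, x_ig0
            )
            x = x.copy()
            x[i_off:] = x_el_off + x_ig

    return Transient(
        time=t,
        force=protocol.force(t),
        x=x,
        SL0=SL0,
        state="ON",
        meta={"protocol": protocol, "params": params},
    )


def _integrate_ig(
    params: TitinMechParams,
    dF: np.ndarray,
    dt: float,
    SL0: float,
    x_el: np.ndarray,
    x_ig0: float = 0.0,
) -> np.ndarray:
    """Advance the tandem-Ig dashpot ``dx/dt = dF * fluidity(SL(t))``.

    The fluidity is linear in SL and SL is affine in the total extension, so
    with the force held constant over a sample interval the ODE is linear in
    ``x_ig`` and admits an exact exponential update.  After the force ramp
    the forcing is constant and the remaining trajectory is evaluated in
    closed form in one vectorized expression.
    """
    c = params.fluidity_max / (params.SL_c - params.SL_ref)  # nm/(s pN um)
    x_ig = np.empty_like(dF)
    x_ig[0] = x_ig0
    n = len(dF)

    def step_exact(i: int, x0: float) -> float:
        f_mid = 0.5 * (dF[i] + dF[i + 1])
        el_mid = 0.5 * (x_el[i] + x_el[i + 1])
        if f_mid == 0.0:
            return x0
        k = f_mid * c * 2e-3  # 1/s ; SL change = 2e-3 um per nm
        x_inf = (params.SL_c - SL0) / 2e-3 - el_mid
        if f_mid > 0.0 and x0 >= x_inf:
            return x0  # at/beyond contour: fluidity clips to zero, no flow
        return x_inf + (x0 - x_inf) * math.exp(-k * dt)

    # index of the first interval over which the forcing is already constant
    i_const = n - 1
    for i in range(n - 1):
        if dF[i] == dF[-1] and x_el[i] == x_el[-1]:
            i_const = i
            break
    for i in range(min(i_const, n - 1)):
        x_ig[i + 1] = step_exact(i, x_ig[i])
    if i_const < n - 1:
        f = dF[-1]
        x_inf = (params.SL_c - SL0) / 2e-3 - x_el[-1]
        if f == 0.0 or (f > 0.0 and x_ig[i_const] >= x_inf):
            x_ig[i_const:] = x_ig[i_const]
        else:
            k = f * c * 2e-3
            tt = np.arange(n - i_const) * dt
            # for shortening (k < 0) the solution diverges from x_inf; an
            # overflow just means SL_ref was crossed, caught below
            with np.errstate(over="ignore"):
                x_ig[i_const:] = x_inf + (x_ig[i_const] - x_inf) * np.exp(-k * tt)

    SL_t = SL0 + 2e-3 * (x_el + x_ig)
    if np.any(SL_t < params.SL_ref - 1e-9):
        raise DomainError(
            "trajectory shortened below SL_ref: resting fluidity law undefined"
        )
    return x_ig


def simulate_off(
    params: TitinMechParams, protocol: ForceStepProtocol, SL0: float
) -> Transient:
    """Simulate the OFF-state (resting) response to a force step.

    ``x(t) = dF(t)/e_pevk + x_Ig(t)`` with
    ``dx_Ig/dt = dF(t) * resting_fluidity(SL0 + 2e-3 x(t))``: as the
    half-sarcomere lengthens the instantaneous SL rises, the fluidity
    self-quenches and the lengthening velocity decays exponentially toward
    the contour limit.
    """
    _validate_finite(params)
    if not (params.SL_ref <= SL0 <= params.SL_c):
        raise DomainError(
            f"SL0={SL0} outside the OFF-model domain [{params.SL_ref}, {params.SL_c}]"
        )
    t = protocol.time_grid()
    dF = protocol.force(t) - protocol.baseline_force
    x_el = dF / params.e_pevk + dF * _series_filament_compliance(params)
    x_ig = _integrate_ig(params, dF, protocol.dt, SL0, x_el)
    return Transient(
        time=t,
        force=protocol.force(t),
        x=x_el + x_ig,
        SL0=SL0,
        state="OFF",
        meta={"protocol": protocol, "params": params},
    )
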