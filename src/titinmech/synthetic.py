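"""Synthetic study generator.

Emulates the experimental design of the force-clamp study — force steps of
both signs applied at several sarcomere lengths to a population of fibers,
at rest and during stimulation — and the X-ray extension-onset scan, so
that every analysis stage can be exercised end-to-end without recordings.

Determinism contract: an identical configuration (including the seed)
produces bit-identical outputs, and random streams are split per fiber with
``numpy.random.SeedSequence.spawn`` so adding a fiber does not perturb the
draws of earlier fibers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .mech_model import (
    TABLE1_PARAMS,
    ForceStepProtocol,
    TitinMechParams,
    simulate_off,
    simulate_on,
)
from .xray import FilamentAxialModel, _m3_features

__all__ = ["SyntheticStudyConfig", "gen_mech_dataset", "gen_xray_observations"]


def _default_params_per_SL() -> dict[float, TitinMechParams]:
    return dict(TABLE1_PARAMS)


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Conditions of the emulated study.

    Defaults mirror the study design: sarcomere lengths 2.5/2.7/3.0 um,
    force steps up to +-0.2 of the ~245 pN isometric reference, Gaussian
    trace noise of 0.5 nm SD, 2% relative noise on X-ray features and 5%
    lognormal fiber-to-fiber parameter variability.
    """

    seed: int = 0
    SL_list: tuple[float, ...] = (2.5, 2.7, 3.0)
    delta_T_list: tuple[float, ...] = (9.0, 20.0, 25.0, 50.0, -9.0, -20.0, -25.0)
    n_fibers: int = 8
    trace_noise_sd: float = 0.5
    force_noise_sd: float = 0.5
    xray_noise_rel: float = 0.02
    xray_spacing_noise_nm: float = 0.005
    param_jitter_cv: float = 0.05
    states: tuple[str, ...] = ("ON", "OFF")
    protocol: ForceStepProtocol = field(
        default_factory=lambda: ForceStepProtocol(delta_T=0.0)
    )
    params_per_SL: tuple[tuple[float, TitinMechParams], ...] = tuple(
        sorted(_default_params_per_SL().items())
    )

    def __post_init__(self) -> None:
        for name in ("trace_noise_sd", "force_noise_sd", "xray_noise_rel",
                     "xray_spacing_noise_nm", "param_jitter_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def params_for(self, SL: float) -> TitinMechParams:
        for sl, p in self.params_per_SL:
            if abs(sl - SL) < 1e-9:
                return p
        raise KeyError(f"no parameter set for SL={SL}")


def _jitter(params: TitinMechParams, cv: float, rng: np.random.Generator) -> TitinMechParams:
    """Lognormal multiplicative jitter (CV ``cv``) on the mechanical constants."""
    if cv == 0:
        return params
    sigma = np.sqrt(np.log1p(cv**2))
    mu = -0.5 * sigma**2  # unit-mean lognormal
    def draw() -> float:
        return float(np.exp(rng.normal(mu, sigma)))
    e1 = params.e1 * draw()
    # keep the invariant e2 < e1 by jittering the ratio, not e2 directly
    e2 = e1 * (params.e2 / params.e1) * min(draw(), 0.99 * params.e1 / params.e2)
    return params.with_(
        e1=e1,
        e2=e2,
        eta3=params.eta3 * draw(),
        eta_sh=params.eta_sh * draw(),
        fluidity_max=params.fluidity_max * draw(),
    )


def gen_mech_dataset(config: SyntheticStudyConfig) -> list:
    """Simulated force-clamp records for every fiber x SL x step x state.

    Gaussian noise (``trace_noise_sd`` nm, ``force_noise_sd`` pN) is added
    sample-wise; each fiber carries its own jittered parameter set.  OFF
    records are generated for positive steps only when the step would drive
    the resting trajectory outside the model's SL domain.
    """
    sq = np.random.SeedSequence(config.seed)
    fiber_seeds = sq.spawn(config.n_fibers)
    transients = []
    for i_fiber, fiber_seed in enumerate(fiber_seeds):
        rng = np.random.Generator(np.random.PCG64(fiber_seed))
        for SL, base_params in config.params_per_SL:
            if SL not in config.SL_list:
                continue
            params = _jitter(base_params, config.param_jitter_cv, rng)
            for delta_T in config.delta_T_list:
                protocol = replace(config.protocol, delta_T=delta_T)
                for state in config.states:
                    if state == "ON":
                        tr = simulate_on(params, protocol, SL)
                    else:
                        if delta_T < 0:
                            continue  # resting shortening leaves the SL domain
                        tr = simulate_off(params, protocol, SL)
                    noisy_x = tr.x + rng.normal(0.0, config.trace_noise_sd, len(tr.x))
                    noisy_f = tr.force + rng.normal(
                        0.0, config.force_noise_sd, len(tr.force)
                    )
                    tr.x = noisy_x if config.trace_noise_sd > 0 else tr.x
                    tr.force = noisy_f if config.force_noise_sd > 0 else tr.force
                    tr.meta.update(
                        fiber=f"fiber{i_fiber:02d}",
                        seed=config.seed,
                        state=state,
                        provenance="synthetic",
                    )
                    transients.append(tr)
    return transients


def gen_xray_observations(
    config: SyntheticStudyConfig,
    true_onset: int,
    target_spacings: Sequence[float] = (14.30, 14.35, 14.35, 14.40, 14.40, 14.40, 14.40, 14.40),
    template: Optional[FilamentAxialModel] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[tuple[float, float, float]]:
    """Noisy ``(S_M3, frac_L, frac_H)`` triplets for the extension-onset scan.

    For each target spacing the extended periodicity is set so the simulated
    M3 spacing of the ``true_onset`` geometry matches it; the subpeak
    fractions are then read off the simulation and perturbed with relative
    Gaussian noise (``xray_noise_rel``), the spacing with absolute Gaussian
    noise (``xray_spacing_noise_nm``).

    The default spacing design emulates the time-resolved study: one
    pre-step pattern at the resting spacing, the smaller step amplitude
    observed twice, and the larger step observed at five time points after
    the step.
    """
    if not (1 <= true_onset <= 49):
        raise ValueError("true_onset must lie in [1, 49]")
    if template is None:
        template = FilamentAxialModel()
    if rng is None:
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence([config.seed, 0x58A1]))
        )
    from scipy.optimize import brentq

    observations = []
    for target in target_spacings:
        if abs(target - template.d) < 1e-9:
            d_ext = template.d
        else:
            d_ext = brentq(
                lambda de: _m3_features(
                    replace(template, onset_layer=true_onset, d_ext=de)
                )[0]
                - target,
                template.d - 0.05,
                template.d + 0.30,
                xtol=1e-6,
            )
        s_m3, frac_l, frac_h = _m3_features(
            replace(template, onset_layer=true_onset, d_ext=float(d_ext))
        )
        observations.append(
            (
                s_m3 + rng.normal(0.0, config.xray_spacing_noise_nm),
                frac_l * (1.0 + rng.normal(0.0, config.xray_noise_rel)),
                frac_h * (1.0 + rng.normal(0.0, config.xray_noise_rel)),
            )
        )
    return observations
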