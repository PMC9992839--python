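"""Recover the per-SL mechanical constants from simulated force steps.

Simulates noiseless ON transients at each sarcomere length, runs the
tangent/back-extrapolation estimators, fits the amplitude- and
velocity-vs-step relations and prints the recovered stiffnesses and
viscosities next to the injected values."""

from titinmech import TABLE1_PARAMS, ForceStepProtocol, simulate_on
from titinmech.estimators import estimate_L1, estimate_L2, estimate_Vsh, fit_relation

DT = 1e-5
print(f"{'SL':>4} {'e1':>7} {'(true)':>7} {'e2':>7} {'(true)':>7} "
      f"{'eta3':>7} {'(true)':>7}")
for SL, params in TABLE1_PARAMS.items():
    l1, l2, v3 = [], [], []
    for step in (25.0, 50.0, 75.0, 100.0):
        protocol = ForceStepProtocol(delta_T=step, rise_time=DT, t_step=5e-3,
                                     duration=0.25, dt=DT)
        tr = simulate_on(params, protocol, SL)
        l1.append((step, estimate_L1(tr, protocol)))
        L2, V3 = estimate_L2(tr, protocol)
        l2.append((step, L2))
        v3.append((step, V3))
    e1 = 1 / fit_relation(l1).slope
    e2 = 1 / fit_relation(l2).slope
    eta3 = 1 / fit_relation(v3).slope
    print(f"{SL:>4} {e1:7.2f} {params.e1:7.2f} {e2:7.2f} {params.e2:7.2f} "
          f"{eta3:7.2f} {params.eta3:7.2f}")

# shortening branch of the rectifier, measured at 3.0 um
vsh = []
for step in (-10.0, -15.0, -20.0, -25.0):
    protocol = ForceStepProtocol(delta_T=step, rise_time=DT, t_step=5e-3,
                                 duration=0.05, dt=DT)
    tr = simulate_on(TABLE1_PARAMS[3.0], protocol, 3.0)
    vsh.append((step, estimate_Vsh(tr, protocol)))
eta_sh = 1 / fit_relation(vsh).slope
print(f"\neta_sh at 3.0 um: {eta_sh:.3e} pN s/nm (true 1.60e-03)"
      f" -> rectification ratio eta3/eta_sh = {TABLE1_PARAMS[3.0].eta3/eta_sh:.0f}")
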