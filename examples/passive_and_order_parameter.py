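"""Passive force-SL curve and the azimuthal order-parameter model.

Left: the exponential passive curve calibrated through 24.9 pN at 3.0 um.
Right: the reduced model of motor reorientation - the order parameter phi
that reproduces the 40% layer-line drop also yields the 80% equatorial
1,1 rise while leaving the 1,0 intensity untouched."""

import numpy as np

from titinmech.passive import PassiveCurveParams, passive_force, passive_stiffness
from titinmech.xray import EquatorialState, equatorial_and_helical, order_parameter_timecourse

params = PassiveCurveParams()
print("SL (um)   passive force (pN/htf)")
for SL in (2.4, 2.6, 2.8, 2.9, 3.0, 3.1):
    print(f"  {SL:.1f}     {passive_force(params, SL):8.2f}")
print(f"passive stiffness at 3.0 um: {passive_stiffness(params, 3.0):.2f} pN/nm per hs")

phi = 1.0 - np.sqrt(0.6)
state = EquatorialState(phi=phi)
i10, i11, iml1 = equatorial_and_helical(state)
print(f"\nphi = {phi:.4f}: I_1,0 x{i10:.2f}   I_1,1 x{i11:.2f}   I_ML1 x{iml1:.2f}")
t = np.array([0.005, 0.020, 0.060])
for ti, p in zip(t, order_parameter_timecourse(state, t)):
    print(f"phi({1e3*ti:4.0f} ms) = {p:.4f}")
print("tau ~ 20 ms exponential reorientation at constant radius.")
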