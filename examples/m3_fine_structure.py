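"""M3 interference fine structure under uniform vs partial filament extension.

Builds the two-array 49-crown thick filament, computes the meridional
intensity around the M3 reflection and compares three geometries: resting
(d = 14.3 nm), uniformly extended by 0.7% (bare zone included) and
partially extended (bare zone and first three layers fixed, extension from
layer 4).  Uniform extension shifts S_M3 without touching the subpeak
balance; partial extension shifts intensity into the low-angle subpeak."""

from dataclasses import replace

from titinmech.xray import FilamentAxialModel
from titinmech.xray import _m3_features

rest = FilamentAxialModel()
uniform = rest.scaled(14.4 / 14.3)
partial = replace(rest, onset_layer=4, d_ext=14.4117)  # matched to S_M3 = 14.4

for label, model in [("rest", rest), ("uniform +0.7%", uniform),
                     ("partial (onset 4)", partial)]:
    s_m3, frac_l, frac_h = _m3_features(model)
    print(f"{label:18}: S_M3 = {s_m3:7.4f} nm   L_M3/tot = {frac_l:.4f}   "
          f"H_M3/tot = {frac_h:.4f}")
print("\npartial extension raises the low-angle and depresses the high-angle")
print("subpeak at the same S_M3 - the fingerprint that localizes the")
print("stress-dependent extension to the titin-interacting region.")
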