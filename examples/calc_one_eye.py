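"""IOL power for a single post-myopic-LASIK eye under all three formulas.

The eye is the training-cohort mean: long (28.43 mm), flat cornea
(r = 8.79 mm), strongly positive spherical aberration (3.69 µm at 8 mm).
The plain Haigis keratometric power overestimates the cornea after myopic
ablation, so it yields the lowest implant power; the SA correction expects
a small myopic surprise at this SA8 and nudges the power below Haigis-L.
"""

from haigisl import FORMULA_IDS, EyeBiometry, effective_corneal_power, iol_power

eye = EyeBiometry(axial_length=28.43, acd=3.62, mean_corneal_radius=8.79, sa8=3.69)

print(f"Eye: AL {eye.axial_length} mm, ACD {eye.acd} mm, "
      f"r {eye.mean_corneal_radius} mm, SA8 {eye.sa8} um")
print(f"{'formula':<20} {'corneal power Z':>16} {'IOL power (plano)':>18}")
for fid in FORMULA_IDS:
    z = effective_corneal_power(eye, fid)
    p = iol_power(eye, fid, target_se=0.0)
    print(f"{fid:<20} {z:>14.2f} D {p:>16.2f} D")
print("\nZ is the effective corneal power each variant feeds the thin-lens "
      "formula;\nthe IOL power is the (continuous) power targeting plano.")
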