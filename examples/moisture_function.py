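"""The soil moisture rate modifier, extended beyond field capacity.

The classic factor is 1.0 from field capacity down to 44.4 % of the maximum
deficit, then declines to 0.2 at the driest state.  The extension mirrors
this on the wet side: from 1.0 at field capacity (SMD = 0) the factor falls
linearly to 0.2 at saturation, so waterlogged months decompose at a fifth
of the unconstrained rate.
"""

from rothc_grass import pedotransfer_water, rate_modifier_moisture

bounds = pedotransfer_water(clay=25.0, sand=40.0, silt=35.0, depth_cm=20.0)
print(
    f"loam over 20 cm: theta_fc {bounds.theta_fc:.3f}, theta_sat {bounds.theta_sat:.3f}"
)
print(
    f"deficit range: {bounds.smd_saturation:.1f} mm (saturation) .. "
    f"{bounds.max_smd_vegetated:.1f} mm (driest, vegetated)"
)
print("\n   SMD (mm)   b (extended)")
for frac in (1.0, 0.5, 0.0):
    smd = frac * bounds.smd_saturation
    b = rate_modifier_moisture(smd, bounds, extended=True)
    print(f"   {smd:8.1f}   {b:.2f}")
for frac in (0.3, 0.7, 1.0):
    smd = frac * bounds.max_smd_vegetated
    b = rate_modifier_moisture(smd, bounds, extended=True)
    print(f"   {smd:8.1f}   {b:.2f}")
print("b = 0.2 at saturation and at the maximum deficit; 1.0 on the plateau")
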