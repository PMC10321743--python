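"""The buckling length scale of confined microtubule bundles.

Balancing the elastic restoring force of a bundle (radius r, Young's modulus
E_Y) against the viscous drag that the extensile activity (rate Edot) exerts
through a confining fluid layer (viscosity mu, thickness h) gives the
wavelength of the initial buckling instability

    L = r [ (h/r) E_Y / (mu Edot) ]^(1/4)

With single-microtubule stiffness values this lands near 270 micrometers --
the observed spacing of same-charge topological defects is about 240 um.
"""

from spider2d.nematic_physics import BucklingParams, buckling_length

params = BucklingParams(
    radius=25e-9,          # m
    youngs_modulus=1e8,    # Pa
    viscosity=1e-3,        # Pa s
    layer_thickness=50e-6, # m
    extension_rate=0.015,  # 1/s
)
L = buckling_length(params)
print(f"buckling length L = {L * 1e6:.0f} micrometers")
print("(same order as the ~240 um mean spacing between same-charge defects)")
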