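"""Show what per-A-scan shadow compensation does to a shadowed scan.

A vessel above the retina attenuates everything beneath it, dimming a band
of columns. The compensation factor at a pixel is built from the signal at
and below it in its own column, so a multiplicative attenuation s rescales
compensated values by s^(1-exponent): with exponent 1 the shadow cancels
exactly, while the default exponent 2 additionally boosts contrast (and
over-corrects a pure attenuation). This example measures the dimmed/plain
column ratio inside the PED before and after compensation at exponent 1.
"""

import numpy as np

from pedci import PhantomSpec, compensate_shadows, generate_phantom, normalize_linear

base = dict(shape=(140, 200), dome_width_px=160, dome_height_px=60, seed=0)
plain = generate_phantom(PhantomSpec(**base))
shadowed = generate_phantom(PhantomSpec(shadow_columns=((90, 110, 0.5),), **base))

mask = plain.mask.mask
shadow_cols = np.zeros(200, dtype=bool)
shadow_cols[90:110] = True
in_shadowed_ped = mask & shadow_cols[None, :]

for label, image in (("before compensation", lambda t: normalize_linear(t.image).values),
                     ("after compensation",
                      lambda t: compensate_shadows(normalize_linear(t.image), exponent=1.0,
                                                   renormalize=False).values)):
    a = image(shadowed)[in_shadowed_ped]
    b = image(plain)[in_shadowed_ped]
    ratio = np.median(a / np.maximum(b, 1e-12))
    print(f"{label}: median shadowed/plain intensity ratio in the PED = {ratio:.3f}")
# Before compensation the shadowed columns sit at roughly the attenuation
# factor (0.5); after compensation the ratio returns to ~1 because the
# column's own residual energy scales with the same attenuation.
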