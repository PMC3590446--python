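"""Build the four deformable nodule templates and inspect their profiles.

Prints the decay parameter rho for the radius extremes of the nodule
range, the gray level along the radial profile, and the analytic
gray-level density that the matcher calibrates against.
"""

import numpy as np

from nodtemplate import (
    TemplateSpec,
    build_template,
    estimate_rho,
    gray_level_density,
    radial_profile,
)

# rho is pinned by the radius and the gray range: q(R) = q_min.
for R in (5, 30):
    print(f"R = {R:2d} px, q_max = 255, q_min = 61  ->  rho = {estimate_rho(R, 255, 61):.2f} px")

spec = TemplateSpec("circle", R=12.0, q_max=255.0, q_min=61.0)
print(f"\ncircle R = {spec.R}: q(0) = {radial_profile(spec, 0):.0f} (peak), "
      f"q(rho) = {radial_profile(spec, spec.rho):.1f} (peak/e), "
      f"q(R) = {radial_profile(spec, spec.R):.0f} (boundary)")

# The gray-level density: high mass near q_min (the wide rim), zero at q_max.
for q in (61.0, 150.0, 254.9):
    print(f"psi(q = {q:5.1f}) = {gray_level_density(spec, q):6.2f}")

# Rendered stencils: support pixel counts for each shape.
for shape, kwargs in [("circle", {}), ("semicircle", {"angle": 45.0}),
                      ("sphere", {}), ("hollow_sphere", {})]:
    img = build_template(TemplateSpec(shape, R=14.0, **kwargs))
    print(f"{shape:14s} R = 14: stencil {img.values.shape}, "
          f"{int(img.support.sum())} support pixels, "
          f"gray range [{img.values[img.support].min():.0f}, "
          f"{img.values[img.support].max():.0f}]")
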