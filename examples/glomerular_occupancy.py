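"""Glomerular occupancy and colocalization on synthetic section images.

Generates glomeruli whose reporter-labeled axons either fill the glomerulus
(control-like) or concentrate in a compartment covering 40% of it
(silencing-like), computes the multi-radius spatial-filter occupancy curves,
compares the groups by two-way ANOVA, and reports the colocalization
coefficient and equivalent diameter.
"""

from olfquant import (
    binarize,
    colocalization_coefficient,
    compare_occupancy,
    gen_glomerulus_image,
    glomerulus_diameter,
    occupancy_curve,
)

radii = (1, 2, 4, 6, 8, 11, 16)
curves = {"control": [], "compartmentalized": []}
for group, frac in (("control", 1.0), ("compartmentalized", 0.4)):
    for i in range(8):
        img = gen_glomerulus_image(roi_diameter_px=48, occupied_fraction=frac,
                                   seed=100 * (group == "control") + i)
        axon = binarize(img.channels["axon"], method=128.0)
        marker = binarize(img.channels["marker"], method=128.0)
        curves[group].append(occupancy_curve(axon, img.rois[0], radii))
        if i == 0:
            coloc = colocalization_coefficient(axon, marker, img.rois[0])
            diam = glomerulus_diameter(img.rois[0], img.pixel_size_um)
            print(f"{group:>17}: colocalization {coloc:5.1f}%  "
                  f"diameter {diam:.0f} um")

for group, cs in curves.items():
    mean = [sum(c.occupancy_pct[k] for c in cs) / len(cs) for k in range(len(radii))]
    print(f"{group:>17}: occupancy " +
          "  ".join(f"r={r}:{m:5.1f}%" for r, m in zip(radii, mean)))

res = compare_occupancy(curves)
print(f"group effect (two-way ANOVA): F = {res.f:.1f}, p = {res.p:.2e}")

# Fully innervated glomeruli sit at 100% at every filter radius; axons
# restricted to a compartment start low and only saturate when one filter
# covers the glomerulus — the group term of the ANOVA quantifies that contrast.
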