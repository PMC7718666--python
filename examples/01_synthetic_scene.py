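"""Generate one synthetic en-face angiogram and inspect its ground truth.

The scene emulates a superficial-plexus OCTA angiogram: a few large vessels
crossing the field, a capillary mesh, a central avascular zone and speckle
noise.  Everything the image pipeline will later estimate is known exactly.
"""

from octaquant.synthetic import AngioSceneParams, generate_vessel_network

truth = generate_vessel_network(AngioSceneParams(seed=42))

print(f"image: {truth.image.shape[0]}x{truth.image.shape[1]} px, "
      f"{truth.image.mm_per_pixel * 1000:.2f} um/px, plexus {truth.image.plexus}")
print(f"total centerline length: {truth.skeleton_length_mm:.1f} mm "
      f"({truth.large_length_mm:.1f} mm large vessels, "
      f"{truth.capillary_length_mm:.1f} mm capillaries)")
print(f"FAZ area: {truth.faz_polygon.area_mm2:.3f} mm^2 "
      f"(centroid {truth.faz_polygon.centroid[0]:.2f}, {truth.faz_polygon.centroid[1]:.2f} mm)")
print(f"vessel pixels: {truth.vessel_mask.sum()} "
      f"({truth.large_vessel_mask.sum()} large)")

# The analytic centerline length is the reference every downstream
# length-based metric is validated against.
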