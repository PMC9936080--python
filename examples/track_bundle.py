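"""CoG-seeded deterministic tractography on a synthetic language-tract stand-in.

Builds a curved (quarter-circle) high-FA corridor in an isotropic background,
seeds streamlines at the bundle midpoint (the role a hotspot CoG plays in the
real analysis), and prints the recovered streamline count, mean length and
mean FA against the known ground truth.
"""

import numpy as np

from stimmap import BundleSpec, TrackingParams, gen_tensor_bundle, track_streamlines, tract_stats

spec = BundleSpec(kind="arc", arc_radius=40.0, fa_inside=0.8, fa_background=0.05)
vol, centerline = gen_tensor_bundle(spec, seed=0)
seed_point = centerline[len(centerline) // 2]

params = TrackingParams()  # FA floor 0.1 and 50% of local FA max; min length 20 mm
lines = track_streamlines(vol, seed_point, params)
stats = tract_stats(lines, vol)

print(f"seeded at {np.round(seed_point, 1)} mm on the bundle centerline")
print(f"streamlines surviving the {params.min_length:.0f} mm filter: {stats.count}")
print(f"mean tract length: {stats.mean_length:.1f} mm "
      f"(ground-truth arc length {np.pi * spec.arc_radius / 2:.1f} mm)")
print(f"mean FA along streamlines: {stats.mean_fa:.3f} (corridor target {spec.fa_inside})")
print("-> deterministic principal-eigenvector tracking recovers the constructed "
      "bundle's geometry; a 15 mm bundle would be removed entirely by the length filter.")
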