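"""Run the whole comparison pipeline end to end and inspect the report.

One seeded call executes phantom construction, cohort generation, both field
solves, the overlap analysis, CoG-seeded tractography and the outcome
statistics, returning a JSON-serializable report.  Equivalent to the CLI:

    stimmap run-all --seed 11 --out report.json
"""

import json

from stimmap import PipelineConfig, run_pipeline

config = PipelineConfig(seed=5, spacing=3.0)  # 3 mm grid: ~10 s; 2.0 for full detail
report = run_pipeline(config)

c = report["cohort"]
print(f"cohort: mean CoG distance {c['mean_mm']:.2f} +/- {c['sd_mm']:.2f} mm over "
      f"{len(c['distances_mm'])} subjects")
f = report["fields"]
print(f"fields (subject 0, coil over its nTMS CoG): overlap {f['overlap_percent']:.1f} % "
      f"of the {f['ntms_halfmax_area_mm2']:.0f} mm^2 nTMS half-max area in the DES ROI")
for modality, t in report["tracts"].items():
    print(f"tracts [{modality}]: {t['count']} streamlines, "
          f"mean length {t['mean_length_mm']:.1f} mm, mean FA {t['mean_fa']:.3f}")
w = report["wab"]
print(f"WAB: preop p={w['preop']['p']:.3f} (groups drawn from near-identical "
      f"distributions), postop p={w['postop']['p']:.4f} (nTMS group scores higher)")
print(f"provenance: config {report['provenance']['config_hash']}, "
      f"seed {report['provenance']['seed']} -> rerunning reproduces every "
      "deterministic field bit-identically")

with open("pipeline_report.json", "w") as fh:
    json.dump(report, fh, indent=2, sort_keys=True)
print("full report written to pipeline_report.json")
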