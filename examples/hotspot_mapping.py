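"""From stimulation-trial records to hotspots, CoGs and paired distances.

Generates a 9-subject synthetic cohort of paired DES/nTMS positive sites with
the displacement statistics observed clinically (6.32 +/- 2.6 mm), applies
the run-of-three positivity rule to simulated trial sequences, and prints the
per-subject CoG distances with their mean and 95% confidence interval.
"""

import numpy as np

from stimmap import (
    CohortSpec,
    center_of_gravity,
    cog_distance,
    confidence_interval,
    detect_hotspots,
    gen_hotspot_cohort,
    gen_trial_records,
)

# the positivity rule on raw trial sequences: a site counts as a hotspot when
# the counting task is interrupted in three consecutive trials
sites = np.array([[0.0, 0.0, 78.0], [8.0, 0.0, 77.0], [0.0, 9.0, 77.0]])
trials, truth = gen_trial_records(sites, p_interrupt=[1.0, 0.6, 0.1], n_trials=5, seed=4)
hs = detect_hotspots(trials)
print(f"{len(hs)} of {len(sites)} sites positive under the run-of-three rule "
      f"(ground truth {int(truth.sum())})")

# paired cohort: every subject has DES sites on the cortex and nTMS sites
# displaced tangentially by a truncated-normal amount
subjects = gen_hotspot_cohort(CohortSpec(n_subjects=9), seed=1)
d = np.array([cog_distance(center_of_gravity(s.ntms), center_of_gravity(s.des)) for s in subjects])
lo, hi = confidence_interval(d)
print("per-subject CoG distances [mm]:", np.round(d, 2))
print(f"mean {d.mean():.2f} mm, SD {d.std(ddof=1):.2f} mm, 95% CI {lo:.2f}-{hi:.2f} mm")
print("-> compares with the clinically observed 6.32 +/- 2.6 mm separation of "
      "preoperative and intraoperative language sites.")
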