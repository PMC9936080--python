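"""Group comparisons of language outcome (WAB) scores.

Computes the Welch t-test directly from the published-style (mean, SD, n)
summaries for the pre- and postoperative comparisons, then regenerates raw
synthetic cohorts at the same parameters and shows that the test on samples
agrees, including a power estimate at the postoperative effect size.
"""

import numpy as np

from stimmap import GroupSummary, OutcomeSpec, gen_outcome_scores, t_test, t_test_from_summaries
from stimmap.synthetic import WAB_POSTOP, WAB_PREOP

for name, groups in (("preoperative", WAB_PREOP), ("postoperative", WAB_POSTOP)):
    a = GroupSummary(*groups[0][1:])
    b = GroupSummary(*groups[1][1:])
    res = t_test_from_summaries(a, b, kind="welch")
    print(f"{name:14s}: {groups[0][0]} {a.mean}+/-{a.sd} (n={a.n}) vs "
          f"{groups[1][0]} {b.mean}+/-{b.sd} (n={b.n}) -> Welch t={res.statistic:.2f}, "
          f"df={res.df:.1f}, p={res.p:.4f}")

samples = gen_outcome_scores(OutcomeSpec(groups=WAB_POSTOP), seed=2)
res = t_test(samples["ntms"], samples["non_ntms"])
print(f"same test on one regenerated cohort: p={res.p:.4f}")

rng = np.random.default_rng(3)
power = np.mean(
    [t_test(rng.normal(78.4, 10.4, 9), rng.normal(59.5, 8.8, 7)).p < 0.05 for _ in range(500)]
)
print(f"power at the postoperative effect size (500 replicates): {100 * power:.0f} %")
print("-> the preoperative groups are indistinguishable; the postoperative "
      "difference is detected essentially every time at these group sizes.")
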