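"""Randomization test for the effect-size change pattern across task groups.

Question: when the clinical cohort is split by severity (CAARMS = 0 vs > 0),
do the mirror-game effect sizes versus controls change much more than the
TMT effect sizes?  The statistic is

    T = min(median Solo change, median LF change) - median TMT change,

and the p-value compares the true severity split against random equal-size
splits of the clinical cohort.
"""

import numpy as np
import pandas as pd

from mirrortrail import bootstrap_pattern_test
from mirrortrail.records import FEATURE_NAMES, LF_FEATURES, SOLO_FEATURES

rng = np.random.default_rng(0)


def cohort(n, mg_shift=0.0, tmt_shift=0.0):
    df = pd.DataFrame(rng.normal(size=(n, 18)), columns=FEATURE_NAMES)
    df[list(SOLO_FEATURES + LF_FEATURES)] += mg_shift
    df[list(FEATURE_NAMES[:6])] += tmt_shift
    return df


cc = cohort(32)
# severity-graded movement effect: mild half shifted 0.5, severe half 1.5;
# TMT shifted equally in both halves (no severity gradient)
su = pd.concat([cohort(16, mg_shift=0.5, tmt_shift=1.2),
                cohort(16, mg_shift=1.5, tmt_shift=1.2)], ignore_index=True)
labels = np.arange(32) >= 16  # True marks the severe half

res = bootstrap_pattern_test(cc, su, labels, n=10_000, seed=4)
o = res.observed
print(f"median effect-size change: TMT {o.median_tmt:+.3f}  "
      f"Solo {o.median_solo:+.3f}  LF {o.median_lf:+.3f}")
print(f"observed pattern statistic T = {o.statistic:.3f}")
print(f"p-value over {res.n_splits} random splits: {res.p_value:.4f}")
print("\nSmall p: the graded movement effect is tied to the severity split --")
print("random splits of the clinical cohort almost never reproduce a pattern")
print("this strong. With no true gradient the p-value is uniform on [0, 1].")
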