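"""Summarise sequencing coverage over a captured target region.

Simulates a deep-capture depth profile over a 5 kb target: most bases draw
Poisson depths around 5000x while a small repeat-like stretch captures no
reads at all (absent bases count as 0x).  The summary reports the fraction
of target bases at or above each depth threshold and the mean depth.
"""

import numpy as np

from amlpanel import TargetRegion, coverage_summary

rng = np.random.default_rng(11)
target = TargetRegion("chr_demo", 0, 5000, "DEMO", 1, "exonic")
depths = {}
for pos in range(1, 5001):
    if 4000 < pos <= 4180:  # un-baitable repeat stretch: no coverage
        continue
    depths[("chr_demo", pos)] = int(rng.poisson(5000))

summary = coverage_summary(depths, [target], thresholds=[1, 10, 100, 1000])
print(f"mean depth {summary['mean_depth']:.0f}x over {summary['total_bases']} target bases")
for t, frac in summary["fractions"].items():
    print(f"  >= {t:>5}x: {100 * frac:5.1f}% of target bases")
print("\nThe uncovered stretch caps every fraction at ~96%; deep uniform")
print("coverage elsewhere is what lets the caller see subclones and")
print("residual disease at fractions of a percent of reads.")
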