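#!/usr/bin/env python
"""Apply the RT-based trial exclusions and recode responses.

Excludes trials with RT < 100 ms and RT more than 2.5 SD above the
participant's mean (experimenter-entered responses are never filtered),
then recodes responses into 'right first' / 'visual first' binaries with
the visual-first SOA sign convention.
"""

import argparse
from pathlib import Path

from toj.preprocess import filter_trials, load_trials

ap = argparse.ArgumentParser()
ap.add_argument("--trials", type=Path, default=Path("results/simulated/trials.csv"))
ap.add_argument("--out", type=Path, default=Path("results/preprocessed"))
args = ap.parse_args()

trials = load_trials(args.trials)
res = filter_trials(trials)
res.write(args.out)

s = res.summary()
print(f"{s['n_input']} trials in; excluded {s['n_excluded_fast']} fast, "
      f"{s['n_excluded_outlier']} slow outliers, "
      f"{s['n_excluded_missing_rt']} missing-RT "
      f"({100 * s['exclusion_fraction']:.1f}% of self-entered trials)")
print(f"wrote retained/excluded tables and summary to {args.out}")
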