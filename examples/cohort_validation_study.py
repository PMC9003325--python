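"""Run a scaled-down validation study end to end.

Generates a paired cohort (6 Parkinson's-like and 4 elderly-control
subjects, 3 cued trials each), runs both detection pipelines on every
trial, averages per subject and prints the group means plus the
method-agreement summary (Bland-Altman limits of agreement, Pearson r,
regression slope) across the five metrics.
"""

import gaitinit as gi

study = gi.run_study(groups=[(gi.GROUP_PRESETS["PD"], 6),
                             (gi.GROUP_PRESETS["ELD"], 4)],
                     n_trials=3, seed=1)

print("group means by source (s):")
cols = ["group", "source", "n_subjects"] + list(gi.METRIC_NAMES)
print(study.group_means[cols].round(3).to_string(index=False))

s = study.agreement.summary
print("\ncross-metric agreement, IMU vs force platform (mean over the five"
      " metrics):")
print(f"  LOA half-width  {s['loa_half_width_s']['mean']:.4f} s")
print(f"  CV              {s['cv_percent']['mean']:.2f} %")
print(f"  Pearson r       {s['pearson_r']['mean']:.4f}")
print(f"  slope           {s['slope']['mean']:.3f}")
print("\nA small LOA half-width and r near 1 mean the wearable reproduces")
print("the gold-standard timings at the subject level.")
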