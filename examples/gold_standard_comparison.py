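"""Compare the wearable detector against the force-platform gold standard
on one paired trial.

The same true events drive both synthetic recordings; the two detectors
run independently and the per-event differences show the wearable's timing
error at the single-trial level.
"""

import gaitinit as gi

spec = gi.SyntheticTrialSpec(t_apa=0.45, t_to=1.26, t_hs=1.73, seed=7,
                             trial_id="pair", subject_id="S1")
ev_imu, _ = gi.detect_events_imu(gi.synthesize_accel(spec),
                                 gi.EXTENDED_WINDOWS)
ev_fp = gi.detect_events_fp(gi.synthesize_forceplate(spec))

print("event            IMU [s]   platform [s]   difference [ms]")
for label, a, b in [("APA onset", ev_imu.apa_onset_s, ev_fp.apa_onset_s),
                    ("toe-off", ev_imu.toe_off_s, ev_fp.toe_off_s),
                    ("heel-strike", ev_imu.heel_strike_s,
                     ev_fp.heel_strike_s)]:
    print(f"{label:15s} {a:8.3f} {b:12.3f} {1000 * (a - b):12.1f}")
print("\nDifferences of a few milliseconds are well below the 7 ms sample")
print("interval of the 140 Hz accelerometer.")
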