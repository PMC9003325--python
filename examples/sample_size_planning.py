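"""Plan a Bland-Altman agreement study.

Given an expected bias and SD of between-method differences (here the
literature values for APA duration: bias -0.02 s, SD 0.13 s), compute the
minimum number of subjects for which, with 90 % power, both 95 %
limits-of-agreement confidence bounds fall inside a maximum allowed
difference delta.
"""

import gaitinit as gi

bias, sd = -0.02, 0.13
print(f"expected differences: bias {bias} s, SD {sd} s "
      f"(LOA half-width {1.96 * sd:.3f} s)")
print("delta [s]   minimum n  (alpha 0.05, power 0.90)")
for delta in (0.36, 0.40, 0.45, 0.50, 0.60):
    n = gi.ba_sample_size(bias, sd, delta, alpha=0.05, power=0.9)
    print(f"   {delta:.2f}      {n:5d}")
print("\nTighter allowed differences demand rapidly larger samples: the")
print("confidence bounds of the limits of agreement shrink only as 1/sqrt(n).")
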