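"""Wolpaw information transfer rate for six-class operating points.

Recomputes bits/selection and bits/min for a range of accuracies at
T = 0.4 s per selection (300 ms stimulus + 100 ms decision window).
"""

from pacbci import itr, selection_time

t = selection_time("cvep6", decision_window=0.1)
print(f"selection time T = {t} s\n")
print("accuracy   bits/selection   ITR (bits/min)")
for p in (1 / 6, 0.50, 0.75, 0.9251, 0.9463, 0.9662, 0.9991, 1.0):
    res = itr(6, p, t)
    print(f"{p:8.4f}   {res.bits_per_selection:14.4f}   "
          f"{res.bits_per_min:14.2f}")
print("\nChance (1/6) is worth 0 bits; perfect accuracy is log2(6) = 2.585")
print("bits per selection, i.e. 387.7 bits/min at 0.4 s per selection.")
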