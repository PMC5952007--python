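"""Scan all 21 band pairs of the canonical seven-band comodulogram.

Injects delta->theta coupling and shows that the (delta, theta) cell is
the largest of the 7*6/2 = 21 phase-amplitude pairs.
"""

import numpy as np

from pacbci import CANONICAL_BANDS, CouplingSpec, comodulogram, \
    gen_coupled_signal

FS = 250.0
x = gen_coupled_signal(CouplingSpec(depth=0.9), FS, 12.0,
                       noise_sigma=0.5, seed=7)
com = comodulogram(x, CANONICAL_BANDS, FS, method="iplv")

names = [b.name for b in com.bands]
print("phase \\ amplitude " + "".join(f"{n:>9}" for n in names))
for i, row in enumerate(com.values):
    cells = "".join("         " if not np.isfinite(v) else f"{v:9.3f}"
                    for v in row)
    print(f"{names[i]:<18}" + cells)

lf, hf = com.argmax_pair()
print(f"\nstrongest of {com.n_pairs} pairs: {lf.name} phase -> "
      f"{hf.name} amplitude (the injected pair)")
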