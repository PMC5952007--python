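"""Estimate delta->theta phase-amplitude coupling three ways.

Builds a 4 s synthetic trace whose 6 Hz (theta) amplitude is modulated by
the phase of a 2 Hz (delta) oscillation at depth 0.8, plus pink noise,
then prints the iPLV, PLV and MVL coupling estimates next to an uncoupled
control and a surrogate significance threshold.
"""

from pacbci import CANONICAL_BANDS, CouplingSpec, gen_coupled_signal, pac
from pacbci.cfc import pac_phases, surrogate_threshold, iplv

FS = 250.0
DELTA, THETA = CANONICAL_BANDS[0], CANONICAL_BANDS[1]

coupled = gen_coupled_signal(CouplingSpec(depth=0.8), FS, 4.0,
                             noise_sigma=0.3, seed=1)
uncoupled = gen_coupled_signal(CouplingSpec(depth=0.0), FS, 4.0,
                               noise_sigma=0.3, seed=1)

print("estimator   coupled  uncoupled")
for method in ("iplv", "plv", "mvl"):
    a = pac(coupled, DELTA, THETA, FS, method).value
    b = pac(uncoupled, DELTA, THETA, FS, method).value
    print(f"{method:<10}  {a:7.4f}  {b:9.4f}")

phi, phi_env, a_hf = pac_phases(uncoupled, DELTA, THETA, FS)
thr = surrogate_threshold(phi, phi_env, a_hf, "iplv", FS, seed=0)
print(f"\niPLV of the uncoupled control: {iplv(phi, phi_env):.4f}")
print(f"its 200-shift surrogate 95th percentile: {thr:.4f}")
print("The control stays below its surrogate threshold (not significant),")
print("while the coupled trace's iPLV is an order of magnitude larger.")
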