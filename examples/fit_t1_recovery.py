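"""Fit a magnitude inversion-recovery curve and apply the Look-Locker correction.

Simulates the 7-image hybrid (4+2+1) acquisition of a post-contrast
myocardium-like T1 at 68 bpm, rectifies the signed recovery to magnitude
(as scanner images are), adds noise, and refits the 3-parameter model
SI = |A - B exp(-TI/T1*)| with T1 = T1* (B/A - 1).
"""

import numpy as np

from molliecv import fit_ir, make_scheme, recovered_fraction, ti_schedule

TRUE_T1 = 420.0  # msec, post-contrast myocardium
A, B = 250.0, 500.0  # ideal inversion: B = 2A, so T1* = T1/ (B/A - 1)

scheme = make_scheme("hybrid_post")
tis = ti_schedule(scheme, rr_msec=882.0).ti_msec  # 68 bpm
rng = np.random.default_rng(7)
signal = np.abs(A - B * np.exp(-tis / TRUE_T1)) + rng.normal(0, 4, tis.size)

fit = fit_ir(list(zip(tis, np.abs(signal))))
print(f"sampled TIs (msec): {np.round(tis, 0)}")
print(f"fitted A = {fit.a:.1f}, B = {fit.b:.1f}, T1* = {fit.t1_star_msec:.1f} msec")
print(f"Look-Locker corrected T1 = {fit.t1_msec:.1f} msec (truth {TRUE_T1})")
print(f"valid fit: {fit.valid}, residual sum of squares: {fit.rss:.1f}")
frac = recovered_fraction(4 * 625.0, fit.t1_msec)
print(f"magnetization recovered after 4 beats at RR 625: {100 * frac:.1f}%")
# The corrected T1 lands within a few msec of truth; >99% recovery by four
# beats is why the post-contrast scheme can skip the fifth heart beat.
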