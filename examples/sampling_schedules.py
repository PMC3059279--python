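"""Compare cardiac-gated sampling schemes and their breath-hold cost.

Prints the effective-inversion-time schedule of the classic 3+3+5 scheme
and the two shortened hybrids at a 68 bpm heart rate, plus the number of
heart beats each acquisition occupies.
"""

from molliecv import breath_hold_beats, make_scheme, rr_from_heart_rate, ti_schedule

HR = 68
rr = rr_from_heart_rate(HR)
print(f"heart rate {HR} bpm -> R-R interval {rr:.0f} msec\n")

for kind in ("classic", "hybrid_pre", "hybrid_post"):
    scheme = make_scheme(kind)
    sched = ti_schedule(scheme, rr)
    print(f"{kind}: groups {scheme.samples_per_inversion}, "
          f"{scheme.total_images} images, {breath_hold_beats(scheme)} beats")
    for g in range(len(scheme.samples_per_inversion)):
        tis = [f"{ti:.0f}" for grp, _, ti in sched.entries if grp == g]
        print(f"  inversion {g}: TIeff = {', '.join(tis)} msec")
    print()
# Within a group TIeff steps by one R-R; group g starts at 90 + 80 g msec.
# The hybrids need 9 and 13 beats against 17 for classic — shorter breath
# holds and fewer inversions before full recovery.
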