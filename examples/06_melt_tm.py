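"""Extract melting temperatures from thermal-shift melt curves and report
the stability change of a mutant against its parent.

T_M is the extremum of the first derivative of the smoothed
fluorescence-vs-temperature curve (25-95 C, 1 C intervals).
"""

from nbmature import delta_tm, simulate_melt_curve, tm_from_melt

parent = simulate_melt_curve(43.38, noise_sd=2.0, seed=0)
mutant = simulate_melt_curve(50.74, noise_sd=2.0, seed=1)
tm_parent = tm_from_melt(parent).tm
tm_mutant = tm_from_melt(mutant).tm
print(f"parent T_M = {tm_parent:.2f} C (truth 43.38)")
print(f"mutant T_M = {tm_mutant:.2f} C (truth 50.74)")
print(f"delta T_M  = {delta_tm(tm_mutant, tm_parent):+.2f} C")
# A positive shift means the mutations stabilised the fold as well as
# improving the binding affinity.
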