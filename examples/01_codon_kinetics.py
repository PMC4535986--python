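"""Per-codon elongation kinetics at fixed free ternary-complex pools.

Builds the packaged (synthetic) E. coli parameter set and evaluates the
12-state elongation cycle for every codon, here naively using the *total*
tRNA concentrations as if they were all free — the comparison point that the
self-consistent solver (example 02) corrects.
"""

from elokin import ecoli_defaults, elongation_profile, overall_elongation_rate

m, kp, rp, cs = ecoli_defaults(growth_rate=2.5, pathway="2-3-2")
prof = elongation_profile(cs.X_total, m, kp)
t_mean, w = overall_elongation_rate(prof, cs.p)

print(f"overall elongation rate (total concentrations): {w:.2f} codons/s")
print("codon   t_elo[ms]  rate[1/s]  error frequency")
for c in ("CUG", "AAA", "AUA", "UGG"):
    p = prof.loc(c)
    print(f"{c}     {1e3 * p.t_elo:8.2f} {p.omega_elo:9.2f}  {p.P_nr:.2e}")
print(
    "\nFast codons are read by abundant cognate tRNAs (CUG); rare-tRNA codons"
    "\nwait longer for a cognate ternary complex and see more near-cognate"
    "\ncompetition, which raises their missense error frequency."
)
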