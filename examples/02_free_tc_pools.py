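"""Self-consistent free ternary-complex concentrations.

Active ribosomes sequester tRNA in their A, P and E sites and in the
recharging cycle, so the pool of free ternary complexes a ribosome can
actually bind is much smaller than the measured total tRNA concentration —
and the depletion is strongly species dependent.
"""

from elokin import ecoli_defaults, solve_self_consistent

m, kp, rp, cs = ecoli_defaults(growth_rate=2.5, pathway="2-3-2")
sol = solve_self_consistent(cs, kp, rp, m)

print(f"converged in {sol.iterations} sweeps (residual {sol.residual:.1e})")
print(f"overall elongation rate: {sol.omega_elo:.2f} codons/s")
print(f"free EF-Tu: {sol.E_free:.1f} of {cs.E_total:.1f} uM")
print("\ntRNA    total[uM]  free[uM]  free fraction")
for a in ("Ile2", "Lys", "Leu1", "Trp"):
    print(
        f"{a:6s} {cs.X_total[a]:9.2f} {sol.X_hat[a]:9.2f}"
        f"  {100 * sol.free_fraction[a]:6.1f} %"
    )
print(
    "\nIle2 reads only the rare codon AUA, so most of it stays free; Lys"
    "\nserves the heavily used codons AAA/AAG and is largely tied up on"
    "\nribosomes and in recharging."
)
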