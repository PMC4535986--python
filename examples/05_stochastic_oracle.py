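"""Stochastic simulation as an independent check of the analytic theory.

Samples the 12-state cycle by exact event-driven simulation and integrates
the master equation of a short mRNA, then compares both against the
analytic mean first-passage times.
"""

import numpy as np

from elokin import generate_fixture
from elokin.kinetics import codon_profile
from elokin.simulate import MRNA, evolve_mrna_probabilities, simulate_codon_cycle

m, kp, rp, cs = generate_fixture(seed=1)
cp = codon_profile(cs.X_total, m, m.codons[0], kp)

n = 50_000
times, outcomes = simulate_codon_cycle(cp.rates, n, seed=2024)
se = times.std(ddof=1) / np.sqrt(n)
print(f"analytic elongation time: {cp.t_elo:.4f} s")
print(f"simulated mean ({n} cycles): {times.mean():.4f} +- {se:.4f} s")
print(f"analytic error frequency: {cp.P_nr:.3e}, simulated: {(outcomes == 1).mean():.3e}")

mrna = MRNA(tuple(m.codons[:3]))
t_total = sum(codon_profile(cs.X_total, m, c, kp).t_elo for c in mrna.codons)
P = evolve_mrna_probabilities(mrna, cs.X_total, kp, m, [t_total])
print(f"\n3-codon mRNA, expected translation time {t_total:.3f} s")
print(f"master equation: P(terminated by t = <t>) = {P['terminated'].iloc[0]:.3f}")
print(
    "\nThe sampled mean sits within statistical error of the mean"
    "\nfirst-passage time, and the integrated master equation gives the full"
    "\ntime-dependent distribution over all 12 x L ribosomal states."
)
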