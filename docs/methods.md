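# Methods

## Model

Translation elongation on one codon is a continuous-time Markov chain on 12
transient states plus one absorbing "cycle complete" state.  The 20 arcs are:
from the empty A site (state 0) to cognate-bound (1), near-cognate-bound (6)
and non-cognate-bound (11); reversible initial binding (1→0, 6→0, 11→0, all
at the common dissociation rate `omega_off`, because dissociation precedes
codon-anticodon contact) and reversible codon recognition (1↔2, 6↔7, forward
at the common `omega_rec`); the irreversible selection cascade 2→3→4
(GTPase activation/GTP hydrolysis at `omega_23`/`omega_78`, then Pi release
and EF-Tu rearrangement at the common `omega_con`); rejection (4→0 at
`omega_40`, 9→0 at the proofreading rate `omega_90`) versus accommodation
(4→5 at `omega_45`, 9→10 at `omega_9_10`); and processing plus translocation
(5→done, 10→done at the common `omega_pro`).  Kinetic discrimination between
cognate and near-cognate complexes lives entirely in the branch-specific
rates (recognition reversal, GTPase activation, proofreading,
accommodation); a non-cognate complex always dissociates.

Codon specificity enters only through the three binding rates,
`kappa_on` times the summed free ternary-complex (TC) concentration over the
codon's cognate / near-cognate / non-cognate tRNA sets.  The cognacy
classification is data (a 61×43 table for E. coli), never derived at run
time.

### Elongation time and dwell times

`t_c` is the mean first-passage time 0→done, obtained from the linear
first-step system `(diag(exit) − W) t = 1` restricted to the transient
states reachable from 0 (a dense 12×12 solve; matrix exponentials would be
needless here).  Dwell times are `t_(c|i) = p_i · t_c` with `p` the
stationary distribution of the auxiliary process in which the arcs 5→done
and 10→done are redirected to state 0.  The implementation also computes the
expected sojourn times of the absorbing chain (a solve against the transpose
of the same matrix — numerically independent of the stationary solve) and
verifies both routes agree; the test suite asserts the identities
`sum_i t_(c|i) = t_c` and `p_i = t_(c|i)/t_c` to 1e-10 relative on random
rate sets, and a third, stochastic route (event-driven sampling) agrees
within statistical error.  Unreachable states (e.g. the near branch when no
near-cognate TC exists) carry dwell 0 by convention.

### Fidelity

Effective accommodation rates condense each branch into
`omega_co = omega_01 pi_12 pi_23 pi_45 / (1 − pi_12 pi_21)` and its
near-cognate mirror; the quotient `P_nr = omega_nr/(omega_co + omega_nr)` is
the probability that the accommodated aa-tRNA is near-cognate — the missense
error frequency.  The products of jump probabilities are exactly the
first-step-analysis absorption probabilities of the sub-chains, which the
tests verify independently.

### Free ternary-complex balance

At steady state every tRNA species `b` obeys

    X_free_b = X_total_b * [1 + omega_dis/(kappa_ass E_free)
        + R (Phi_co S1(b) + Phi_nr S2(b) + omega_elo tau_no S3(b))]^-1

where `S1` sums `P_co(c) p_c / sum_{a cognate to c} X_free_a` over the codons
cognate to `b`, `S2` the near-cognate analogue with `P_nr` and the
near-cognate pool, and `S3` ranges over the codons non-cognate to `b`
(weighted by their cognate pools: every elongation event briefly holds
non-cognate TCs of unrelated species).  The time constants `tau_co`,
`tau_nr`, `tau_no` are closed-form combinations of internal rates and branch
jump probabilities (mean bound time per accommodation, or per cycle for
non-cognates).  The sequestration factors are

    2-3-2:  Phi = 2 + omega_elo (tau + 1/omega_re + 1/(kappa_ass E_free))
    2-1-2:  Phi = 1 + omega_elo (tau + 1/omega_pro + 1/omega_re + 1/(kappa_ass E_free))

— the leading constant counts how many ribosomal tRNA sites hold a tRNA of
the species at translocation (P and E sites in 2-3-2, P site only in 2-1-2),
and the bracket adds transit through processing, recharging and TC
re-formation.

Free EF-Tu is fixed by conservation: the total pool splits into free EF-Tu,
EF-Tu inside free TCs, and EF-Tu inside ribosome-bound TCs (states
1–4, 6–9, 11, weighted by steady-state occupancies and the active-ribosome
concentration `R`).  The conservation form is this package's own closure of
the balance; its audit (total recovered to 1e-10 relative) is part of the
test suite.

### Solver

The coupled unknowns (free-TC vector, free EF-Tu, overall rate `omega_elo`,
per-codon accommodation probabilities) are iterated as a damped Picard map
`X ← (1−λ) X + λ RHS(X)` with λ = 0.5, tolerance 1e-10 (maximum relative
change of all unknowns), at most 10⁴ sweeps, initialized at
`X_free = X_total`; if the residual grows for five consecutive sweeps the
damping falls once to 0.1.  Free EF-Tu is floored at a tiny positive value
*during* iteration (transients can overshoot the pool) and re-audited
without the floor at the solution; an insufficient EF-Tu pool is an error,
not a clipped result.  Likewise, a cognate pool under 1e-15 uM for a used
codon aborts with the codon named — silent clipping would mask infeasible
parameter sets.  Fixed points satisfy `0 < X_free ≤ X_total` by construction
and are verified to be initialization independent.  `omega_elo` is
recomputed from the usage-weighted mean elongation time each sweep
(self-consistent mode) or pinned to a supplied measured value.

### Steady-state occupancy and perturbations

Because steady-state fluxes make codon position irrelevant, cell-wide
occupancy lives on 12×61 = 732 states: `P_c = p_c t_c / <t>` and
`P_{c,i} = p_c t_(c|i) / <t>`.  Usage scans set one codon's usage and
rescale all others proportionally (exactly normalization preserving);
overexpression replaces the usage vector by a gene's codon frequencies (the
strong-overexpression limit), with a convex-mixture option (default off) for
partial overexpression.  Scan points warm-start from the previous solution;
correctness is guarded by the initialization-independence property.  Gene
usage counts all sense codons of the CDS including the start codon and drops
the trailing stop (an internal stop is an error); this convention is a
deliberate choice and documented here because either inclusion rule is
defensible.

### Stochastic oracle

`simulate_codon_cycle` samples the exact process (exponential waiting times,
one uniform draw per jump against cumulative rates, one seeded generator per
run; the inner loop is numba-compiled with a numpy fallback).  Whole-mRNA
translation concatenates per-codon cycles for a single ribosome with frozen
TC pools — consistent with the mean-field balance, and valid at the low
ribosome densities the theory assumes; ribosome–ribosome interference is out
of scope.  `evolve_mrna_probabilities` integrates the master equation on the
12·L-state space (LSODA, rtol 1e-10) with an explicit terminal state so
total probability is conserved to 1e-8; simulation, integration and the
analytic first-passage times close a three-way consistency triangle in the
tests.

## Parameters and packaged data

Units are fixed package-wide: concentrations in uM, first-order rates in
s⁻¹, `kappa_on` and `kappa_ass` in uM⁻¹s⁻¹.  The packaged E. coli tables are
**synthetic reconstructions** (marked in filenames and headers):

- *Cognacy*: cognate assignments follow standard E. coli decoding (43
  elongator species covering all 61 sense codons); near-cognate means a
  non-cognate tRNA with a cognate codon at Hamming distance one from the row
  codon.  A measured classification can be dropped in as a TSV.
- *Rates*: one set per release pathway, chosen once for physiological
  plausibility — initial selection fast (`omega_off` 2×10⁴ s⁻¹, `omega_rec`
  10⁴ s⁻¹) so that non-cognate sampling is cheap, near-cognate GTPase
  activation slow (8 s⁻¹) and proofreading strong (400 vs 10 s⁻¹), giving
  error frequencies near 10⁻³–10⁻⁴ and overall rates of 10–25 codons/s.
- *Concentrations/usages*: plausible relative tRNA abundances (the same
  composition at all four growth rates, a simplification), ribosome and
  EF-Tu pools scaled with growth rate, and a genome-style usage vector whose
  fast-growth column fixes AAA at 4.67%.
- *lacZ-like CDS*: a deterministic 1023-codon sequence reproducing the real
  gene's salient biases (UGG enriched to ~3.9%, AAA depleted to ~1.5%).

Consequently the per-species numerical outputs (e.g. the exact free-TC
fraction of tRNA-Lys) are properties of these stand-ins, not predictions for
real E. coli; what the passing tests do establish is the internal
consistency of the theory (dwell/first-passage/stochastic agreement,
conservation laws, fixed-point properties) and its qualitative physiology
(species-dependent depletion, usage-driven slowdown and error increase,
stronger feedback for 2-3-2 release).  Quantitative agreement with measured
data requires supplying measured tables.

## Problem sizes and numerical choices

The test suite runs the full 61-codon balance a handful of times
(seconds each at tolerance 1e-10), 20-point usage scans at tolerance 1e-8,
and stochastic comparisons at 10⁴–10⁵ samples with 3-standard-error bands —
sizes chosen so the whole suite completes in about a minute while keeping
every comparison statistically meaningful.  Degenerate inputs are errors,
not silent fallbacks: a reachable state without exit, a process without an
absorbing path, both accommodation rates zero, unnormalized usage vectors.

## Known limitations

- Ribosome–ribosome interactions (traffic), initiation and termination
  kinetics are out of scope; the balance treats the elongating pool in
  mean field.
- Internal rates are codon independent by model assumption; wobble-dependent
  internal kinetics would need per-codon rate tables.
- The recharging cycle is a single effective rate per species
  (`omega_re`); explicit synthetase kinetics are not modelled.
- Time-dependent whole-transcriptome master equations (≈3.6×10⁶ states) are
  intentionally unsupported; time dependence is available per mRNA.
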