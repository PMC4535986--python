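"""Exact stochastic simulation and master-equation integration.

These routines are deliberately independent of the analytic machinery in
:mod:`elokin.kinetics`: they sample the very same continuous-time Markov
process by exponential waiting times and categorical jumps, and integrate its
master equation numerically, so that mean elongation times, error
frequencies and occupancy probabilities can be cross-checked three ways
(analytic, sampled, integrated).

A single ribosome is simulated; the free ternary-complex pools are frozen
during a run, consistent with the mean-field treatment (one ribosome cannot
measurably deplete cellular pools).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.integrate import solve_ivp

from elokin.cognacy import SENSE_CODONS, STOP_CODONS, CognacyMatrix
from elokin.errors import NoAbsorptionError, ValidationError
from elokin.kinetics import (
    ABSORBING,
    N_STATES,
    CodonRateSet,
    KineticParams,
    binding_rates,
    build_generator,
)

__all__ = [
    "MRNA",
    "Trajectory",
    "simulate_codon_cycle",
    "simulate_mrna",
    "simulate_mrna_ensemble",
    "evolve_mrna_probabilities",
]

OUTCOME_COGNATE = 0
OUTCOME_NEAR = 1

try:  # jit-compiled jump loop; pure-numpy fallback below
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f

        return deco


@_njit(cache=False)
def _sample_cycles_jit(cumP, exit_rate, n, seed, absorbing):  # pragma: no cover
    np.random.seed(seed)
    times = np.empty(n)
    outcomes = np.zeros(n, dtype=np.int8)
    for k in range(n):
        s = 0
        t = 0.0
        while True:
            t += -np.log(np.random.random()) / exit_rate[s]
            u = np.random.random()
            nxt = np.searchsorted(cumP[s], u)
            if nxt == absorbing:
                if s == 10:
                    outcomes[k] = 1
                times[k] = t
                break
            s = nxt
    return times, outcomes


def _sample_cycles_numpy(cumP, exit_rate, n, seed, absorbing):
    rng = np.random.default_rng(seed)
    state = np.zeros(n, dtype=np.int64)
    t = np.zeros(n)
    outcome = np.zeros(n, dtype=np.int8)
    alive = np.arange(n)
    while alive.size:
        s = state[alive]
        t[alive] += rng.exponential(1.0, size=alive.size) / exit_rate[s]
        u = rng.random(alive.size)
        nxt = (u[:, None] > cumP[s]).sum(axis=1)
        finishing = nxt == absorbing
        if finishing.any():
            outcome[alive[finishing]] = np.where(
                s[finishing] == 10, OUTCOME_NEAR, OUTCOME_COGNATE
            )
        state[alive] = nxt
        alive = alive[~finishing]
    return t, outcome


@dataclass(frozen=True)
class MRNA:
    """An mRNA coding sequence as an ordered tuple of sense codons (stop excluded)."""

    codons: tuple[str, ...]

    def __post_init__(self):
        if not self.codons:
            raise ValidationError("mRNA must contain at least one codon")
        for x, c in enumerate(self.codons, start=1):
            if c not in SENSE_CODONS:
                raise ValidationError(f"codon {c!r} at position {x} is not a sense codon")

    def __len__(self) -> int:
        return len(self.codons)

    @property
    def n_states(self) -> int:
        """Size of the translation state space for this mRNA (12 per codon)."""
        return N_STATES * len(self.codons)

    @classmethod
    def from_sequence(cls, seq: str) -> "MRNA":
        s = str(seq).strip().upper().replace("T", "U")
        if len(s) % 3 != 0:
            raise ValidationError(f"sequence length {len(s)} not divisible by 3")
        triplets = [s[i : i + 3] for i in range(0, len(s), 3)]
        if triplets and triplets[-1] in STOP_CODONS:
            triplets = triplets[:-1]
        return cls(tuple(triplets))

    @classmethod
    def from_fasta(cls, path) -> "MRNA":
        rec = next(SeqIO.parse(str(path), "fasta"))
        return cls.from_sequence(str(rec.seq))


@dataclass
class Trajectory:
    """Event log of one ribosome translating one mRNA.

    ``times`` are the event times (strictly increasing), ``positions`` the
    1-based codon index and ``states`` the internal state 0..11 entered at
    each event.  ``completion_times`` holds the time at which each codon's
    cycle finished; ``outcomes`` whether the accommodated aa-tRNA was cognate
    (0) or near-cognate (1).
    """

    times: np.ndarray
    positions: np.ndarray
    states: np.ndarray
    completion_times: np.ndarray
    outcomes: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "position": self.positions, "state": self.states}
        )


def _check_absorbing(g: CodonRateSet) -> None:
    if not g.reachable()[ABSORBING]:
        raise NoAbsorptionError("no positive-rate path from state 0 to absorption")


def simulate_codon_cycle(
    g: CodonRateSet, n: int, seed=None, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``n`` independent elongation cycles of one codon.

    Returns ``(times, outcomes)``: the first-passage times from state 0 to
    completion and, per sample, whether the accommodated aa-tRNA was cognate
    (``OUTCOME_COGNATE``) or near-cognate (``OUTCOME_NEAR``).  The walkers
    are advanced in lockstep with vectorized exponential waiting times and a
    single uniform draw per jump; runs are reproducible under a fixed seed.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    _check_absorbing(g)
    if rng is None:
        rng = np.random.default_rng(seed)
    W = g.W
    exit_rate = W.sum(axis=1)
    # guard against division by zero on the absorbing row (never visited)
    safe_exit = np.where(exit_rate > 0, exit_rate, 1.0)
    cumP = np.cumsum(W / safe_exit[:, None], axis=1)
    run_seed = int(rng.integers(0, 2**31 - 1))
    if _HAVE_NUMBA:
        return _sample_cycles_jit(cumP, safe_exit, int(n), run_seed, ABSORBING)
    return _sample_cycles_numpy(cumP, safe_exit, int(n), run_seed, ABSORBING)


def _codon_generators(mrna: MRNA, X_hat, kp: KineticParams, cmap: CognacyMatrix):
    x = pd.Series(X_hat)
    gens = {}
    for c in set(mrna.codons):
        gens[c] = build_generator(binding_rates(x, cmap, c, kp), kp)
    return gens


def simulate_mrna(
    mrna: MRNA, X_hat, kp: KineticParams, cmap: CognacyMatrix, seed=None
) -> Trajectory:
    """Simulate one ribosome translating the mRNA from first to last codon.

    The translation process is the concatenation of the codon-specific
    cycles; the total time is the sum of the per-codon first-passage times.
    """
    rng = np.random.default_rng(seed)
    gens = _codon_generators(mrna, X_hat, kp, cmap)
    for g in gens.values():
        _check_absorbing(g)
    times, positions, states = [], [], []
    completion = np.empty(len(mrna))
    outcomes = np.empty(len(mrna), dtype=np.int8)
    t = 0.0
    for x, c in enumerate(mrna.codons, start=1):
        W = gens[c].W
        exit_rate = W.sum(axis=1)
        s = 0
        while True:
            lam = exit_rate[s]
            t += rng.exponential(1.0 / lam)
            u = rng.random()
            cum = np.cumsum(W[s]) / lam
            nxt = int(np.searchsorted(cum, u, side="right"))
            if nxt == ABSORBING:
                outcomes[x - 1] = OUTCOME_NEAR if s == 10 else OUTCOME_COGNATE
                completion[x - 1] = t
                break
            s = nxt
            times.append(t)
            positions.append(x)
            states.append(s)
    return Trajectory(
        times=np.asarray(times),
        positions=np.asarray(positions, dtype=np.int64),
        states=np.asarray(states, dtype=np.int64),
        completion_times=completion,
        outcomes=outcomes,
    )


def simulate_mrna_ensemble(
    mrna: MRNA, X_hat, kp: KineticParams, cmap: CognacyMatrix, n: int, seed=None
) -> np.ndarray:
    """Total translation times of ``n`` independent ribosomes (vectorized).

    Per-codon cycles are independent, so the ensemble is generated codon by
    codon with :func:`simulate_codon_cycle` and summed.
    """
    rng = np.random.default_rng(seed)
    gens = _codon_generators(mrna, X_hat, kp, cmap)
    total = np.zeros(n)
    for c in mrna.codons:
        t, _ = simulate_codon_cycle(gens[c], n, rng=rng)
        total += t
    return total


def _mrna_generator_matrix(mrna: MRNA, X_hat, kp: KineticParams, cmap: CognacyMatrix):
    """Dense rate matrix on the 12*L + 1 state space (terminal state last).

    State (x, i) maps to index 12*(x-1) + i; completion of the last codon
    feeds an absorbing 'terminated' state so that total probability is
    conserved.
    """
    L = len(mrna)
    gens = _codon_generators(mrna, X_hat, kp, cmap)
    dim = N_STATES * L + 1
    W = np.zeros((dim, dim))
    for x, c in enumerate(mrna.codons):
        g = gens[c].W
        base = N_STATES * x
        W[base : base + N_STATES, base : base + N_STATES] = g[:N_STATES, :N_STATES]
        nxt = N_STATES * (x + 1) if x + 1 < L else dim - 1
        W[base + 5, nxt] = g[5, ABSORBING]
        W[base + 10, nxt] = g[10, ABSORBING]
    return W


def evolve_mrna_probabilities(
    mrna: MRNA,
    X_hat,
    kp: KineticParams,
    cmap: CognacyMatrix,
    t_grid,
    p0: np.ndarray | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> pd.DataFrame:
    """Integrate the master equation of single-ribosome translation.

    Returns a table indexed by the requested times whose columns are the
    ``12 * L`` states ``pos<x>_state<i>`` plus ``terminated``.  The initial
    distribution defaults to all mass on the first codon's empty-A-site
    state.  Total probability is conserved (columns sum to 1 at every time).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if (np.diff(t_grid) < 0).any() or (t_grid < 0).any():
        raise ValidationError("t_grid must be nonnegative and nondecreasing")
    W = _mrna_generator_matrix(mrna, X_hat, kp, cmap)
    dim = W.shape[0]
    Q = W.T - np.diag(W.sum(axis=1))  # dP/dt = Q P with column-stochastic flow
    if p0 is None:
        p0 = np.zeros(dim)
        p0[0] = 1.0
    else:
        p0 = np.asarray(p0, dtype=float)
        if p0.shape != (dim,):
            raise ValidationError(f"p0 must have shape ({dim},)")
        if abs(p0.sum() - 1.0) > 1e-9:
            raise ValidationError("p0 must be normalized")

    # the initial distribution is defined at time 0; integrate forward from there
    t1 = float(t_grid[-1])
    if t1 == 0.0:
        sol_y = np.tile(p0[:, None], (1, len(t_grid)))
    else:
        res = solve_ivp(
            lambda _, y: Q @ y,
            (0.0, t1),
            p0,
            t_eval=t_grid,
            method="LSODA",
            rtol=rtol,
            atol=atol,
        )
        if not res.success:
            raise ValidationError(f"master-equation integration failed: {res.message}")
        sol_y = res.y
    sums = sol_y.sum(axis=0)
    if np.max(np.abs(sums - 1.0)) > 1e-8:
        raise ValidationError("probability not conserved during integration")
    cols = [
        f"pos{x}_state{i}" for x in range(1, len(mrna) + 1) for i in range(N_STATES)
    ] + ["terminated"]
    return pd.DataFrame(sol_y.T, index=t_grid, columns=cols)
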