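"""The twelve-state elongation cycle of a single codon.

States (A-site of a ribosome reading codon ``c``)::

    0   empty A site
    1-5  cognate branch: initial binding (1), codon recognition (2), GTPase
         activation / GTP hydrolysis (3), Pi release and EF-Tu rearrangement
         (4), aa-tRNA accommodation with EF-Tu release (5)
    6-10 near-cognate branch, mirror of 1-5
    11  non-cognate ternary complex bound (always dissociates)
    12  absorbing state: elongation cycle complete, ribosome on next codon

The 20 arcs of the process::

    0->1,6,11 (binding, concentration dependent)   1->0, 6->0, 11->0 (omega_off)
    1->2, 6->7 (omega_rec)    2->1 (omega_21)   2->3 (omega_23)
    3->4, 8->9 (omega_con)    4->0 (omega_40)   4->5 (omega_45)
    7->6 (omega_76)  7->8 (omega_78)  9->0 (omega_90)  9->10 (omega_9_10)
    5->12, 10->12 (omega_pro: peptide-bond formation + translocation)

Only the three binding rates depend on the codon; the 12 internal rates are
codon independent.  The elongation time ``t_elo`` of a codon is the mean
first-passage time from state 0 to state 12.  Dwell times per state come from
the stationary distribution of an auxiliary process in which absorption is
identified with the initial state; the module computes them by two
mathematically independent routes and checks their agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from elokin.cognacy import CognacyMatrix
from elokin.errors import (
    DegenerateStateError,
    NoAbsorptionError,
    UndefinedFidelityError,
    ValidationError,
)

__all__ = [
    "N_STATES",
    "ABSORBING",
    "EFTU_STATES",
    "PATHWAY_212",
    "PATHWAY_232",
    "KineticParams",
    "CodonRateSet",
    "CodonProfile",
    "ElongationProfile",
    "binding_rates",
    "build_generator",
    "transition_probabilities",
    "mean_first_passage_time",
    "auxiliary_stationary",
    "dwell_times",
    "effective_accommodation_rates",
    "accommodation_probabilities",
    "codon_profile",
    "elongation_profile",
]

N_STATES = 12  # transient states 0..11
ABSORBING = 12  # index of the absorbing "cycle complete" state

#: transient states in which an EF-Tu molecule is part of the ribosome-bound
#: ternary complex (all bound states before accommodation).
EFTU_STATES = (1, 2, 3, 4, 6, 7, 8, 9, 11)

#: transient states in which a tRNA of the incoming ternary complex is bound.
TC_BOUND_STATES = (1, 2, 3, 4, 6, 7, 8, 9, 11)

PATHWAY_212 = "2-1-2"
PATHWAY_232 = "2-3-2"

_INTERNAL_RATES = (
    "omega_off",
    "omega_rec",
    "omega_21",
    "omega_23",
    "omega_con",
    "omega_40",
    "omega_45",
    "omega_76",
    "omega_78",
    "omega_90",
    "omega_9_10",
    "omega_pro",
)


@dataclass(frozen=True)
class KineticParams:
    """Codon-independent rates of the elongation cycle.

    ``kappa_on`` is the ternary-complex binding rate constant (uM^-1 s^-1),
    identical for cognate, near-cognate and non-cognate complexes.  The twelve
    internal rates (s^-1) follow the equalities of the model:
    ``omega_rec`` = rate 1->2 = 6->7 (codon recognition),
    ``omega_con`` = rate 3->4 = 8->9 (Pi release / EF-Tu rearrangement),
    ``omega_pro`` = rate 5->done = 10->done (processing + translocation),
    ``omega_off`` = rate 1->0 = 6->0 = 11->0 (initial dissociation).
    """

    kappa_on: float
    omega_off: float
    omega_rec: float
    omega_21: float
    omega_23: float
    omega_con: float
    omega_40: float
    omega_45: float
    omega_76: float
    omega_78: float
    omega_90: float
    omega_9_10: float
    omega_pro: float
    pathway: str = PATHWAY_212

    def __post_init__(self):
        if self.pathway not in (PATHWAY_212, PATHWAY_232):
            raise ValidationError(f"unknown pathway {self.pathway!r}")
        if self.kappa_on <= 0:
            raise ValidationError("kappa_on must be positive")
        for name in _INTERNAL_RATES:
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")

    def with_pathway(self, pathway: str) -> "KineticParams":
        return replace(self, pathway=pathway)


@dataclass(frozen=True)
class CodonRateSet:
    """Full rate matrix of the 13-state (12 transient + absorbing) process.

    ``W[i, j]`` is the transition rate i -> j; entries outside the 20 arcs of
    the model are zero.  ``omega_01``, ``omega_06``, ``omega_0_11`` are the
    concentration-dependent binding rates used to build the matrix.
    """

    W: np.ndarray
    omega_01: float
    omega_06: float
    omega_0_11: float
    params: KineticParams

    @property
    def exit_rates(self) -> np.ndarray:
        """Total outgoing rate per state (length 13; absorbing row is 0)."""
        return self.W.sum(axis=1)

    def reachable(self) -> np.ndarray:
        """Boolean mask over the 13 states reachable from state 0 (cached)."""
        cached = getattr(self, "_reach", None)
        if cached is not None:
            return cached
        seen = np.zeros(N_STATES + 1, dtype=bool)
        stack = [0]
        seen[0] = True
        while stack:
            i = stack.pop()
            for j in np.flatnonzero(self.W[i] > 0):
                if not seen[j]:
                    seen[j] = True
                    stack.append(int(j))
        object.__setattr__(self, "_reach", seen)
        return seen


def binding_rates(
    X_hat, m: CognacyMatrix, codon: str, kp: KineticParams
) -> tuple[float, float, float]:
    """Concentration-dependent binding rates (omega_01, omega_06, omega_0_11).

    Each rate is ``kappa_on`` times the summed free ternary-complex
    concentration over the cognate, near-cognate or non-cognate tRNA set of
    the codon.

    Parameters
    ----------
    X_hat : mapping or pandas Series of free TC concentrations (uM), indexed
        by the tRNA names of ``m``.
    """
    x = pd.Series(X_hat).reindex(list(m.trnas))
    if x.isna().any():
        missing = list(x.index[x.isna()])
        raise KeyError(f"free-TC concentrations missing for tRNAs {missing}")
    if (x < 0).any():
        neg = list(x.index[x < 0])
        raise ValidationError(f"negative free-TC concentration for {neg}")
    if codon not in m.codons:
        raise KeyError(f"codon {codon!r} not in cognacy matrix")
    row = m.codon_row(codon)
    xv = x.to_numpy(dtype=float)
    from elokin.cognacy import COGNATE, NEAR, NON

    w01 = kp.kappa_on * xv[row == COGNATE].sum()
    w06 = kp.kappa_on * xv[row == NEAR].sum()
    w011 = kp.kappa_on * xv[row == NON].sum()
    return float(w01), float(w06), float(w011)


def build_generator(rates, kp: KineticParams) -> CodonRateSet:
    """Assemble the 13x13 rate matrix from binding rates and internal rates."""
    w01, w06, w011 = (float(r) for r in rates)
    if min(w01, w06, w011) < 0:
        raise ValidationError("binding rates must be nonnegative")
    W = np.zeros((N_STATES + 1, N_STATES + 1))
    W[0, 1] = w01
    W[0, 6] = w06
    W[0, 11] = w011
    W[1, 0] = kp.omega_off
    W[1, 2] = kp.omega_rec
    W[2, 1] = kp.omega_21
    W[2, 3] = kp.omega_23
    W[3, 4] = kp.omega_con
    W[4, 0] = kp.omega_40
    W[4, 5] = kp.omega_45
    W[5, ABSORBING] = kp.omega_pro
    W[6, 0] = kp.omega_off
    W[6, 7] = kp.omega_rec
    W[7, 6] = kp.omega_76
    W[7, 8] = kp.omega_78
    W[8, 9] = kp.omega_con
    W[9, 0] = kp.omega_90
    W[9, 10] = kp.omega_9_10
    W[10, ABSORBING] = kp.omega_pro
    W[11, 0] = kp.omega_off
    return CodonRateSet(W=W, omega_01=w01, omega_06=w06, omega_0_11=w011, params=kp)


def transition_probabilities(g: CodonRateSet) -> np.ndarray:
    """Jump-chain probabilities pi[i, j] = W[i, j] / sum_k W[i, k].

    Rows of unreachable states are left as zeros (undefined but unused);
    a *reachable* transient state with zero total outgoing rate raises
    :class:`DegenerateStateError`.
    """
    out = g.exit_rates
    reach = g.reachable()
    pi = np.zeros_like(g.W)
    for i in range(N_STATES):
        if out[i] > 0:
            pi[i] = g.W[i] / out[i]
        elif reach[i]:
            raise DegenerateStateError(f"state {i} is reachable but has no outgoing rate")
    return pi


def _transient_matrix(g: CodonRateSet, states: np.ndarray) -> np.ndarray:
    """A = diag(exit) - W restricted to the given transient states."""
    W = g.W[np.ix_(states, states)]
    out = g.exit_rates[states]
    return np.diag(out) - W


def mean_first_passage_time(g: CodonRateSet) -> float:
    """Mean first-passage time 0 -> absorbing, by the linear first-step system.

    Solves ``(diag(exit) - W) t = 1`` over the transient states reachable
    from 0.
    """
    reach = g.reachable()
    if not reach[ABSORBING]:
        raise NoAbsorptionError("no positive-rate path from state 0 to absorption")
    states = np.flatnonzero(reach[:N_STATES])
    A = _transient_matrix(g, states)
    t = np.linalg.solve(A, np.ones(len(states)))
    return float(t[list(states).index(0)])


def auxiliary_stationary(g: CodonRateSet) -> np.ndarray:
    """Stationary distribution of the auxiliary (recurrent) process.

    The auxiliary process redirects the two absorbing arcs 5->done and
    10->done back to state 0 with the same rate omega_pro, turning the
    absorbing chain into a recurrent one whose stationary probabilities equal
    the dwell-time fractions of the original process.  Returns a length-12
    vector with zeros on states unreachable from 0.
    """
    reach = g.reachable()
    if not reach[ABSORBING]:
        raise NoAbsorptionError("no positive-rate path from state 0 to absorption")
    states = np.flatnonzero(reach[:N_STATES])
    Waux = g.W[:N_STATES, :N_STATES].copy()
    Waux[5, 0] += g.W[5, ABSORBING]
    Waux[10, 0] += g.W[10, ABSORBING]
    Wr = Waux[np.ix_(states, states)]
    Q = Wr - np.diag(Wr.sum(axis=1))  # generator, rows sum to zero
    n = len(states)
    # stationary: p Q = 0, sum p = 1 -> replace one column of Q^T by ones
    M = Q.T.copy()
    M[-1, :] = 1.0
    rhs = np.zeros(n)
    rhs[-1] = 1.0
    try:
        p = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as exc:
        raise DegenerateStateError(f"singular stationary system: {exc}") from exc
    if (p < -1e-12).any():
        raise DegenerateStateError("stationary solve produced negative probabilities")
    full = np.zeros(N_STATES)
    full[states] = np.clip(p, 0.0, None)
    full /= full.sum()
    return full


def dwell_times(
    g: CodonRateSet, cross_check_tol: float = 1e-8, cross_check: bool = True
) -> tuple[np.ndarray, float]:
    """Mean dwell time per state over one elongation cycle, and t_elo.

    The dwell times are ``t_i = p_aux_i * t_elo`` with the auxiliary-process
    stationary distribution ``p_aux`` and the mean first-passage time
    ``t_elo``.  They are cross-checked against the expected sojourn times of
    the absorbing process (fundamental-matrix route, an independent solve);
    disagreement beyond ``cross_check_tol`` (relative) raises.

    Unreachable states carry dwell 0 by convention.
    """
    t_elo = mean_first_passage_time(g)
    p_aux = auxiliary_stationary(g)
    dwell = p_aux * t_elo
    if not cross_check:
        return dwell, t_elo

    # independent route: row of the fundamental matrix of the absorbing chain
    reach = g.reachable()
    states = np.flatnonzero(reach[:N_STATES])
    A = _transient_matrix(g, states)
    e0 = np.zeros(len(states))
    e0[list(states).index(0)] = 1.0
    sojourn = np.linalg.solve(A.T, e0)
    dwell_abs = np.zeros(N_STATES)
    dwell_abs[states] = sojourn
    scale = max(t_elo, 1e-300)
    if np.max(np.abs(dwell - dwell_abs)) / scale > cross_check_tol:
        raise DegenerateStateError(
            "dwell-time routes disagree: auxiliary stationary vs absorbing sojourn"
        )
    return dwell, t_elo


def effective_accommodation_rates(g: CodonRateSet, pi: np.ndarray | None = None) -> tuple[float, float]:
    """Effective cognate and near-cognate accommodation rates.

    ``omega_co = omega_01 * pi_12 * pi_23 * pi_45 / (1 - pi_12 * pi_21)`` and
    the mirrored expression for the near-cognate branch.  Each equals the
    binding rate times the probability that a bound complex accommodates
    rather than dissociates (a first-step-analysis result).
    """
    if pi is None:
        pi = transition_probabilities(g)
    denom_co = 1.0 - pi[1, 2] * pi[2, 1]
    denom_nr = 1.0 - pi[6, 7] * pi[7, 6]
    if denom_co <= 0 or denom_nr <= 0:
        raise DegenerateStateError("recognition loop traps probability (pi product = 1)")
    w_co = g.omega_01 * pi[1, 2] * pi[2, 3] * pi[4, 5] / denom_co
    w_nr = g.omega_06 * pi[6, 7] * pi[7, 8] * pi[9, 10] / denom_nr
    return float(w_co), float(w_nr)


def accommodation_probabilities(omega_co: float, omega_nr: float) -> tuple[float, float]:
    """Probabilities that the accommodated aa-tRNA is cognate / near-cognate.

    ``P_nr`` is the near-cognate missense error frequency of the codon.
    """
    total = omega_co + omega_nr
    if total <= 0:
        raise UndefinedFidelityError("both accommodation rates vanish")
    p_co = omega_co / total
    return float(p_co), float(1.0 - p_co)


@dataclass(frozen=True)
class CodonProfile:
    """Per-codon kinetic summary."""

    codon: str
    t_elo: float
    omega_elo: float
    dwell: np.ndarray  # length 12
    omega_co: float
    omega_nr: float
    P_co: float
    P_nr: float
    rates: CodonRateSet


@dataclass
class ElongationProfile:
    """Kinetic summary for a set of codons at fixed free-TC concentrations."""

    codons: tuple[str, ...]
    t_elo: np.ndarray
    dwell: np.ndarray  # (n_codons, 12)
    omega_co: np.ndarray
    omega_nr: np.ndarray
    P_co: np.ndarray
    P_nr: np.ndarray

    def __post_init__(self):
        self.codons = tuple(self.codons)
        self._index = {c: i for i, c in enumerate(self.codons)}

    @property
    def omega_elo_c(self) -> np.ndarray:
        """Codon-specific elongation rates, 1 / t_elo."""
        return 1.0 / self.t_elo

    def loc(self, codon: str) -> CodonProfile:
        i = self._index[codon]
        return CodonProfile(
            codon=codon,
            t_elo=float(self.t_elo[i]),
            omega_elo=float(1.0 / self.t_elo[i]),
            dwell=self.dwell[i],
            omega_co=float(self.omega_co[i]),
            omega_nr=float(self.omega_nr[i]),
            P_co=float(self.P_co[i]),
            P_nr=float(self.P_nr[i]),
            rates=None,
        )

    def to_frame(self) -> pd.DataFrame:
        """Per-codon table with elongation times/rates and error frequencies."""
        return pd.DataFrame(
            {
                "codon": list(self.codons),
                "t_elo": self.t_elo,
                "omega_elo": self.omega_elo_c,
                "omega_co": self.omega_co,
                "omega_nr": self.omega_nr,
                "P_co": self.P_co,
                "P_nr": self.P_nr,
            }
        ).set_index("codon")


def codon_profile(X_hat, m: CognacyMatrix, codon: str, kp: KineticParams) -> CodonProfile:
    """Full kinetic characterization of one codon at given free-TC pools."""
    br = binding_rates(X_hat, m, codon, kp)
    g = build_generator(br, kp)
    pi = transition_probabilities(g)
    dwell, t_elo = dwell_times(g)
    w_co, w_nr = effective_accommodation_rates(g, pi)
    p_co, p_nr = accommodation_probabilities(w_co, w_nr)
    return CodonProfile(
        codon=codon,
        t_elo=t_elo,
        omega_elo=1.0 / t_elo,
        dwell=dwell,
        omega_co=w_co,
        omega_nr=w_nr,
        P_co=p_co,
        P_nr=p_nr,
        rates=g,
    )


def pool_sums(x: np.ndarray, m: CognacyMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-codon summed free-TC concentration over the three cognacy sets.

    ``x`` is the free-TC vector ordered like ``m.trnas``.  Returns three
    arrays ordered like ``m.codons``.
    """
    from elokin.cognacy import COGNATE, NEAR, NON

    x = np.asarray(x, dtype=float)
    return (
        (m.cls == COGNATE) @ x,
        (m.cls == NEAR) @ x,
        (m.cls == NON) @ x,
    )


def profile_from_pools(
    s_co: np.ndarray,
    s_nr: np.ndarray,
    s_no: np.ndarray,
    codons,
    kp: KineticParams,
) -> ElongationProfile:
    """Elongation profile from precomputed per-codon pool sums (fast path)."""
    codons = tuple(codons)
    n = len(codons)
    t_elo = np.empty(n)
    dwell = np.empty((n, N_STATES))
    w_co = np.empty(n)
    w_nr = np.empty(n)
    p_co = np.empty(n)
    p_nr = np.empty(n)
    for k in range(n):
        g = build_generator(
            (kp.kappa_on * s_co[k], kp.kappa_on * s_nr[k], kp.kappa_on * s_no[k]), kp
        )
        pi = transition_probabilities(g)
        # the two dwell routes are asserted equal in the test suite; the
        # solver hot path uses the stationary route alone
        dwell[k], t_elo[k] = dwell_times(g, cross_check=False)
        w_co[k], w_nr[k] = effective_accommodation_rates(g, pi)
        p_co[k], p_nr[k] = accommodation_probabilities(w_co[k], w_nr[k])
    return ElongationProfile(
        codons=codons, t_elo=t_elo, dwell=dwell, omega_co=w_co, omega_nr=w_nr, P_co=p_co, P_nr=p_nr
    )


def elongation_profile(X_hat, m: CognacyMatrix, kp: KineticParams, codons=None) -> ElongationProfile:
    """Kinetic summary for every codon of the matrix (or a subset)."""
    x = pd.Series(X_hat).reindex(list(m.trnas))
    if x.isna().any():
        missing = list(x.index[x.isna()])
        raise KeyError(f"free-TC concentrations missing for tRNAs {missing}")
    s_co, s_nr, s_no = pool_sums(x.to_numpy(dtype=float), m)
    if codons is None:
        return profile_from_pools(s_co, s_nr, s_no, m.codons, kp)
    idx = [m.codons.index(c) for c in codons]
    return profile_from_pools(s_co[idx], s_nr[idx], s_no[idx], codons, kp)
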