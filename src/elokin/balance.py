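"""Self-consistent steady-state balance of free ternary-complex pools.

Total tRNA concentrations are measured in vivo, but ribosomes only see the
*free* ternary complexes.  Each tRNA species ``b`` is distributed over free
TCs, free aa-tRNA / deacylated tRNA in the recharging cycle, and
ribosome-bound tRNA (A-, P- and E-site occupancy).  At steady state this
gives one implicit equation per species,

    X_free_b = X_total_b / (1 + omega_dis/(kappa_ass*E_free)
               + R * (Phi_co * sum_{c cognate to b} P_co(c) p_c / S_co(c)
                    + Phi_nr * sum_{c near-cog to b} P_nr(c) p_c / S_nr(c)
                    + omega_elo * tau_no * sum_{c non-cog to b} P_co(c) p_c / S_co(c)))

with S_co(c), S_nr(c) the summed free-TC pools of the cognate / near-cognate
sets of codon c.  The dimensionless sequestration factors Phi depend on the
E-site release pathway: for 2-3-2 release Phi = 2 + omega_elo*(tau + 1/omega_re
+ 1/(kappa_ass*E_free)); for 2-1-2 release Phi = 1 + omega_elo*(tau +
1/omega_pro + 1/omega_re + 1/(kappa_ass*E_free)).  The tau constants are
combinations of internal rates and branch transition probabilities.

The coupled unknowns (free-TC vector, free EF-Tu, overall elongation rate,
and the per-codon accommodation probabilities hidden inside the elongation
profile) are solved by damped fixed-point iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from elokin.cognacy import COGNATE, NEAR, NON, CognacyMatrix
from elokin.errors import (
    InfeasibleParametersError,
    NonConvergenceError,
    ValidationError,
)
from elokin.kinetics import (
    EFTU_STATES,
    PATHWAY_212,
    PATHWAY_232,
    ElongationProfile,
    KineticParams,
    pool_sums,
    profile_from_pools,
)

__all__ = [
    "CellState",
    "RechargingParams",
    "FreeTCSolution",
    "tau_constants",
    "phi_constants",
    "free_eftu",
    "free_tc_update",
    "solve_self_consistent",
]

#: cognate pools below this value (uM) for a used codon abort the solver
#: rather than being clipped, so infeasible parameter sets are not masked.
POOL_FLOOR = 1e-15


@dataclass(frozen=True)
class RechargingParams:
    """Ternary-complex formation and tRNA recharging constants.

    ``kappa_ass`` (uM^-1 s^-1) and ``omega_dis`` (s^-1) govern the
    association / dissociation of aa-tRNA with free EF-Tu:GTP; ``omega_re``
    (s^-1) is the effective rate at which a deacylated tRNA released from the
    E site is re-aminoacylated by its synthetase.
    """

    kappa_ass: float
    omega_dis: float
    omega_re: float

    def __post_init__(self):
        if self.kappa_ass <= 0:
            raise ValidationError("kappa_ass must be positive")
        if self.omega_dis < 0 or self.omega_re < 0:
            raise ValidationError("omega_dis and omega_re must be nonnegative")


@dataclass
class CellState:
    """Growth-condition inputs for the balance.

    ``X_total`` is the per-species total tRNA concentration (uM), ``R`` the
    concentration of actively translating ribosomes, ``E_total`` the total
    EF-Tu concentration, ``p`` the codon usage (fractions summing to 1 over
    the sense codons).
    """

    growth_rate: float
    X_total: pd.Series
    R: float
    E_total: float
    p: pd.Series
    pathway: str = PATHWAY_212

    def __post_init__(self):
        self.X_total = pd.Series(self.X_total, dtype=float)
        self.p = pd.Series(self.p, dtype=float)
        if self.pathway not in (PATHWAY_212, PATHWAY_232):
            raise ValidationError(f"unknown pathway {self.pathway!r}")
        if (self.X_total < 0).any() or self.R < 0 or self.E_total < 0:
            raise ValidationError("concentrations must be nonnegative")
        if (self.p < 0).any() or (self.p > 1).any():
            raise ValidationError("codon usages must lie in [0, 1]")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ValidationError(f"codon usages sum to {self.p.sum():.12f}, not 1")

    def with_usage(self, p: pd.Series) -> "CellState":
        return CellState(
            growth_rate=self.growth_rate,
            X_total=self.X_total,
            R=self.R,
            E_total=self.E_total,
            p=p,
            pathway=self.pathway,
        )

    def with_pathway(self, pathway: str) -> "CellState":
        return CellState(
            growth_rate=self.growth_rate,
            X_total=self.X_total,
            R=self.R,
            E_total=self.E_total,
            p=self.p,
            pathway=pathway,
        )


@dataclass
class FreeTCSolution:
    """Converged output of the self-consistent balance."""

    X_hat: pd.Series
    E_free: float
    omega_elo: float
    profile: ElongationProfile
    iterations: int
    residual: float
    Phi_co: float = np.nan
    Phi_nr: float = np.nan

    @property
    def free_fraction(self) -> pd.Series:
        """X_free / X_total per tRNA species (set by the solver)."""
        return self._free_fraction

    _free_fraction: pd.Series = field(default=None, repr=False)


def _internal_pis(kp: KineticParams) -> dict[str, float]:
    """Codon-independent branch transition probabilities."""
    return {
        "pi_23": kp.omega_23 / (kp.omega_21 + kp.omega_23),
        "pi_45": kp.omega_45 / (kp.omega_40 + kp.omega_45),
        "pi_78": kp.omega_78 / (kp.omega_76 + kp.omega_78),
        "pi_9_10": kp.omega_9_10 / (kp.omega_90 + kp.omega_9_10),
    }


def tau_constants(kp: KineticParams, pi: np.ndarray | None = None) -> tuple[float, float, float]:
    """Sequestration time scales (tau_co, tau_nr, tau_no) in seconds.

    tau_co is the mean time a cognate ternary complex spends bound to a
    ribosome per successful accommodation; tau_nr the near-cognate analogue;
    tau_no the mean bound time of non-cognate complexes per elongation cycle.

    If ``pi`` (a full jump-probability matrix) is given, the branch
    probabilities are taken from it; otherwise they are computed from the
    internal rates, which is equivalent because they are codon independent.
    """
    if pi is not None:
        pi_23, pi_45, pi_78, pi_9_10 = pi[2, 3], pi[4, 5], pi[7, 8], pi[9, 10]
    else:
        p = _internal_pis(kp)
        pi_23, pi_45, pi_78, pi_9_10 = p["pi_23"], p["pi_45"], p["pi_78"], p["pi_9_10"]
    for name, val in [
        ("omega_rec", kp.omega_rec),
        ("omega_23", kp.omega_23),
        ("omega_con", kp.omega_con),
        ("omega_45", kp.omega_45),
        ("omega_off", kp.omega_off),
        ("pi_23", pi_23),
        ("pi_45", pi_45),
    ]:
        if val <= 0:
            raise ValidationError(f"tau constants undefined: {name} is zero")
    tau_co = (
        1.0 / (kp.omega_rec * pi_23 * pi_45)
        + 1.0 / (kp.omega_23 * pi_45)
        + 1.0 / (kp.omega_con * pi_45)
        + 1.0 / kp.omega_45
    )
    if pi_78 <= 0 or pi_9_10 <= 0 or kp.omega_78 <= 0 or kp.omega_9_10 <= 0:
        raise ValidationError("tau constants undefined: near-cognate branch rate is zero")
    tau_nr = (
        1.0 / (kp.omega_rec * pi_78 * pi_9_10)
        + 1.0 / (kp.omega_78 * pi_9_10)
        + 1.0 / (kp.omega_con * pi_9_10)
        + 1.0 / kp.omega_9_10
    )
    tau_no = 1.0 / (kp.omega_rec * pi_23 * pi_45) + 1.0 / (kp.omega_off * pi_45)
    return float(tau_co), float(tau_nr), float(tau_no)


def phi_constants(
    pathway: str,
    omega_elo: float,
    tau_co: float,
    tau_nr: float,
    rp: RechargingParams,
    E_free: float,
    omega_pro: float,
) -> tuple[float, float]:
    """Dimensionless sequestration factors (Phi_co, Phi_nr).

    Phi counts how many tRNA-equivalents of species time are tied up per
    elongation event: bound on ribosomes (the constant 2 or 1 reflecting
    whether the E-site tRNA waits for the next TC), in transit through the
    recharging cycle, and re-forming a ternary complex.
    """
    if E_free <= 0 or rp.kappa_ass * E_free <= 0:
        raise ValidationError("phi constants undefined: kappa_ass * E_free is zero")
    if rp.omega_re <= 0:
        raise ValidationError("phi constants undefined: omega_re is zero")
    cycle = 1.0 / rp.omega_re + 1.0 / (rp.kappa_ass * E_free)
    if pathway == PATHWAY_232:
        phi_co = 2.0 + omega_elo * (tau_co + cycle)
        phi_nr = 2.0 + omega_elo * (tau_nr + cycle)
    elif pathway == PATHWAY_212:
        if omega_pro <= 0:
            raise ValidationError("phi constants undefined: omega_pro is zero")
        phi_co = 1.0 + omega_elo * (tau_co + 1.0 / omega_pro + cycle)
        phi_nr = 1.0 + omega_elo * (tau_nr + 1.0 / omega_pro + cycle)
    else:
        raise ValidationError(f"unknown pathway {pathway!r}")
    return float(phi_co), float(phi_nr)


def _bound_eftu(cs: CellState, profile: ElongationProfile, p: np.ndarray) -> float:
    """EF-Tu concentration inside ribosome-bound ternary complexes.

    Steady-state occupancy of the EF-Tu-carrying states {1..4, 6..9, 11},
    weighted by codon usage and the active-ribosome concentration.
    """
    t_mean = float(p @ profile.t_elo)
    tu_dwell = profile.dwell[:, list(EFTU_STATES)].sum(axis=1)
    return cs.R * float(p @ tu_dwell) / t_mean


def free_eftu(
    cs: CellState,
    X_hat,
    profile: ElongationProfile,
    rp: RechargingParams | None = None,
) -> float:
    """Free EF-Tu concentration from the EF-Tu conservation law.

    The total pool splits into free EF-Tu, EF-Tu inside free ternary
    complexes, and EF-Tu inside ribosome-bound ternary complexes.  Raises
    :class:`InfeasibleParametersError` if the implied free concentration is
    negative (the EF-Tu pool cannot cover the demand).
    """
    x = pd.Series(X_hat, dtype=float)
    p = cs.p.reindex(list(profile.codons)).to_numpy(dtype=float)
    e_free = cs.E_total - float(x.sum()) - _bound_eftu(cs, profile, p)
    if e_free < 0:
        raise InfeasibleParametersError(
            f"EF-Tu pool insufficient: conservation implies E_free = {e_free:.4g} uM"
        )
    return float(e_free)


def free_tc_update(
    X_hat,
    cs: CellState,
    kp: KineticParams,
    rp: RechargingParams,
    m: CognacyMatrix,
    profile: ElongationProfile,
    Phi_co: float,
    Phi_nr: float,
    E_free: float,
    omega_elo: float,
) -> pd.Series:
    """One evaluation of the implicit free-TC balance (right-hand side).

    Returns the updated free-TC vector implied by the current elongation
    profile, sequestration factors and free EF-Tu.  Codons with usage above
    zero whose cognate free pool has collapsed below ``POOL_FLOOR`` raise
    :class:`InfeasibleParametersError` naming the codon.
    """
    x = pd.Series(X_hat, dtype=float).reindex(list(m.trnas))
    xv = x.to_numpy(dtype=float)
    p = cs.p.reindex(list(m.codons)).fillna(0.0).to_numpy(dtype=float)
    if tuple(profile.codons) != tuple(m.codons):
        raise ValidationError("profile codon order must match the cognacy matrix")
    s_co, s_nr, _ = pool_sums(xv, m)

    used = p > 0
    bad = used & (s_co < POOL_FLOOR)
    if bad.any():
        names = [m.codons[i] for i in np.flatnonzero(bad)]
        raise InfeasibleParametersError(
            f"cognate free-TC pool underflow for used codons {names}"
        )

    # per-codon fractional loads; codons with empty near-cognate sets (or
    # vanishing near-cognate pools with P_nr == 0) contribute nothing
    load_co = np.where(used, profile.P_co * p / np.where(s_co > 0, s_co, 1.0), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nr_term = profile.P_nr * p / s_nr
    load_nr = np.where(used & (s_nr > 0) & (profile.P_nr > 0), nr_term, 0.0)

    Mco = m.cls == COGNATE
    Mnr = m.cls == NEAR
    Mno = m.cls == NON
    seq = (
        Phi_co * (Mco.T @ load_co)
        + Phi_nr * (Mnr.T @ load_nr)
        + omega_elo * _tau_no_cached(kp) * (Mno.T @ load_co)
    )
    bracket = 1.0 + rp.omega_dis / (rp.kappa_ass * E_free) + cs.R * seq
    out = cs.X_total.reindex(list(m.trnas)).to_numpy(dtype=float) / bracket
    return pd.Series(out, index=list(m.trnas))


def _tau_no_cached(kp: KineticParams) -> float:
    return tau_constants(kp)[2]


def solve_self_consistent(
    cs: CellState,
    kp: KineticParams,
    rp: RechargingParams,
    m: CognacyMatrix,
    tol: float = 1e-10,
    damping: float = 0.5,
    max_sweeps: int = 10_000,
    omega_elo_mode: str = "self_consistent",
    pinned_omega_elo: float | None = None,
    x0: pd.Series | None = None,
) -> FreeTCSolution:
    """Solve the coupled free-TC / elongation-rate / EF-Tu fixed point.

    Damped Picard iteration ``X <- (1 - damping) X + damping RHS(X)``,
    initialized at ``X = X_total`` (or ``x0``).  Each sweep recomputes the
    per-codon elongation profile from the current pools, the overall
    elongation rate, the free EF-Tu concentration and the sequestration
    factors, then applies the implicit balance.  Convergence is declared when
    the maximum relative change of all unknowns drops below ``tol``.  On
    persistent residual growth the damping is reduced to 0.1 once.

    With ``omega_elo_mode="pinned"`` the overall elongation rate used inside
    the sequestration factors is held at ``pinned_omega_elo`` instead of
    being recomputed from the profile.
    """
    if kp.pathway != cs.pathway:
        kp = kp.with_pathway(cs.pathway)
    if omega_elo_mode not in ("self_consistent", "pinned"):
        raise ValidationError(f"unknown omega_elo_mode {omega_elo_mode!r}")
    if omega_elo_mode == "pinned" and not (pinned_omega_elo and pinned_omega_elo > 0):
        raise ValidationError("pinned mode requires a positive pinned_omega_elo")

    trnas = list(m.trnas)
    codons = list(m.codons)
    X_total = cs.X_total.reindex(trnas)
    if X_total.isna().any():
        raise ValidationError(
            f"total concentrations missing for {list(X_total.index[X_total.isna()])}"
        )
    p = cs.p.reindex(codons).fillna(0.0).to_numpy(dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError("codon usage does not cover the cognacy matrix codons")

    tau_co, tau_nr, _ = tau_constants(kp)
    x = (X_total if x0 is None else pd.Series(x0).reindex(trnas)).to_numpy(dtype=float).copy()
    e_floor = max(cs.E_total, 1.0) * 1e-9

    prev = {"x": x.copy(), "omega_elo": np.nan, "e_free": np.nan}
    residuals: list[float] = []
    grew = 0
    profile = None
    e_free = cs.E_total
    omega_elo = np.nan

    for sweep in range(1, max_sweeps + 1):
        s_co, s_nr, s_no = pool_sums(x, m)
        bad = (p > 0) & (s_co < POOL_FLOOR)
        if bad.any():
            names = [codons[i] for i in np.flatnonzero(bad)]
            raise InfeasibleParametersError(
                f"cognate free-TC pool underflow for used codons {names}"
            )
        profile = profile_from_pools(s_co, s_nr, s_no, codons, kp)
        t_mean = float(p @ profile.t_elo)
        omega_elo_model = 1.0 / t_mean
        omega_elo = pinned_omega_elo if omega_elo_mode == "pinned" else omega_elo_model

        e_free = cs.E_total - float(x.sum()) - _bound_eftu(cs, profile, p)
        e_free = max(e_free, e_floor)

        phi_co, phi_nr = phi_constants(
            cs.pathway, omega_elo, tau_co, tau_nr, rp, e_free, kp.omega_pro
        )
        rhs = free_tc_update(
            pd.Series(x, index=trnas), cs, kp, rp, m, profile, phi_co, phi_nr, e_free, omega_elo
        ).to_numpy(dtype=float)
        x_new = (1.0 - damping) * x + damping * rhs

        scale = np.maximum(np.abs(x_new), 1e-30)
        res_x = float(np.max(np.abs(x_new - prev["x"]) / scale))
        # on the first sweep only the pool change is meaningful
        res_w = (
            abs(omega_elo_model - prev["omega_elo"]) / max(omega_elo_model, 1e-30)
            if np.isfinite(prev["omega_elo"])
            else 0.0
        )
        res_e = (
            abs(e_free - prev["e_free"]) / max(e_free, 1e-30)
            if np.isfinite(prev["e_free"])
            else 0.0
        )
        residual = max(res_x, res_w, res_e)
        residuals.append(residual)

        prev = {"x": x_new.copy(), "omega_elo": omega_elo_model, "e_free": e_free}
        x = x_new

        if residual <= tol:
            break
        if len(residuals) > 1 and residual > residuals[-2]:
            grew += 1
            if grew >= 5 and damping > 0.1:
                damping = 0.1
                grew = 0
        else:
            grew = 0
    else:
        raise NonConvergenceError(
            f"no convergence after {max_sweeps} sweeps (residual {residuals[-1]:.3g})",
            residuals=residuals,
        )

    # final audit without the floor: conservation must hold exactly
    x_series = pd.Series(x, index=trnas)
    e_final = free_eftu(cs, x_series, profile, rp)
    sol = FreeTCSolution(
        X_hat=x_series,
        E_free=e_final,
        omega_elo=float(omega_elo),
        profile=profile,
        iterations=sweep,
        residual=residuals[-1],
        Phi_co=phi_co,
        Phi_nr=phi_nr,
    )
    sol._free_fraction = x_series / X_total.replace(0.0, np.nan)
    return sol
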