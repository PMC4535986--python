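"""Synthetic fixture generation.

Produces random but feasible parameter sets — a cognacy classification in
which every codon has at least one cognate tRNA, internal rates drawn
log-uniformly over physiological decades, Dirichlet codon usages and positive
concentration pools — so the whole pipeline can be exercised without any
reference data.  Fixtures are deterministic under a fixed seed.

The generator emulates the *structure* of the in-vivo inputs (competition,
sequestration, recharging), not any particular organism's values: ribosome
demand is kept small relative to the tRNA pools and EF-Tu is provided in
excess, mirroring the physiological regime in which the steady-state balance
has a solution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from elokin.balance import CellState, RechargingParams
from elokin.cognacy import COGNATE, NEAR, NON, SENSE_CODONS, CognacyMatrix
from elokin.errors import ValidationError
from elokin.kinetics import PATHWAY_212, PATHWAY_232, KineticParams

__all__ = ["generate_fixture", "random_generator_rates"]


def _random_cognacy(rng: np.random.Generator, n_codons: int, n_trnas: int) -> CognacyMatrix:
    codons = tuple(rng.choice(SENSE_CODONS, size=n_codons, replace=False))
    trnas = tuple(f"tRNA{j:02d}" for j in range(n_trnas))
    cls = np.full((n_codons, n_trnas), NON, dtype=np.int8)
    for i in range(n_codons):
        # at least one cognate per codon so every codon can be translated
        k = 1 + rng.binomial(1, 0.3)
        cognate = rng.choice(n_trnas, size=min(k, n_trnas), replace=False)
        cls[i, cognate] = COGNATE
        for j in range(n_trnas):
            if cls[i, j] == NON and rng.random() < 0.25:
                cls[i, j] = NEAR
    return CognacyMatrix(codons, trnas, cls)


def random_generator_rates(
    rng: np.random.Generator, pathway: str = PATHWAY_212
) -> KineticParams:
    """Random kinetic parameters, log-uniform over 1e-1 .. 1e3 s^-1.

    The forward rates along the two branches are kept at least as large as
    their competing reject rates often enough for absorption to be fast; no
    structural constraint beyond positivity is imposed.
    """

    def lu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return KineticParams(
        kappa_on=lu(0.1, 10.0),
        omega_off=lu(1.0, 1e3),
        omega_rec=lu(1.0, 1e3),
        omega_21=lu(0.1, 100.0),
        omega_23=lu(1.0, 1e3),
        omega_con=lu(1.0, 1e3),
        omega_40=lu(0.1, 10.0),
        omega_45=lu(1.0, 1e3),
        omega_76=lu(1.0, 1e3),
        omega_78=lu(0.1, 100.0),
        omega_90=lu(1.0, 1e3),
        omega_9_10=lu(0.1, 100.0),
        omega_pro=lu(1.0, 100.0),
        pathway=pathway,
    )


def generate_fixture(
    seed: int,
    n_trnas: int = 8,
    n_codons: int = 12,
    pathway: str | None = None,
) -> tuple[CognacyMatrix, KineticParams, RechargingParams, CellState]:
    """Random feasible (cognacy, kinetics, recharging, cell-state) quadruple.

    Parameters
    ----------
    seed : RNG seed; identical seeds give identical fixtures.
    n_trnas, n_codons : fixture dimensions; ``n_codons >= n_trnas >= 1``.
    pathway : E-site release pathway; drawn at random when omitted.
    """
    if n_trnas < 1:
        raise ValidationError("n_trnas must be >= 1")
    if n_codons < n_trnas:
        raise ValidationError("n_codons must be >= n_trnas")
    if n_codons > len(SENSE_CODONS):
        raise ValidationError(f"n_codons cannot exceed {len(SENSE_CODONS)}")
    rng = np.random.default_rng(seed)
    if pathway is None:
        pathway = PATHWAY_212 if rng.random() < 0.5 else PATHWAY_232

    m = _random_cognacy(rng, n_codons, n_trnas)
    kp = random_generator_rates(rng, pathway)
    rp = RechargingParams(
        kappa_ass=float(np.exp(rng.uniform(np.log(1.0), np.log(50.0)))),
        omega_dis=float(np.exp(rng.uniform(np.log(0.001), np.log(1.0)))),
        omega_re=float(np.exp(rng.uniform(np.log(1.0), np.log(50.0)))),
    )

    x_total = pd.Series(
        np.exp(rng.uniform(np.log(1.0), np.log(50.0), size=n_trnas)),
        index=list(m.trnas),
    )
    usage = pd.Series(rng.dirichlet(np.ones(n_codons)), index=list(m.codons))
    total = float(x_total.sum())
    R = float(rng.uniform(0.005, 0.02)) * total
    E_total = float(rng.uniform(1.5, 3.0)) * (total + R)
    cs = CellState(
        growth_rate=float(rng.uniform(0.5, 2.5)),
        X_total=x_total,
        R=R,
        E_total=E_total,
        p=usage,
        pathway=pathway,
    )
    return m, kp, rp, cs
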