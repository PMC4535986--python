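"""Codon-usage perturbation experiments.

Two kinds of in-silico experiment:

- *single-codon scans*: the usage of one codon is set to a new value while
  the mutual ratios of all other codon usages stay at their baseline values
  (the whole vector is renormalized), and the self-consistent balance is
  re-solved at every grid point;
- *gene overexpression*: the transcriptome usage vector is replaced by (or
  mixed with) the codon frequencies of a single gene, modelling the limit in
  which most ribosomes translate that gene.  Total tRNA concentrations are
  untouched: only the usage input changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from elokin.balance import CellState, RechargingParams, solve_self_consistent
from elokin.cognacy import SENSE_CODONS, STOP_CODONS, CognacyMatrix
from elokin.errors import ParseError, ValidationError
from elokin.kinetics import KineticParams

__all__ = [
    "reweight_usage",
    "usage_from_gene",
    "usage_from_fasta",
    "mix_usage",
    "scan_usage",
]


def reweight_usage(p, target: str, new_value: float) -> pd.Series:
    """Set the usage of one codon, rescaling all others proportionally.

    The output satisfies the normalization condition exactly and preserves
    every pairwise ratio among the non-target codons.
    """
    if not (0.0 <= new_value < 1.0):
        raise ValidationError(f"new_value must lie in [0, 1), got {new_value}")
    pv = pd.Series(p, dtype=float)
    if target not in pv.index:
        raise KeyError(f"codon {target!r} not in usage vector")
    rest = 1.0 - pv[target]
    if rest <= 0:
        raise ValidationError(f"baseline usage of {target} is 1; cannot rescale the rest")
    out = pv * (1.0 - new_value) / rest
    out[target] = new_value
    return out


def mix_usage(p_wild, p_gene, fraction: float) -> pd.Series:
    """Convex combination of wild-type and gene usage (partial overexpression)."""
    if not (0.0 <= fraction <= 1.0):
        raise ValidationError("fraction must lie in [0, 1]")
    a = pd.Series(p_wild, dtype=float)
    b = pd.Series(p_gene, dtype=float).reindex(a.index).fillna(0.0)
    return (1.0 - fraction) * a + fraction * b


def _clean_cds(seq: str) -> str:
    s = str(seq).strip().upper().replace("T", "U")
    if any(b not in "ACGU" for b in s):
        bad = sorted({b for b in s if b not in "ACGU"})
        raise ParseError(f"non-ACGU symbols in coding sequence: {bad}")
    if len(s) % 3 != 0:
        raise ValidationError(f"coding sequence length {len(s)} not divisible by 3")
    return s


def usage_from_gene(cds: str, codons=SENSE_CODONS) -> pd.Series:
    """Codon frequencies of a coding sequence as a usage vector.

    All sense codons of the CDS are counted, including the start codon; a
    single trailing stop codon is dropped.  An internal stop codon raises a
    validation error naming its position (1-based codon index).
    """
    s = _clean_cds(cds)
    triplets = [s[i : i + 3] for i in range(0, len(s), 3)]
    if triplets and triplets[-1] in STOP_CODONS:
        triplets = triplets[:-1]
    for pos, t in enumerate(triplets, start=1):
        if t in STOP_CODONS:
            raise ValidationError(f"internal stop codon {t} at codon position {pos}")
    if not triplets:
        raise ValidationError("empty coding sequence")
    counts = pd.Series(0.0, index=list(codons))
    vc = pd.Series(triplets).value_counts()
    counts.loc[vc.index] = vc.to_numpy(dtype=float)
    return counts / counts.sum()


def usage_from_fasta(path, codons=SENSE_CODONS) -> pd.Series:
    """Read the first record of a FASTA file and return its codon usage."""
    rec = next(SeqIO.parse(str(path), "fasta"))
    return usage_from_gene(str(rec.seq), codons=codons)


@dataclass
class ScanPoint:
    """One grid point of a usage scan."""

    grid_value: float
    converged: bool
    solution: object  # FreeTCSolution or None
    error: str | None = None


def scan_usage(
    cs: CellState,
    kp: KineticParams,
    rp: RechargingParams,
    m: CognacyMatrix,
    target: str,
    grid,
    track_codons=None,
    warm_start: bool = True,
    **solver_kwargs,
) -> pd.DataFrame:
    """Re-solve the balance along a grid of usages for one codon.

    Returns a long-format table with one row per (grid point, quantity):
    free-TC concentrations of the target codon's cognate tRNA species, the
    elongation rate and missense error frequency of the tracked codons
    (default: every codon sharing a cognate tRNA with the target), the
    overall elongation rate, and a convergence flag.  Non-convergence at a
    point is recorded, not fatal.
    """
    grid = [float(v) for v in grid]
    for v in grid:
        if not (0.0 <= v < 1.0):
            raise ValidationError(f"grid value {v} outside [0, 1)")
    co_set, _, _ = m.trnas_for_codon(target)
    if track_codons is None:
        track = set()
        for a in co_set:
            track |= m.codons_for_trna(a)[0]
        track_codons = sorted(track)

    rows = []
    x_prev = None
    for v in grid:
        p_new = reweight_usage(cs.p, target, v)
        cs_v = cs.with_usage(p_new)
        try:
            sol = solve_self_consistent(
                cs_v, kp, rp, m, x0=x_prev if warm_start else None, **solver_kwargs
            )
            if warm_start:
                x_prev = sol.X_hat
            rows.append((v, "omega_elo_overall", "", sol.omega_elo, True))
            for a in sorted(co_set):
                rows.append((v, "X_hat", a, float(sol.X_hat[a]), True))
            for c in track_codons:
                prof = sol.profile.loc(c)
                rows.append((v, "omega_elo", c, prof.omega_elo, True))
                rows.append((v, "P_nr", c, prof.P_nr, True))
        except Exception as exc:  # recorded, not fatal
            rows.append((v, "error", "", np.nan, False))
            rows[-1] = (v, "error", type(exc).__name__, np.nan, False)
    return pd.DataFrame(
        rows, columns=["grid_value", "quantity", "key", "value", "converged"]
    )
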