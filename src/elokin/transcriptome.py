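"""Transcriptome-wide averages and steady-state ribosome occupancy.

At steady state the probability of finding a ribosome on a codon of species
``c`` is proportional to how often the codon occurs (usage ``p_c``) and how
long the ribosome dwells on it (elongation time ``t_c``):

    P_c = p_c * t_c / <t>,   <t> = sum_c p_c t_c

The joint probability over (codon, internal state) factorizes into this
marginal and the dwell-time fractions of the codon-specific cycle, so the
whole cell-wide steady state lives on a reduced space of 12 x n_codons
states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from elokin.errors import ValidationError
from elokin.kinetics import N_STATES, ElongationProfile

__all__ = ["OccupancyProfile", "overall_elongation_rate", "occupancy", "per_codon_table"]


def _check_usage(profile: ElongationProfile, p) -> np.ndarray:
    pv = pd.Series(p, dtype=float).reindex(list(profile.codons))
    if pv.isna().any():
        raise ValidationError(
            f"usage missing for codons {list(pv.index[pv.isna()])}"
        )
    arr = pv.to_numpy(dtype=float)
    if (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-9:
        raise ValidationError(f"codon usage not normalized (sum = {arr.sum():.12f})")
    return arr


def overall_elongation_rate(profile: ElongationProfile, p) -> tuple[float, float]:
    """Usage-weighted mean elongation time and the overall elongation rate.

    Returns ``(<t>, omega_elo)`` with ``<t> = sum_c p_c t_c`` and
    ``omega_elo = 1 / <t>``.
    """
    pv = _check_usage(profile, p)
    t_mean = float(pv @ profile.t_elo)
    return t_mean, 1.0 / t_mean


@dataclass
class OccupancyProfile:
    """Steady-state ribosome occupancy over the reduced (codon, state) space."""

    marginal: pd.Series  # P_c
    joint: pd.DataFrame  # P_{c,i}, codons x 12 states
    conditional: pd.DataFrame  # P_{i|c}

    @property
    def n_states(self) -> int:
        """Size of the reduced steady-state space."""
        return self.joint.size


def occupancy(profile: ElongationProfile, p) -> OccupancyProfile:
    """Steady-state marginal, joint and conditional occupancy probabilities."""
    pv = _check_usage(profile, p)
    t_mean = float(pv @ profile.t_elo)
    marginal = pv * profile.t_elo / t_mean
    conditional = profile.dwell / profile.t_elo[:, None]
    joint = pv[:, None] * profile.dwell / t_mean
    cols = [f"state_{i}" for i in range(N_STATES)]
    idx = list(profile.codons)
    return OccupancyProfile(
        marginal=pd.Series(marginal, index=idx, name="P_c"),
        joint=pd.DataFrame(joint, index=idx, columns=cols),
        conditional=pd.DataFrame(conditional, index=idx, columns=cols),
    )


def per_codon_table(profile: ElongationProfile, p) -> pd.DataFrame:
    """Long per-codon summary table (usage, times, rates, error frequency, occupancy)."""
    pv = _check_usage(profile, p)
    occ = occupancy(profile, p)
    df = profile.to_frame()
    df.insert(0, "p_c", pv)
    df["P_st"] = occ.marginal
    return df
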