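"""Parameter-table reading/writing, packaged defaults and configuration.

Packaged reference tables live under ``elokin/data``.  They are *synthetic
reconstructions* of the E. coli inputs the model needs (cognacy
classification, internal transition rates, tRNA / ribosome / EF-Tu
concentrations per growth rate, codon usages, a lacZ-like coding sequence):
the values are physiologically plausible stand-ins assembled from standard
decoding assignments and magnitude estimates, not measured data — see the
provenance headers inside each file.  All packaged tables pass the same
validators as user-supplied ones.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from elokin.balance import CellState, RechargingParams
from elokin.cognacy import CognacyMatrix, load_cognacy
from elokin.errors import ParseError, ValidationError
from elokin.kinetics import PATHWAY_212, PATHWAY_232, KineticParams

__all__ = [
    "GROWTH_RATES",
    "packaged_path",
    "load_rates",
    "load_cellstate",
    "write_cellstate",
    "ecoli_defaults",
    "lacz_like_cds_path",
    "load_config",
    "DEFAULT_CONFIG",
]

GROWTH_RATES = (0.7, 1.07, 1.6, 2.5)

_DATA_FILES = {
    "cognacy": "ecoli_cognacy.synthetic.tsv",
    "rates": "ecoli_rates.synthetic.tsv",
    "concentrations": "ecoli_trna_concentrations.synthetic.tsv",
    "usage": "ecoli_codon_usage.synthetic.tsv",
    "lacz": "lacz_like_cds.synthetic.fasta",
}

_INTERNAL_RATE_NAMES = (
    "kappa_on",
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


def packaged_path(key: str) -> Path:
    """Filesystem path of a packaged data table."""
    try:
        name = _DATA_FILES[key]
    except KeyError:
        raise KeyError(f"unknown packaged table {key!r}; choose from {sorted(_DATA_FILES)}")
    return Path(resources.files("elokin.data") / name)


def lacz_like_cds_path() -> Path:
    """Path of the packaged synthetic lacZ-like coding sequence (FASTA)."""
    return packaged_path("lacz")


def load_rates(
    path=None, pathway: str = PATHWAY_212
) -> tuple[KineticParams, RechargingParams, dict[float, float]]:
    """Read kinetic and recharging rates from a TSV keyed by rate name.

    Columns: ``rate``, ``value``, ``rsd``, ``pathway`` (``2-1-2``, ``2-3-2``
    or ``both``).  Rows named ``omega_elo_<mu>`` carry the measured overall
    elongation rate per growth rate and are returned as a dict for use with
    the pinned solver mode.
    """
    if pathway not in (PATHWAY_212, PATHWAY_232):
        raise ValidationError(f"unknown pathway {pathway!r}")
    path = packaged_path("rates") if path is None else path
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"rate", "value", "pathway"}
    if not need.issubset(df.columns):
        raise ParseError(f"rates table must have columns {sorted(need)}")
    df = df[(df["pathway"] == pathway) | (df["pathway"] == "both")]
    values = dict(zip(df["rate"], df["value"].astype(float)))

    missing = [n for n in _INTERNAL_RATE_NAMES if n not in values]
    if missing:
        raise ParseError(f"rates table is missing {missing}")
    kp = KineticParams(**{n: values[n] for n in _INTERNAL_RATE_NAMES}, pathway=pathway)
    try:
        rp = RechargingParams(
            kappa_ass=values["kappa_ass"],
            omega_dis=values["omega_dis"],
            omega_re=values["omega_re"],
        )
    except KeyError as exc:
        raise ParseError(f"rates table is missing recharging constant {exc}") from exc
    measured = {
        float(name.split("_")[-1]): v
        for name, v in values.items()
        if name.startswith("omega_elo_")
    }
    return kp, rp, measured


def _growth_column(df: pd.DataFrame, growth_rate: float) -> str:
    for col in df.columns:
        try:
            if abs(float(col) - growth_rate) < 1e-9:
                return col
        except ValueError:
            continue
    raise ParseError(f"no column for growth rate {growth_rate} in {list(df.columns)}")


def load_cellstate(
    conc_path=None,
    usage_path=None,
    growth_rate: float = 2.5,
    pathway: str = PATHWAY_212,
    cognacy: CognacyMatrix | None = None,
) -> CellState:
    """Assemble a CellState from a concentration table and a usage table.

    The concentration table has one row per tRNA species plus the rows
    ``ribosomes_active`` and ``EF-Tu_total``; the usage table one row per
    sense codon, in percent.  Columns are growth rates.  Usages are
    renormalized to fractions (they exclude stop codons by construction).
    """
    conc_path = packaged_path("concentrations") if conc_path is None else conc_path
    usage_path = packaged_path("usage") if usage_path is None else usage_path
    conc = pd.read_csv(conc_path, sep="\t", comment="#", index_col=0)
    usage = pd.read_csv(usage_path, sep="\t", comment="#", index_col=0)
    ccol = _growth_column(conc, growth_rate)
    ucol = _growth_column(usage, growth_rate)

    if "ribosomes_active" not in conc.index or "EF-Tu_total" not in conc.index:
        raise ParseError("concentration table needs rows 'ribosomes_active' and 'EF-Tu_total'")
    R = float(conc.loc["ribosomes_active", ccol])
    E_total = float(conc.loc["EF-Tu_total", ccol])
    x_total = conc.drop(index=["ribosomes_active", "EF-Tu_total"])[ccol].astype(float)

    p = usage[ucol].astype(float)
    if (p < 0).any():
        raise ValidationError("negative codon usage")
    p = p / p.sum()

    if cognacy is not None:
        missing_t = [a for a in cognacy.trnas if a not in x_total.index]
        if missing_t:
            raise ParseError(f"concentration table is missing tRNA rows {missing_t}")
        missing_c = [c for c in cognacy.codons if c not in p.index]
        if missing_c:
            raise ParseError(f"usage table is missing codon rows {missing_c}")
        x_total = x_total.reindex(list(cognacy.trnas))
        p = p.reindex(list(cognacy.codons))
    return CellState(
        growth_rate=growth_rate, X_total=x_total, R=R, E_total=E_total, p=p, pathway=pathway
    )


def write_cellstate(cs: CellState, conc_path, usage_path) -> None:
    """Write a CellState back to the two-table layout (single growth column)."""
    col = str(cs.growth_rate)
    conc = cs.X_total.to_frame(name=col)
    conc.loc["ribosomes_active"] = cs.R
    conc.loc["EF-Tu_total"] = cs.E_total
    conc.index.name = "name"
    conc.to_csv(conc_path, sep="\t")
    usage = (cs.p * 100.0).to_frame(name=col)
    usage.index.name = "codon"
    usage.to_csv(usage_path, sep="\t")


def ecoli_defaults(
    growth_rate: float = 2.5, pathway: str = PATHWAY_232
) -> tuple[CognacyMatrix, KineticParams, RechargingParams, CellState]:
    """Packaged synthetic E. coli parameter set for one growth condition."""
    m = load_cognacy(packaged_path("cognacy"))
    m.validate_full_ecoli()
    kp, rp, _ = load_rates(pathway=pathway)
    cs = load_cellstate(growth_rate=growth_rate, pathway=pathway, cognacy=m)
    return m, kp, rp, cs


DEFAULT_CONFIG = {
    "pathway": PATHWAY_232,
    "growth_rate": 2.5,
    "omega_elo_mode": "self_consistent",
    "solver": {"tol": 1e-10, "damping": 0.5, "max_sweeps": 10_000},
}


def load_config(path=None) -> dict:
    """YAML configuration merged over the defaults."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    if cfg["pathway"] not in (PATHWAY_212, PATHWAY_232):
        raise ValidationError(f"config: unknown pathway {cfg['pathway']!r}")
    if cfg["omega_elo_mode"] not in ("self_consistent", "pinned"):
        raise ValidationError(f"config: unknown omega_elo_mode {cfg['omega_elo_mode']!r}")
    return cfg
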