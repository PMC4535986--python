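"""Codon-tRNA cognacy classification.

Every (sense codon, elongator tRNA) pair is classified as cognate,
near-cognate or non-cognate.  The classification is *data*, not computation:
it is read from a table, and the module only validates and indexes it.  Each
codon ``c`` induces a partition of the tRNA set into the three classes
``A_co(c)``, ``A_nr(c)``, ``A_no(c)``; each tRNA ``a`` symmetrically induces a
partition ``C_co(a)``, ``C_nr(a)``, ``C_no(a)`` of the sense codons.

File format (TSV): first column ``codon`` holding RNA triplets, remaining
columns named after tRNA species, cells in ``{C, N, -}`` for
cognate / near-cognate / non-cognate.  Lines starting with ``#`` are comments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from elokin.errors import ParseError, ValidationError

__all__ = [
    "SENSE_CODONS",
    "STOP_CODONS",
    "COGNATE",
    "NEAR",
    "NON",
    "CognacyMatrix",
    "load_cognacy",
    "write_cognacy",
]

RNA_BASES = "UCAG"
STOP_CODONS = ("UAA", "UAG", "UGA")

#: The 61 sense codons in standard codon-table order (U, C, A, G).
SENSE_CODONS = tuple(
    "".join(b) for b in itertools.product(RNA_BASES, repeat=3) if "".join(b) not in STOP_CODONS
)

# integer codes used in the classification array
COGNATE = 2
NEAR = 1
NON = 0

_SYMBOL_TO_CODE = {"C": COGNATE, "N": NEAR, "-": NON}
_CODE_TO_SYMBOL = {v: k for k, v in _SYMBOL_TO_CODE.items()}


def _check_codon(codon: str, dna_ok: bool = False) -> str:
    """Normalize and validate a codon string; returns the RNA triplet."""
    c = str(codon).strip().upper()
    if dna_ok:
        c = c.replace("T", "U")
    if len(c) != 3 or any(b not in "ACGU" for b in c):
        raise ParseError(f"not an RNA triplet: {codon!r}")
    if c in STOP_CODONS:
        raise ParseError(f"stop codon {c} is not a sense codon")
    return c


@dataclass
class CognacyMatrix:
    """Classification of every (codon, tRNA) pair.

    Parameters
    ----------
    codons : ordered RNA triplets (rows)
    trnas : ordered tRNA species names (columns)
    cls : int array of shape (n_codons, n_trnas) with values in
        {COGNATE, NEAR, NON}
    """

    codons: tuple[str, ...]
    trnas: tuple[str, ...]
    cls: np.ndarray
    _codon_index: dict = field(init=False, repr=False)
    _trna_index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.codons = tuple(self.codons)
        self.trnas = tuple(self.trnas)
        self.cls = np.asarray(self.cls, dtype=np.int8)
        if len(set(self.codons)) != len(self.codons):
            raise ValidationError("duplicate codon rows")
        if len(set(self.trnas)) != len(self.trnas):
            raise ValidationError("duplicate tRNA columns")
        for c in self.codons:
            if c not in SENSE_CODONS:
                raise ValidationError(f"{c} is not a sense codon")
        if self.cls.shape != (len(self.codons), len(self.trnas)):
            raise ValidationError(
                f"classification shape {self.cls.shape} does not match "
                f"{len(self.codons)} codons x {len(self.trnas)} tRNAs"
            )
        if not np.isin(self.cls, (COGNATE, NEAR, NON)).all():
            raise ValidationError("classification entries must be COGNATE, NEAR or NON")
        self._codon_index = {c: i for i, c in enumerate(self.codons)}
        self._trna_index = {a: j for j, a in enumerate(self.trnas)}

    # -- size bookkeeping -------------------------------------------------
    @property
    def n_entries(self) -> int:
        """Number of classified (codon, tRNA) cells."""
        return self.cls.size

    # -- boolean membership masks ----------------------------------------
    def mask(self, kind: int) -> np.ndarray:
        """Boolean (n_codons, n_trnas) mask for one classification."""
        return self.cls == kind

    # -- partitions -------------------------------------------------------
    def trnas_for_codon(self, codon: str) -> tuple[set, set, set]:
        """Partition of the tRNA set induced by one codon.

        Returns ``(cognate, near-cognate, non-cognate)`` sets of tRNA names.
        """
        try:
            i = self._codon_index[codon]
        except KeyError:
            raise KeyError(f"codon {codon!r} not in matrix") from None
        row = self.cls[i]
        tr = np.asarray(self.trnas, dtype=object)
        return (
            set(tr[row == COGNATE]),
            set(tr[row == NEAR]),
            set(tr[row == NON]),
        )

    def codons_for_trna(self, trna: str) -> tuple[set, set, set]:
        """Partition of the sense codons induced by one tRNA species."""
        try:
            j = self._trna_index[trna]
        except KeyError:
            raise KeyError(f"tRNA {trna!r} not in matrix") from None
        col = self.cls[:, j]
        co = np.asarray(self.codons, dtype=object)
        return (
            set(co[col == COGNATE]),
            set(co[col == NEAR]),
            set(co[col == NON]),
        )

    def codon_row(self, codon: str) -> np.ndarray:
        return self.cls[self._codon_index[codon]]

    def validate_full_ecoli(self) -> None:
        """Check the E. coli shape: all 61 sense codons x 43 tRNA species."""
        if set(self.codons) != set(SENSE_CODONS):
            missing = set(SENSE_CODONS) - set(self.codons)
            raise ValidationError(f"missing sense codons: {sorted(missing)}")
        if len(self.trnas) != 43:
            raise ValidationError(f"expected 43 tRNA species, found {len(self.trnas)}")


def load_cognacy(path, dna_ok: bool = False) -> CognacyMatrix:
    """Read a cognacy table from a TSV file.

    Parameters
    ----------
    path : file path
    dna_ok : if True, transliterate T to U in codon labels.

    Raises
    ------
    ParseError
        For unknown codons (including stop codons) or symbols outside
        ``{C, N, -}``; the message names the offending cell.
    ValidationError
        For duplicate codons or tRNA names.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.columns[0].lower() != "codon":
        raise ParseError(f"first column must be 'codon', found {df.columns[0]!r}")
    trnas = tuple(df.columns[1:])
    codons = []
    rows = []
    for _, rec in df.iterrows():
        codon = _check_codon(rec.iloc[0], dna_ok=dna_ok)
        row = []
        for a in trnas:
            sym = str(rec[a]).strip()
            if sym not in _SYMBOL_TO_CODE:
                raise ParseError(f"cell ({codon}, {a}): unknown symbol {sym!r}")
            row.append(_SYMBOL_TO_CODE[sym])
        codons.append(codon)
        rows.append(row)
    return CognacyMatrix(tuple(codons), trnas, np.array(rows, dtype=np.int8))


def write_cognacy(m: CognacyMatrix, path, header_comment: str | None = None) -> None:
    """Write a cognacy matrix in the same TSV format accepted by load_cognacy."""
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("codon\t" + "\t".join(m.trnas) + "\n")
        for i, c in enumerate(m.codons):
            syms = [_CODE_TO_SYMBOL[int(v)] for v in m.cls[i]]
            fh.write(c + "\t" + "\t".join(syms) + "\n")
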