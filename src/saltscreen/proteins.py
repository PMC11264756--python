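"""Physicochemical characterisation of protein sequences.

Computes the standard ProtParam-style property set for each FASTA
record: residue count, average molecular weight, isoelectric point
(Bjellqvist pKa set, bisection on net charge), GRAVY (Kyte–Doolittle
mean hydropathy), Ikai's aliphatic index and Guruprasad's instability
index.  The hydropathy and dipeptide-instability weight tables are taken
from ``Bio.SeqUtils.ProtParamData``; the formulas are evaluated here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, TextIO, Union

import pandas as pd
from Bio import SeqIO
from Bio.SeqUtils import ProtParamData

__all__ = [
    "ProteinRecord",
    "STANDARD_AA",
    "read_fasta",
    "mol_weight",
    "isoelectric_point",
    "net_charge",
    "gravy",
    "aliphatic_index",
    "instability_index",
    "characterize",
    "characterize_fasta",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

# average residue masses (Da); a peptide adds one water (18.01524 Da)
WATER_MASS = 18.01524
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

# Bjellqvist/ExPASy pKa values: termini plus ionisable side chains, with
# residue-specific corrections for the terminal residues (the set behind
# ExPASy Compute pI/Mw-style outputs)
BJELLQVIST = {
    "nterm": 7.5,
    "cterm": 3.55,
    "base": {"H": 5.98, "K": 10.0, "R": 12.0},    # positive below pKa
    "acid": {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},  # negative above pKa
    "nterm_residue": {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7},
    "cterm_residue": {"D": 4.55, "E": 4.75},
}
# simple one-pKa-per-group alternative (EMBOSS-style textbook values)
EMBOSS = {
    "nterm": 8.6,
    "cterm": 3.6,
    "base": {"H": 6.5, "K": 10.8, "R": 12.5},
    "acid": {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1},
    "nterm_residue": {},
    "cterm_residue": {},
}
PKA_SETS = {"bjellqvist": BJELLQVIST, "emboss": EMBOSS}


class UnknownResidueError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str
    aa_count: int
    MW: float
    pI: float | None
    gravy: float
    aliphatic_index: float
    instability_index: float | None
    has_nonstandard: bool = False


def _check_sequence(seq: str) -> str:
    seq = seq.upper()
    bad = [(i, c) for i, c in enumerate(seq) if c not in STANDARD_AA]
    if bad:
        pos = ", ".join(f"{c}@{i}" for i, c in bad[:5])
        raise UnknownResidueError(f"non-standard residues: {pos}")
    return seq


def read_fasta(source: Union[str, TextIO]) -> list[tuple[str, str]]:
    """Parse FASTA into (id, uppercased sequence) pairs.

    Records containing non-standard residues are kept (they are flagged
    downstream); empty records raise.
    """
    records = []
    for rec in SeqIO.parse(source, "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r}")
        records.append((rec.id, seq))
    if not records:
        raise ValueError("no FASTA records found")
    return records


def mol_weight(seq: str) -> float:
    """Average molecular weight in Da: residue masses plus one water."""
    if not seq:
        raise ValueError("empty sequence")
    seq = _check_sequence(seq)
    return math.fsum(RESIDUE_MASS[c] for c in seq) + WATER_MASS


def net_charge(seq: str, ph: float, pka_set: str = "bjellqvist") -> float:
    """Henderson–Hasselbalch net charge at a given pH."""
    seq = _check_sequence(seq)
    pk = PKA_SETS[pka_set]
    pka_n = pk["nterm_residue"].get(seq[0], pk["nterm"])
    pka_c = pk["cterm_residue"].get(seq[-1], pk["cterm"])
    pos = 1.0 / (1.0 + 10 ** (ph - pka_n))
    neg = 1.0 / (1.0 + 10 ** (pka_c - ph))
    for aa, pka in pk["base"].items():
        pos += seq.count(aa) / (1.0 + 10 ** (ph - pka))
    for aa, pka in pk["acid"].items():
        neg += seq.count(aa) / (1.0 + 10 ** (pka - ph))
    return pos - neg


def isoelectric_point(seq: str, tol: float = 1e-3, pka_set: str = "bjellqvist") -> float:
    """pH of zero net charge, by bisection on [0, 14] to ``tol`` pH units."""
    lo, hi = 0.0, 14.0
    # net charge is strictly decreasing in pH
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pka_set) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gravy(seq: str) -> float:
    """Grand average of hydropathy: mean Kyte–Doolittle value per residue."""
    seq = _check_sequence(seq)
    if not seq:
        raise ValueError("empty sequence")
    return math.fsum(ProtParamData.kd[c] for c in seq) / len(seq)


def aliphatic_index(seq: str) -> float:
    """Ikai's aliphatic index from mole percentages of A, V, I and L.

    AI = X_Ala + 2.9 X_Val + 3.9 (X_Ile + X_Leu), X in mole percent.
    """
    seq = _check_sequence(seq)
    L = len(seq)
    x = lambda aa: 100.0 * seq.count(aa) / L
    return x("A") + 2.9 * x("V") + 3.9 * (x("I") + x("L"))


def instability_index(seq: str) -> float:
    """Guruprasad's instability index: (10/L) Σ DIWV over consecutive dipeptides."""
    seq = _check_sequence(seq)
    if len(seq) < 2:
        raise ValueError("instability index needs >= 2 residues")
    total = math.fsum(ProtParamData.DIWV[seq[i]][seq[i + 1]] for i in range(len(seq) - 1))
    return 10.0 * total / len(seq)


def characterize(record_id: str, seq: str) -> ProteinRecord:
    """Full property record for one sequence.

    Sequences with non-standard residues get MW over known residues only
    and no pI/instability (policy: refuse rather than guess), with a
    warning.
    """
    seq = seq.upper()
    nonstandard = any(c not in STANDARD_AA for c in seq)
    if nonstandard:
        warnings.warn(
            f"{record_id}: non-standard residues; pI and instability index withheld",
            stacklevel=2,
        )
        clean = "".join(c for c in seq if c in STANDARD_AA)
        return ProteinRecord(
            id=record_id,
            sequence=seq,
            aa_count=len(seq),
            MW=mol_weight(clean) if clean else float("nan"),
            pI=None,
            gravy=gravy(clean) if clean else float("nan"),
            aliphatic_index=aliphatic_index(clean) if clean else float("nan"),
            instability_index=None,
            has_nonstandard=True,
        )
    return ProteinRecord(
        id=record_id,
        sequence=seq,
        aa_count=len(seq),
        MW=mol_weight(seq),
        pI=isoelectric_point(seq),
        gravy=gravy(seq),
        aliphatic_index=aliphatic_index(seq),
        instability_index=instability_index(seq) if len(seq) >= 2 else None,
        has_nonstandard=False,
    )


def characterize_fasta(source: Union[str, TextIO]) -> pd.DataFrame:
    """Property table for a FASTA file, one row per record."""
    rows = []
    for rid, seq in read_fasta(source):
        r = characterize(rid, seq)
        rows.append(
            {
                "id": r.id,
                "aa": r.aa_count,
                "instability_index": r.instability_index,
                "aliphatic_index": r.aliphatic_index,
                "gravy": r.gravy,
                "pI": r.pI,
                "Mw": r.MW,
            }
        )
    return pd.DataFrame(rows)
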