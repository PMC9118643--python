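"""Physicochemical descriptors computed from sequence alone: length,
average molecular weight, isoelectric point, instability index, aliphatic
index and GRAVY — the classic ProtParam panel.

All sums use average (not monoisotopic) residue masses.  The ambiguity
letter X is excluded from every sum with a logged warning; the reported
length includes X.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint
from Bio.SeqUtils.ProtParamData import DIWV, kd

from .io_formats import AMINO_ACIDS, ProteinRecord, SodfamError

logger = logging.getLogger("sodfam")

#: ExPASy average residue masses (Da)
AVERAGE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524


def _strip_x(seq: str, what: str) -> str:
    if "X" in seq:
        logger.warning("%s: %d ambiguous X residue(s) excluded", what, seq.count("X"))
        seq = seq.replace("X", "")
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise SodfamError(f"{what}: invalid residues {sorted(bad)}")
    return seq


def molecular_weight(seq: str) -> float:
    """Average molecular mass in daltons: sum of residue masses plus one
    water."""
    seq = _strip_x(seq, "molecular_weight")
    if not seq:
        raise SodfamError("molecular_weight: empty sequence")
    return sum(AVERAGE_MASS[c] for c in seq) + WATER_MASS


def isoelectric_point(seq: str) -> float:
    """pH at which the net charge is zero, under the Bjellqvist pKa set
    (one free N- and one free C-terminus), solved by bisection."""
    seq = _strip_x(seq, "isoelectric_point")
    if not seq:
        raise SodfamError("isoelectric_point: empty sequence")
    return float(IsoelectricPoint(seq).pi())


def charge_at_pH(seq: str, ph: float) -> float:
    """Net charge of the polypeptide at a given pH (Bjellqvist model);
    exposed for oracle-style root checks."""
    seq = _strip_x(seq, "charge_at_pH")
    return float(IsoelectricPoint(seq).charge_at_pH(ph))


def instability_index(seq: str) -> float:
    """Guruprasad instability index: (10/L) times the sum of dipeptide
    instability weights over consecutive residue pairs."""
    seq = _strip_x(seq, "instability_index")
    if len(seq) < 2:
        raise SodfamError("instability_index: need at least 2 residues")
    total = sum(DIWV[seq[i]][seq[i + 1]] for i in range(len(seq) - 1))
    return 10.0 / len(seq) * total


def aliphatic_index(seq: str) -> float:
    """Relative volume of aliphatic side chains:
    X(Ala) + 2.9 X(Val) + 3.9 (X(Ile) + X(Leu)) in mole percent."""
    seq = _strip_x(seq, "aliphatic_index")
    if not seq:
        raise SodfamError("aliphatic_index: empty sequence")
    n = len(seq)
    x = lambda aa: 100.0 * seq.count(aa) / n
    return x("A") + 2.9 * x("V") + 3.9 * (x("I") + x("L"))


def gravy(seq: str) -> float:
    """Grand average of hydropathicity: mean Kyte-Doolittle hydropathy."""
    seq = _strip_x(seq, "gravy")
    if not seq:
        raise SodfamError("gravy: empty sequence")
    return sum(kd[c] for c in seq) / len(seq)


@dataclass(frozen=True)
class PhyschemProfile:
    protein_id: str
    length_aa: int
    mw_da: float
    pi: float
    instability: float
    aliphatic: float
    gravy: float


def physchem_profile(record: ProteinRecord) -> PhyschemProfile:
    seq = record.seq
    return PhyschemProfile(
        protein_id=record.id,
        length_aa=len(seq),  # X included in the reported length
        mw_da=molecular_weight(seq),
        pi=isoelectric_point(seq),
        instability=instability_index(seq),
        aliphatic=aliphatic_index(seq),
        gravy=gravy(seq),
    )


def physchem_table(records) -> pd.DataFrame:
    """Descriptor table, one row per protein.  Molecular weight is reported
    in daltons (the scale on which such tables are conventionally printed,
    whatever the column header claims)."""
    rows = [physchem_profile(r) for r in records]
    return pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in rows],
            "length_aa": [r.length_aa for r in rows],
            "pi": [round(r.pi, 2) for r in rows],
            "mw_da": [round(r.mw_da, 2) for r in rows],
            "instability": [round(r.instability, 2) for r in rows],
            "aliphatic": [round(r.aliphatic, 2) for r in rows],
            "gravy": [round(r.gravy, 3) for r in rows],
        }
    )
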