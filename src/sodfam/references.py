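"""Embedded reference domains and metal-ligand coordinate tables.

The Cu/Zn reference is the curated human SOD1 polypeptide (cf. UniProt
P00441) and the Fe/Mn reference is a curated human SOD2 (Mn-SOD)
polypeptide (cf. UniProt P04179, 24-residue mitochondrial transit peptide
included).  These are configuration data — an internal coordinate system
for ligand bookkeeping — not measurements.  Ligand positions are indexed
0-based into the stored strings and are asserted against their expected
residue letters at import time, so an editing error in either sequence
fails loudly.

The bridging histidine shared by the Cu and Zn sites of canonical SOD1 is
assigned to the Cu set only, so that the four Cu ligands and three Zn
ligands sum to the seven conserved ligands of a catalytically complete
Cu/Zn domain.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import SodfamError

# Human SOD1, 154 aa (initiator Met included).  Cu ligands H47/H49/H64/H121,
# Zn ligands H72/H81/D84 in 1-based numbering.
HUMAN_SOD1 = (
    "MATKAVCVLKGDGPVQGIINFEQKESNGPVKVWGSIKGLTEGLHGFHVHEFGDNTAGCTSAG"
    "PHFNPLSRKHGGPKDEERHVGDLGNVTADKDGVADVSIEDSVISLSGDHCIIGRTLVVHEKA"
    "DDLGKGGNEESTKTGNAGSRLACGVIGIAQ"
)

# Curated human Mn-SOD polypeptide (transit peptide included).  The mature
# chain starts after residue 24.  Mn-linkage ligands His-His-Asp-His plus
# the active-centre triplet His-Tyr-Gln are indexed below.
HUMAN_SOD2 = (
    "MLSRAVCGTSRQLAPVLGYLGSRQKHSLPDLPYDYGALEPHINAQIMQLHHSKHHAAYVNNL"
    "NVTEEKYQEALAKGDVTAQIALQPALKFNGGGHINHSIFWTNLSPNGGGEPKGELLEAIKRD"
    "FGSFDKFKEKLTAASVGVQGSGWGWLGFNKERGHLQIAAACANQDPLQGTTGLIPLLGIDVW"
    "EHAYYLQYKNVRPDYLKAIWNVINWENVTERYMACKK"
)

_SOD2_MATURE_OFFSET = 24
HUMAN_SOD2_MATURE = HUMAN_SOD2[_SOD2_MATURE_OFFSET:]

#: split point between the N- and C-terminal halves of the Fe/Mn domain pair
_FE_SPLIT = 90


@dataclass(frozen=True)
class ReferenceDomain:
    """An embedded reference domain sequence used by the scanner."""

    name: str
    seq: str
    source_note: str = ""


def default_registry() -> tuple[ReferenceDomain, ...]:
    """The three reference domains the scanner searches with: the Cu/Zn-SOD
    domain and the N-/C-terminal halves of the Fe/Mn-SOD domain."""
    return (
        ReferenceDomain("SOD_CU", HUMAN_SOD1, "Cu/Zn-SOD domain, derived from human SOD1"),
        ReferenceDomain(
            "SOD_FE_N",
            HUMAN_SOD2_MATURE[:_FE_SPLIT],
            "Fe/Mn-SOD N-terminal half, derived from human SOD2",
        ),
        ReferenceDomain(
            "SOD_FE_C",
            HUMAN_SOD2_MATURE[_FE_SPLIT:],
            "Fe/Mn-SOD C-terminal half, derived from human SOD2",
        ),
    )


@dataclass(frozen=True)
class LigandReference:
    """Reference metal-ligand columns for one SOD family.

    Positions are 0-based indices into ``ref_seq``; ``*_expected`` gives the
    residue letter required at each position for the column to count as
    conserved.
    """

    family: str  # "CuZn" or "MnFe"
    ref_seq: str
    cu_positions: tuple[int, ...] = ()
    cu_expected: str = ""
    zn_positions: tuple[int, ...] = ()
    zn_expected: str = ""
    mn_positions: tuple[int, ...] = ()
    mn_expected: str = ""
    conf_positions: tuple[int, ...] = ()
    conf_expected: str = ""

    def __post_init__(self) -> None:
        for positions, expected, label in [
            (self.cu_positions, self.cu_expected, "Cu"),
            (self.zn_positions, self.zn_expected, "Zn"),
            (self.mn_positions, self.mn_expected, "Mn"),
            (self.conf_positions, self.conf_expected, "active-centre"),
        ]:
            if len(positions) != len(expected):
                raise SodfamError(f"{label} positions/expected length mismatch")
            for pos, aa in zip(positions, expected):
                if self.ref_seq[pos] != aa:
                    raise SodfamError(
                        f"{self.family} reference: expected {aa} at position {pos}, "
                        f"found {self.ref_seq[pos]}"
                    )

    def ligand_positions(self) -> tuple[tuple[int, str], ...]:
        """All ligand (position, expected residue) pairs, in sequence order."""
        pairs = list(zip(self.cu_positions, self.cu_expected))
        pairs += list(zip(self.zn_positions, self.zn_expected))
        pairs += list(zip(self.mn_positions, self.mn_expected))
        pairs += list(zip(self.conf_positions, self.conf_expected))
        return tuple(sorted(pairs))


#: Cu/Zn family: 4 Cu ligands + 3 Zn ligands = 7 conserved ligands.
CUZN_REFERENCE = LigandReference(
    family="CuZn",
    ref_seq=HUMAN_SOD1,
    cu_positions=(46, 48, 63, 120),
    cu_expected="HHHH",
    zn_positions=(71, 80, 83),
    zn_expected="HHD",
)

#: Fe/Mn family: His-His-Asp-His metal linkage + His-Tyr-Gln active centre.
#: Positions index the mature chain.
MNFE_REFERENCE = LigandReference(
    family="MnFe",
    ref_seq=HUMAN_SOD2_MATURE,
    mn_positions=(25, 73, 159, 163),
    mn_expected="HHDH",
    conf_positions=(29, 33, 143),
    conf_expected="HYQ",
)

#: the consensus of the most frequent Cu/Zn-SOD motif reported for oyster
#: SOD repertoires ("motif 1"); used by worked examples and tests
MOTIF1_CONSENSUS = "DHNHGLQIHEYGDMEHGCDTIGELYHNEH"
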