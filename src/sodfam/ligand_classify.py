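"""Conserved metal-ligand mapping and the five-group functional
classification.

Each candidate domain is threaded onto its family's ligand reference by
global alignment; a ligand column counts as conserved only when the aligned
query residue is exactly the expected one (no substitution, no gap) —
any ligand loss is treated as functional loss.  Domains are then labelled:

* all 4 Cu and all 3 Zn ligands      -> catalytically complete Cu/Zn-SOD
* 4 Cu only                          -> Cu-only
* 3 Zn only                          -> Zn-only
* neither set complete               -> metal-free
* Fe/Mn family with the full His-His-Asp-His linkage and His-Tyr-Gln
  active centre                      -> Mn-SOD

A multi-domain protein takes the best of its per-domain labels under the
priority complete > Cu-only > Zn-only > metal-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align import global_align, glocal_align
from .domain_scan import FAMILY_CUZN, FAMILY_MNFE, DomainArchitecture, DomainHit
from .io_formats import ProteinRecord, SodfamError
from .references import CUZN_REFERENCE, MNFE_REFERENCE, LigandReference

GROUP_MNSOD = "MnSOD"
GROUP_CUZN_ACTIVE = "CuZn_active"
GROUP_CU_ONLY = "Cu_only"
GROUP_ZN_ONLY = "Zn_only"
GROUP_METAL_FREE = "metal_free"
FIVE_GROUPS = (GROUP_MNSOD, GROUP_CUZN_ACTIVE, GROUP_CU_ONLY, GROUP_ZN_ONLY, GROUP_METAL_FREE)

_PRIORITY = {GROUP_CUZN_ACTIVE: 0, GROUP_CU_ONLY: 1, GROUP_ZN_ONLY: 2, GROUP_METAL_FREE: 3}


@dataclass(frozen=True)
class LigandProfile:
    """Per-domain conservation vector over the reference ligand columns."""

    protein_id: str
    domain_index: int
    family: str  # "CuZn" or "MnFe"
    conserved: tuple[bool, ...]  # over ligand_positions() order
    n_cu_conserved: int = 0
    n_zn_conserved: int = 0
    n_mn_conserved: int = 0
    n_conf_conserved: int = 0

    @property
    def n_total(self) -> int:
        return (
            self.n_cu_conserved + self.n_zn_conserved
            + self.n_mn_conserved + self.n_conf_conserved
        )


@dataclass(frozen=True)
class SodClass:
    protein_id: str
    group: str
    per_domain_groups: tuple[str, ...]
    rationale: str

    def __post_init__(self) -> None:
        if self.group not in FIVE_GROUPS:
            raise SodfamError(f"unknown group label {self.group!r}")


def map_ligands(
    domain_seq: str,
    ref: LigandReference,
    protein_id: str = "",
    domain_index: int = 0,
) -> LigandProfile:
    """Thread ``domain_seq`` onto the reference by global alignment and
    score each ligand column for strict conservation."""
    if len(domain_seq) < 40:
        raise SodfamError("map_ligands: domain sequence shorter than 40 residues")
    res = global_align(domain_seq, ref.ref_seq)
    ref_to_query = res.b_to_a_map()  # ref position -> query position
    conserved = []
    counts = {"cu": 0, "zn": 0, "mn": 0, "conf": 0}
    for kind, positions, expected in [
        ("cu", ref.cu_positions, ref.cu_expected),
        ("zn", ref.zn_positions, ref.zn_expected),
        ("mn", ref.mn_positions, ref.mn_expected),
        ("conf", ref.conf_positions, ref.conf_expected),
    ]:
        for pos, aa in zip(positions, expected):
            qpos = ref_to_query.get(pos)
            ok = qpos is not None and domain_seq[qpos] == aa
            if ok:
                counts[kind] += 1
            conserved.append((pos, ok))
    conserved.sort()
    return LigandProfile(
        protein_id=protein_id,
        domain_index=domain_index,
        family=ref.family,
        conserved=tuple(ok for _, ok in conserved),
        n_cu_conserved=counts["cu"],
        n_zn_conserved=counts["zn"],
        n_mn_conserved=counts["mn"],
        n_conf_conserved=counts["conf"],
    )


def ligand_columns_in_span(peptide: str, ref: LigandReference) -> int:
    """Thread a short peptide (e.g. a motif consensus) into the reference by
    semi-global alignment and count the ligand columns falling within the
    spanned reference region."""
    res = glocal_align(peptide, ref.ref_seq)
    return sum(res.a_start <= pos < res.a_end for pos, _ in ref.ligand_positions())


def _domain_label(profile: LigandProfile) -> str:
    if profile.family == "MnFe":
        n_expected = len(MNFE_REFERENCE.mn_positions) + len(MNFE_REFERENCE.conf_positions)
        complete = profile.n_mn_conserved + profile.n_conf_conserved == n_expected
        return GROUP_MNSOD if complete else GROUP_METAL_FREE
    cu_ok = profile.n_cu_conserved == len(CUZN_REFERENCE.cu_positions)
    zn_ok = profile.n_zn_conserved == len(CUZN_REFERENCE.zn_positions)
    if cu_ok and zn_ok:
        return GROUP_CUZN_ACTIVE
    if cu_ok:
        return GROUP_CU_ONLY
    if zn_ok:
        return GROUP_ZN_ONLY
    return GROUP_METAL_FREE


def classify(architecture: DomainArchitecture, profiles: list[LigandProfile]) -> SodClass:
    """Assign the protein-level five-group label from per-domain ligand
    profiles.  Classification is a pure function of the profile vectors."""
    if not profiles:
        raise SodfamError(f"classify: no ligand profiles for {architecture.protein_id}")
    per_domain = tuple(_domain_label(p) for p in profiles)
    if architecture.family_call == FAMILY_MNFE:
        group = GROUP_MNSOD if GROUP_MNSOD in per_domain else GROUP_METAL_FREE
        counts = ";".join(
            f"domain{p.domain_index}:mn={p.n_mn_conserved}/4,conf={p.n_conf_conserved}/3"
            for p in profiles
        )
    else:
        group = min(
            (g for g in per_domain if g != GROUP_MNSOD),
            key=lambda g: _PRIORITY[g],
            default=GROUP_METAL_FREE,
        )
        counts = ";".join(
            f"domain{p.domain_index}:cu={p.n_cu_conserved}/4,zn={p.n_zn_conserved}/3"
            for p in profiles
        )
    return SodClass(
        protein_id=architecture.protein_id,
        group=group,
        per_domain_groups=per_domain,
        rationale=counts,
    )


def profile_protein(
    record: ProteinRecord,
    architecture: DomainArchitecture,
    hits: list[DomainHit],
    cuzn_ref: LigandReference = CUZN_REFERENCE,
    mnfe_ref: LigandReference = MNFE_REFERENCE,
) -> list[LigandProfile]:
    """Build per-domain ligand profiles for one scanned protein.

    Cu/Zn-family proteins are profiled per SOD_CU hit span; Fe/Mn-family
    proteins are profiled once against the full Fe/Mn reference (its ligand
    columns span both domain halves).
    """
    if architecture.family_call == FAMILY_MNFE:
        return [map_ligands(record.seq, mnfe_ref, protein_id=record.id, domain_index=0)]
    profiles = []
    cu_hits = sorted(
        (h for h in hits if h.protein_id == record.id and h.domain_name == "SOD_CU"),
        key=lambda h: h.q_start,
    )
    for i, h in enumerate(cu_hits):
        domain_seq = record.seq[h.q_start : h.q_end]
        profiles.append(map_ligands(domain_seq, cuzn_ref, protein_id=record.id, domain_index=i))
    return profiles


def classify_proteins(records, architectures, hits) -> tuple[list[SodClass], list[LigandProfile]]:
    """Profile and classify every candidate (non-``none``) architecture."""
    rec_by_id = {r.id: r for r in records}
    calls: list[SodClass] = []
    all_profiles: list[LigandProfile] = []
    for arch in architectures:
        if arch.family_call not in (FAMILY_CUZN, FAMILY_MNFE):
            continue
        profiles = profile_protein(rec_by_id[arch.protein_id], arch, hits)
        if not profiles:
            continue
        all_profiles.extend(profiles)
        calls.append(classify(arch, profiles))
    return calls, all_profiles


def classification_table(calls, profiles) -> pd.DataFrame:
    prof_rows = [
        {
            "protein_id": p.protein_id,
            "domain_index": p.domain_index,
            "n_cu": p.n_cu_conserved,
            "n_zn": p.n_zn_conserved,
            "n_mn": p.n_mn_conserved,
            "n_conf": p.n_conf_conserved,
        }
        for p in profiles
    ]
    prof_df = pd.DataFrame(
        prof_rows, columns=["protein_id", "domain_index", "n_cu", "n_zn", "n_mn", "n_conf"]
    )
    call_df = pd.DataFrame(
        [{"protein_id": c.protein_id, "group": c.group, "rationale": c.rationale} for c in calls],
        columns=["protein_id", "group", "rationale"],
    )
    return prof_df.merge(call_df, on="protein_id", how="left")


def recover_knockouts(truth: pd.DataFrame, calls: list[SodClass]) -> pd.DataFrame:
    """Compare calls against a generator truth table.

    ``truth`` needs columns ``entity_id`` and ``planted_group``.  Returns
    per-group precision/recall; raises if any truth id lacks a call.
    """
    call_by_id = {c.protein_id: c.group for c in calls}
    missing = sorted(set(truth["entity_id"]) - set(call_by_id))
    if missing:
        raise SodfamError(f"recover_knockouts: no calls for ids {', '.join(missing)}")
    merged = truth.assign(called_group=[call_by_id[e] for e in truth["entity_id"]])
    rows = []
    for group in FIVE_GROUPS:
        tp = int(((merged["planted_group"] == group) & (merged["called_group"] == group)).sum())
        fp = int(((merged["planted_group"] != group) & (merged["called_group"] == group)).sum())
        fn = int(((merged["planted_group"] == group) & (merged["called_group"] != group)).sum())
        if tp + fp + fn == 0:
            continue
        rows.append(
            {
                "group": group,
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "precision": tp / (tp + fp) if tp + fp else float("nan"),
                "recall": tp / (tp + fn) if tp + fn else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["group", "tp", "fp", "fn", "precision", "recall"])
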