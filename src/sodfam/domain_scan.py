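"""Candidate identification by local alignment against embedded reference
domains with Karlin-Altschul E-value thresholding.

The published identification stage ran BLAST and a domain-HMM search with
the same cutoff (E <= 1e-10); because the two thresholds coincide, the two
criteria collapse to a single embedded-reference local-alignment test with
that cutoff.  Repeated domains are found by best-hit-then-mask iteration:
the best-scoring local hit over all references is recorded if significant,
its span is masked, and the scan repeats on the unmasked remainder.  Later
hits may not overlap earlier masked spans at all.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .align import local_align
from .io_formats import ProteinRecord, SodfamError
from .references import ReferenceDomain, default_registry

logger = logging.getLogger("sodfam")

#: gapped BLOSUM62 Karlin-Altschul constants (fixed, not estimated per query)
KA_LAMBDA = 0.267
KA_K = 0.041

#: minimum aligned columns for a reportable hit; prevents spurious
#: micro-hits in the segments left over after masking
MIN_HIT_COLS = 40

FAMILY_CUZN = "CuZn_family"
FAMILY_MNFE = "MnFe_family"
FAMILY_NONE = "none"


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    domain_name: str
    q_start: int  # 0-based half-open span on the protein
    q_end: int
    score: float
    evalue: float

    def __post_init__(self) -> None:
        if self.q_start >= self.q_end:
            raise SodfamError(f"hit on {self.protein_id}: empty span")
        if self.evalue < 0:
            raise SodfamError("negative E-value")


@dataclass(frozen=True)
class DomainArchitecture:
    protein_id: str
    ordered_domains: tuple[str, ...]
    n_sod_cu: int
    family_call: str


def evalue(score: float, m: int, n: int, lam: float = KA_LAMBDA, k: float = KA_K) -> float:
    """Karlin-Altschul expected number of chance hits:
    E = K * m * n * exp(-lambda * score)."""
    if m <= 0 or n <= 0:
        raise SodfamError("evalue: sequence lengths must be positive")
    if score < 0:
        raise SodfamError("evalue: score must be non-negative")
    return k * m * n * math.exp(-lam * score)


def scan_domains(
    protein: ProteinRecord,
    registry: tuple[ReferenceDomain, ...] | None = None,
    threshold: float = 1.0e-10,
    min_hit_cols: int = MIN_HIT_COLS,
) -> tuple[DomainArchitecture, list[DomainHit]]:
    """Scan one protein against the reference registry.

    Returns the domain architecture and the recorded hits sorted by start
    position.  Ties between equally scoring references are broken by
    registry order (logged).
    """
    if registry is None:
        registry = default_registry()
    if not registry:
        raise SodfamError("scan_domains: empty reference registry")

    m = len(protein.seq)
    hits: list[DomainHit] = []
    # unmasked segments as (offset, subsequence)
    segments: list[tuple[int, str]] = [(0, protein.seq)]
    while True:
        best = None  # (score, registry_idx, seg_offset, result)
        for seg_off, seg in segments:
            if len(seg) < min_hit_cols:
                continue
            for reg_idx, ref in enumerate(registry):
                res = local_align(seg, ref.seq)
                if res.n_cols < min_hit_cols:
                    continue
                e = evalue(res.score, m, len(ref.seq))
                if e > threshold:
                    continue
                key = (-res.score, reg_idx, seg_off + res.a_start)
                if best is None or key < best[0]:
                    best = (key, reg_idx, seg_off, res, e)
                elif key == best[0]:
                    logger.info(
                        "scan_domains %s: tie between references resolved by registry order",
                        protein.id,
                    )
        if best is None:
            break
        _, reg_idx, seg_off, res, e = best
        ref = registry[reg_idx]
        q_start = seg_off + res.a_start
        q_end = seg_off + res.a_end
        hits.append(
            DomainHit(
                protein_id=protein.id,
                domain_name=ref.name,
                q_start=q_start,
                q_end=q_end,
                score=res.score,
                evalue=e,
            )
        )
        # mask: split the segment containing the hit
        new_segments: list[tuple[int, str]] = []
        for off, seg in segments:
            seg_end = off + len(seg)
            if off <= q_start and q_end <= seg_end:
                left = seg[: q_start - off]
                right = seg[q_end - off :]
                if left:
                    new_segments.append((off, left))
                if right:
                    new_segments.append((q_end, right))
            else:
                new_segments.append((off, seg))
        segments = new_segments

    hits.sort(key=lambda h: h.q_start)
    ordered = tuple(h.domain_name for h in hits)
    n_sod_cu = sum(1 for d in ordered if d == "SOD_CU")
    if any(d.startswith("SOD_FE") for d in ordered):
        family = FAMILY_MNFE
    elif n_sod_cu > 0:
        family = FAMILY_CUZN
    else:
        family = FAMILY_NONE
    arch = DomainArchitecture(
        protein_id=protein.id,
        ordered_domains=ordered,
        n_sod_cu=n_sod_cu,
        family_call=family,
    )
    return arch, hits


def scan_proteome(
    records,
    registry: tuple[ReferenceDomain, ...] | None = None,
    threshold: float = 1.0e-10,
    min_protein_len: int = 100,
) -> tuple[list[DomainArchitecture], list[DomainHit]]:
    """Scan a collection of proteins; sequences shorter than
    ``min_protein_len`` are filtered out as partial coding products."""
    archs: list[DomainArchitecture] = []
    all_hits: list[DomainHit] = []
    for rec in records:
        if len(rec.seq) < min_protein_len:
            continue
        arch, hits = scan_domains(rec, registry=registry, threshold=threshold)
        archs.append(arch)
        all_hits.extend(hits)
    return archs, all_hits


def candidates(architectures) -> list[DomainArchitecture]:
    """Architectures with at least one significant domain hit."""
    return [a for a in architectures if a.family_call != FAMILY_NONE]


def hits_table(architectures, hits) -> pd.DataFrame:
    arch_by_id = {a.protein_id: a for a in architectures}
    rows = []
    for h in hits:
        a = arch_by_id[h.protein_id]
        rows.append(
            {
                "protein_id": h.protein_id,
                "domain_name": h.domain_name,
                "start": h.q_start,
                "end": h.q_end,
                "score": h.score,
                "evalue": h.evalue,
                "n_sod_cu": a.n_sod_cu,
                "family_call": a.family_call,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "domain_name", "start", "end",
            "score", "evalue", "n_sod_cu", "family_call",
        ],
    )
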