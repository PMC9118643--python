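"""Motif-architecture annotation from provided motif models, and promoter
extraction/scanning with user-supplied position weight matrices.

De-novo motif discovery is out of scope: models are built from aligned
instance sets (``pwm_from_instances``) or loaded from a plain TSV matrix.
Scanning reports the best non-overlapping matches per model (greedy by
score, ties to the leftmost start) above a threshold expressed as a
fraction of the model's maximum attainable score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GeneLocus, SodfamError

DNA_LETTERS = "ACGT"
PROTEIN_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifModel:
    """A log-odds position weight matrix over a DNA or protein alphabet."""

    motif_id: str
    alphabet: str  # "dna" or "protein"
    pwm: np.ndarray  # length x |letters|, log2 odds
    consensus: str
    background: np.ndarray

    @property
    def letters(self) -> str:
        return DNA_LETTERS if self.alphabet == "dna" else PROTEIN_LETTERS

    def __len__(self) -> int:
        return self.pwm.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.pwm.max(axis=1).sum())

    def score(self, window: str) -> float:
        idx = [self.letters.find(c) for c in window]
        if any(i < 0 for i in idx):
            return float("-inf")  # ambiguous/foreign letters never match
        return float(self.pwm[np.arange(len(self)), idx].sum())


@dataclass(frozen=True)
class MotifMatch:
    motif_id: str
    start: int  # 0-based half-open on the scanned (forward) sequence
    end: int
    score: float
    strand: str = "+"


@dataclass(frozen=True)
class MotifString:
    """Ordered motif occurrence summary for one protein."""

    protein_id: str
    ordered_motif_ids: tuple[str, ...]
    combination: str  # dash-joined, e.g. "1-3-2"


@dataclass(frozen=True)
class PromoterRegion:
    gene_id: str
    seq: str
    truncated: bool = False
    anchor: str = "gene_start"


def _infer_alphabet(instances) -> str:
    letters = set("".join(instances))
    return "dna" if letters <= set(DNA_LETTERS + "N") else "protein"


def pwm_from_instances(
    motif_id: str,
    instances: list[str],
    pseudocount: float = 0.1,
    alphabet: str | None = None,
    background: np.ndarray | None = None,
) -> MotifModel:
    """Build a log-odds PWM from aligned equal-length instances:
    column counts plus a flat pseudocount, normalised, log2 against the
    background distribution (uniform unless given)."""
    if len(instances) < 2:
        raise SodfamError("pwm_from_instances: need at least 2 instances")
    instances = [s.upper() for s in instances]
    lengths = {len(s) for s in instances}
    if len(lengths) != 1:
        raise SodfamError(f"pwm_from_instances: unequal instance lengths {sorted(lengths)}")
    if pseudocount <= 0:
        raise SodfamError("pwm_from_instances: pseudocount must be positive")
    if alphabet is None:
        alphabet = _infer_alphabet(instances)
    letters = DNA_LETTERS if alphabet == "dna" else PROTEIN_LETTERS
    width = lengths.pop()
    counts = np.zeros((width, len(letters)))
    for s in instances:
        for i, c in enumerate(s):
            j = letters.find(c)
            if j < 0:
                raise SodfamError(f"pwm_from_instances: letter {c!r} outside {alphabet} alphabet")
            counts[i, j] += 1
    if background is None:
        background = np.full(len(letters), 1.0 / len(letters))
    background = np.asarray(background, dtype=float)
    probs = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + pseudocount * len(letters))
    pwm = np.log2(probs / background)
    consensus = "".join(letters[j] for j in probs.argmax(axis=1))
    return MotifModel(
        motif_id=str(motif_id), alphabet=alphabet, pwm=pwm,
        consensus=consensus, background=background,
    )


def _candidate_matches(seq: str, model: MotifModel, score_fraction: float) -> list[MotifMatch]:
    w = len(model)
    cutoff = score_fraction * model.max_score
    out = []
    for i in range(len(seq) - w + 1):
        s = model.score(seq[i : i + w])
        if s >= cutoff:
            out.append(MotifMatch(model.motif_id, i, i + w, s))
    return out


def _greedy_nonoverlap(matches: list[MotifMatch]) -> list[MotifMatch]:
    chosen: list[MotifMatch] = []
    for m in sorted(matches, key=lambda m: (-m.score, m.start)):
        if all(m.end <= c.start or m.start >= c.end for c in chosen):
            chosen.append(m)
    return sorted(chosen, key=lambda m: m.start)


def scan_motifs(
    seq: str,
    models: list[MotifModel],
    score_fraction: float = 0.8,
    protein_id: str = "",
) -> tuple[MotifString, list[MotifMatch]]:
    """Report the best non-overlapping occurrences of each model in
    positional order, and the dash-joined combination string."""
    if not (0 < score_fraction <= 1):
        raise SodfamError("scan_motifs: score_fraction must lie in (0, 1]")
    all_matches: list[MotifMatch] = []
    for model in models:
        all_matches.extend(_greedy_nonoverlap(_candidate_matches(seq, model, score_fraction)))
    all_matches.sort(key=lambda m: (m.start, m.motif_id))
    ordered = tuple(m.motif_id for m in all_matches)
    return (
        MotifString(protein_id=protein_id, ordered_motif_ids=ordered, combination="-".join(ordered)),
        all_matches,
    )


def extract_promoters(
    genome: dict[str, str],
    loci: list[GeneLocus],
    length: int = 2000,
) -> list[PromoterRegion]:
    """Extract the region upstream of each gene's 5' end, strand-corrected:
    for + strand genes the ``length`` bases before the gene start, for -
    strand genes the reverse complement of the bases after the gene end.
    Regions truncated at a contig boundary are flagged."""
    out = []
    for g in loci:
        if g.chrom not in genome:
            raise SodfamError(f"extract_promoters: chromosome {g.chrom!r} absent from genome")
        chrom_seq = genome[g.chrom]
        if g.strand == "+":
            lo = max(0, g.start - length)
            seq = chrom_seq[lo : g.start]
            truncated = g.start - length < 0
        else:
            hi = min(len(chrom_seq), g.end + length)
            seq = revcomp(chrom_seq[g.end : hi])
            truncated = g.end + length > len(chrom_seq)
        out.append(PromoterRegion(gene_id=g.gene_id, seq=seq, truncated=truncated))
    return out


def scan_promoters(
    promoters: list[PromoterRegion],
    models: list[MotifModel],
    score_fraction: float = 0.9,
    family_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, MotifMatch]]]:
    """Scan promoter regions with DNA PWMs on both strands.

    Matches are selected greedily per model and per strand; a palindromic
    site therefore counts once on each strand.  Returns per-gene per-model
    (and per-family, if a motif->family map is given) hit counts plus the
    located matches with promoter-local forward coordinates.
    """
    for model in models:
        if model.alphabet != "dna":
            raise SodfamError(f"scan_promoters: model {model.motif_id} is not a DNA model")
    rows = []
    located: list[tuple[str, MotifMatch]] = []
    for prom in promoters:
        counts: dict[str, int] = {m.motif_id: 0 for m in models}
        for model in models:
            fwd = _greedy_nonoverlap(_candidate_matches(prom.seq, model, score_fraction))
            rev_raw = _candidate_matches(revcomp(prom.seq), model, score_fraction)
            # map reverse-strand coordinates back onto the forward sequence
            n = len(prom.seq)
            rev = [
                MotifMatch(m.motif_id, n - m.end, n - m.start, m.score, strand="-")
                for m in _greedy_nonoverlap(rev_raw)
            ]
            for m in fwd + rev:
                counts[model.motif_id] += 1
                located.append((prom.gene_id, m))
        row = {"gene_id": prom.gene_id, **{f"motif_{k}": v for k, v in counts.items()}}
        if family_map:
            fam_counts: dict[str, int] = {}
            for mid, c in counts.items():
                fam = family_map.get(mid, "unassigned")
                fam_counts[fam] = fam_counts.get(fam, 0) + c
            row.update({f"family_{k}": v for k, v in sorted(fam_counts.items())})
        rows.append(row)
    return pd.DataFrame(rows), located


def matches_table(located: list[tuple[str, MotifMatch]]) -> pd.DataFrame:
    """BED-like table of matches (0-based half-open coordinates)."""
    return pd.DataFrame(
        [
            {
                "seq_id": gene_id,
                "start": m.start,
                "end": m.end,
                "motif_id": m.motif_id,
                "score": round(m.score, 4),
                "strand": m.strand,
            }
            for gene_id, m in located
        ],
        columns=["seq_id", "start", "end", "motif_id", "score", "strand"],
    )


def read_pwm_tsv(path) -> MotifModel:
    """Read a PWM from a plain TSV: header ``pos letter1 letter2 ...`` and
    one probability row per position; converted to log2 odds against a
    uniform background."""
    df = pd.read_csv(path, sep="\t")
    letters = "".join(df.columns[1:])
    if letters == DNA_LETTERS:
        alphabet = "dna"
    elif letters == PROTEIN_LETTERS:
        alphabet = "protein"
    else:
        raise SodfamError(f"read_pwm_tsv: unrecognised alphabet columns {letters!r}")
    probs = df.iloc[:, 1:].to_numpy(dtype=float)
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise SodfamError("read_pwm_tsv: rows must be normalised probabilities")
    bg = np.full(len(letters), 1.0 / len(letters))
    pwm = np.log2(np.maximum(probs, 1e-9) / bg)
    consensus = "".join(letters[j] for j in probs.argmax(axis=1))
    return MotifModel(
        motif_id=str(path), alphabet=alphabet, pwm=pwm, consensus=consensus, background=bg
    )
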