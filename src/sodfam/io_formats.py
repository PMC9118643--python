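"""Core record types and readers/writers for the formats the pipeline touches.

Coordinates are converted to 0-based half-open intervals at parse time and
back to 1-based inclusive on write; GFF3 on disk stays 1-based inclusive.
A single internal convention avoids off-by-one errors in promoter extraction
and window arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("sodfam")

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: the 20 standard residues plus the ambiguity letter X
PROTEIN_ALPHABET = AMINO_ACIDS | {"X"}
DNA_ALPHABET = frozenset("ACGTN")


class SodfamError(ValueError):
    """Base class for input-contract violations."""


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence; the unit of all sequence analysis.

    ``seq`` is upper case over the 20 standard letters plus the ambiguity
    letter X.  ``source`` is a free-text provenance tag.
    """

    id: str
    seq: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SodfamError(f"protein id must be a whitespace-free token, got {self.id!r}")
        if not self.seq:
            raise SodfamError(f"protein {self.id}: empty sequence")
        bad = set(self.seq) - PROTEIN_ALPHABET
        if bad:
            raise SodfamError(
                f"protein {self.id}: letters {sorted(bad)} outside the amino-acid alphabet"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneLocus:
    """A gene interval on a chromosome.

    ``start``/``end`` are 0-based half-open internally.  ``rank`` is the
    dense 1..n ordinal of the gene along its chromosome, sorted by start
    (ties broken by end, then id) — the tandem-duplication rule needs a
    total order.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    rank: int | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise SodfamError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise SodfamError(f"gene {self.gene_id}: unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RunConfig:
    """Pipeline thresholds.  Defaults are the study's stated criteria:
    E-value cutoff 1e-10 for domain identification, the 70/70
    coverage/identity rule for duplicate gene pairs, tandem arrays defined
    by at most five intervening genes within a 100-kb window, 2000-bp
    promoters, and ANOVA significance at 0.05."""

    evalue_threshold: float = 1.0e-10
    dup_coverage: float = 0.70
    dup_identity: float = 0.70
    tandem_max_intervening: int = 5
    tandem_window_bp: int = 100_000
    promoter_len_bp: int = 2000
    anova_alpha: float = 0.05
    rng_seed: int = 0
    min_protein_len: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.dup_coverage <= 1 and 0 < self.dup_identity <= 1):
            raise SodfamError("dup_coverage and dup_identity must be fractions in (0, 1]")
        if self.evalue_threshold <= 0:
            raise SodfamError("evalue_threshold must be positive")
        if not (0 < self.anova_alpha < 1):
            raise SodfamError("anova_alpha must lie in (0, 1)")

    def replace(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    Sequences are upper-cased with whitespace stripped; duplicate ids and
    empty files are errors.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(" ", "").replace("*", "")
        records.append(ProteinRecord(id=rec.id, seq=seq, source=str(path)))
        seen[rec.id] = seen.get(rec.id, 0) + 1
    dupes = sorted(k for k, v in seen.items() if v > 1)
    if dupes:
        raise SodfamError(f"duplicate FASTA ids in {path}: {', '.join(dupes)}")
    if not records:
        raise SodfamError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    seqs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_nucleotide_fasta(path: str | Path) -> dict[str, str]:
    """Read a nucleotide FASTA (genome/contigs) into an id → sequence map."""
    path = Path(path)
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise SodfamError(f"duplicate FASTA ids in {path}: {rec.id}")
        genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise SodfamError(f"no FASTA records found in {path}")
    return genome


def write_nucleotide_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
#
# A compact validating reader for gene features.  It enforces the error
# contract (column count with line number, start <= end, known strand) and
# keeps the on-disk 1-based inclusive convention at the boundary.


def assign_ranks(loci: Sequence[GeneLocus]) -> list[GeneLocus]:
    """Return loci sorted per chromosome with dense 1..n ranks by start
    (ties by end, then gene id)."""
    out: list[GeneLocus] = []
    by_chrom: dict[str, list[GeneLocus]] = {}
    for loc in loci:
        by_chrom.setdefault(loc.chrom, []).append(loc)
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.gene_id))
        out.extend(replace(g, rank=i + 1) for i, g in enumerate(ordered))
    return out


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def read_gff3(path: str | Path, feature_type: str = "gene") -> list[GeneLocus]:
    """Read gene features from a GFF3 file into ranked :class:`GeneLocus`.

    On-disk coordinates are 1-based inclusive; internally they become
    0-based half-open.  Malformed lines raise with the line number.
    """
    path = Path(path)
    loci: list[GeneLocus] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise SodfamError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols
            if ftype != feature_type:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise SodfamError(f"{path}:{lineno}: non-integer coordinates") from None
            if start1 > end1:
                raise SodfamError(f"{path}:{lineno}: start {start1} > end {end1}")
            if strand not in ("+", "-"):
                raise SodfamError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
            attrs = _parse_gff_attributes(attr_s)
            gene_id = attrs.get("ID") or attrs.get("Name")
            if not gene_id:
                raise SodfamError(f"{path}:{lineno}: feature without ID attribute")
            if gene_id in seen:
                raise SodfamError(f"{path}:{lineno}: duplicate gene id {gene_id}")
            seen.add(gene_id)
            loci.append(
                GeneLocus(gene_id=gene_id, chrom=chrom, start=start1 - 1, end=end1, strand=strand)
            )
    if not loci:
        raise SodfamError(f"no {feature_type} features found in {path}")
    return assign_ranks(loci)


def write_gff3(loci: Iterable[GeneLocus], path: str | Path, source: str = "sodfam") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in loci:
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        source,
                        "gene",
                        str(g.start + 1),  # back to 1-based inclusive
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# TSV


def write_tsv(df, path: str | Path) -> None:
    """Write a result table deterministically (fixed float formatting)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
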