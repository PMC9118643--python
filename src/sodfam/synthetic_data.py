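"""Synthetic-data generators with machine-readable truth tables.

Every fixture the pipeline consumes can be generated here: SOD-like
proteins with controlled ligand knockouts and 1-4 repeated domains, toy
chromosomes carrying tandem gene arrays plus unrelated decoy genes
(optionally with a collinear partner chromosome), promoters with planted
motif sites, and negative-binomial count matrices with planted condition
effects.  Generation is a pure function of (parameters, seed): the same
call yields byte-identical output.

Knockout substitutions are ligand -> Ala (chemically inert,
alignment-stable).  Background substitutions are drawn from
BLOSUM62-conditional probabilities (P(b|a) proportional to 2^(S(a,b)/2)),
giving realistic divergence without destroying alignability, and never
touch reference ligand columns except where a knockout instructs it.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    GeneLocus,
    ProteinRecord,
    SodfamError,
    assign_ranks,
    write_fasta,
    write_gff3,
    write_nucleotide_fasta,
)
from .ligand_classify import (
    FIVE_GROUPS,
    GROUP_CU_ONLY,
    GROUP_CUZN_ACTIVE,
    GROUP_METAL_FREE,
    GROUP_MNSOD,
    GROUP_ZN_ONLY,
)
from .references import CUZN_REFERENCE, MNFE_REFERENCE

_AA = "ACDEFGHIKLMNPQRSTVWY"


@functools.lru_cache(maxsize=1)
def _blosum_conditional() -> np.ndarray:
    """P(b | a) over the 20 residues, b != a, proportional to
    2^(S(a,b)/2) under BLOSUM62."""
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    n = len(_AA)
    probs = np.zeros((n, n))
    for i, a in enumerate(_AA):
        for j, b in enumerate(_AA):
            if i != j:
                probs[i, j] = 2.0 ** (m[a, b] / 2.0)
        probs[i] /= probs[i].sum()
    return probs


def _mutate(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    protected: frozenset[int] = frozenset(),
) -> str:
    """Substitute each unprotected position with probability ``rate`` using
    BLOSUM62-conditional targets."""
    cond = _blosum_conditional()
    out = list(seq)
    for i in range(len(out)):
        if i in protected or out[i] not in _AA:
            continue
        if rng.random() < rate:
            ai = _AA.index(out[i])
            out[i] = _AA[rng.choice(20, p=cond[ai])]
    return "".join(out)


# ---------------------------------------------------------------------------
# protein families


_GROUP_KNOCKOUTS = {
    GROUP_CUZN_ACTIVE: (),
    GROUP_CU_ONLY: CUZN_REFERENCE.zn_positions,
    GROUP_ZN_ONLY: CUZN_REFERENCE.cu_positions,
    GROUP_METAL_FREE: CUZN_REFERENCE.cu_positions + CUZN_REFERENCE.zn_positions,
    GROUP_MNSOD: (),
}


def _truth_row(entity_id, group=None, knockouts=(), array_id=None, effect=None, seed=None):
    return {
        "entity_id": entity_id,
        "planted_group": group,
        "planted_knockouts": ",".join(map(str, knockouts)),
        "planted_array_id": array_id,
        "planted_effect": effect,
        "seed": seed,
    }


def make_group_protein(
    group: str,
    background_mut_rate: float,
    rng: np.random.Generator,
    protein_id: str,
) -> tuple[ProteinRecord, dict]:
    """One synthetic protein of a given functional group: the family
    template with the group-defining ligand knockouts (ligand -> Ala) plus
    background substitutions away from ligand columns."""
    if group not in FIVE_GROUPS:
        raise SodfamError(f"unknown group {group!r}")
    if group == GROUP_MNSOD:
        template = MNFE_REFERENCE.ref_seq
        ligand_cols = frozenset(p for p, _ in MNFE_REFERENCE.ligand_positions())
    else:
        template = CUZN_REFERENCE.ref_seq
        ligand_cols = frozenset(p for p, _ in CUZN_REFERENCE.ligand_positions())
    knockouts = _GROUP_KNOCKOUTS[group]
    seq = list(template)
    for pos in knockouts:
        seq[pos] = "A"
    seq = _mutate("".join(seq), background_mut_rate, rng, protected=ligand_cols)
    record = ProteinRecord(id=protein_id, seq=seq, source=f"synthetic:{group}")
    return record, _truth_row(protein_id, group=group, knockouts=knockouts)


def make_protein_family(
    n_per_group: int = 10,
    background_mut_rate: float = 0.05,
    seed: int = 0,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """``n_per_group`` proteins for each of the five functional groups."""
    if not (0 <= background_mut_rate <= 0.3):
        raise SodfamError("background_mut_rate must lie in [0, 0.3]")
    rng = np.random.default_rng(seed)
    records, rows = [], []
    for group in FIVE_GROUPS:
        for i in range(n_per_group):
            pid = f"{group.lower()}_{i:02d}"
            rec, row = make_group_protein(group, background_mut_rate, rng, pid)
            row["seed"] = seed
            records.append(rec)
            rows.append(row)
    return records, pd.DataFrame(rows)


def make_domain_concatemer(
    n_copies: int = 4,
    mut_rate: float = 0.15,
    seed: int = 7,
    protein_id: str = "concatemer",
    knockout_zn: bool = False,
) -> ProteinRecord:
    """A multi-domain Cu/Zn-SOD emulation: ``n_copies`` independently
    mutated copies of the Cu/Zn template concatenated head to tail."""
    if n_copies < 1:
        raise SodfamError("n_copies must be >= 1")
    rng = np.random.default_rng(seed)
    ligand_cols = frozenset(p for p, _ in CUZN_REFERENCE.ligand_positions())
    copies = []
    for _ in range(n_copies):
        seq = list(CUZN_REFERENCE.ref_seq)
        if knockout_zn:
            for pos in CUZN_REFERENCE.zn_positions:
                seq[pos] = "A"
        copies.append(_mutate("".join(seq), mut_rate, rng, protected=ligand_cols))
    return ProteinRecord(id=protein_id, seq="".join(copies), source="synthetic:concatemer")


def random_protein(length: int, seed: int) -> ProteinRecord:
    """A uniform-composition random sequence (a non-homolog negative)."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(_AA), size=length))
    return ProteinRecord(id=f"random_{seed}", seq=seq, source="synthetic:random")


# ---------------------------------------------------------------------------
# genomes


@dataclass(frozen=True)
class ArraySpec:
    """A planted tandem array: ``size`` member genes, consecutive member
    starts ``spacing_bp`` apart, with ``intervening`` decoy genes between
    consecutive members."""

    size: int = 3
    spacing_bp: int = 10_000
    intervening: int = 0

    def __post_init__(self) -> None:
        if self.size < 2:
            raise SodfamError("array size must be >= 2")


@dataclass
class SyntheticGenome:
    genome: dict[str, str]
    loci: list[GeneLocus]
    proteins: list[ProteinRecord]
    truth: pd.DataFrame
    partner_genome: dict[str, str] | None = None
    partner_loci: list[GeneLocus] | None = None
    partner_proteins: list[ProteinRecord] | None = None
    homolog_pairs: list[tuple[str, str]] = field(default_factory=list)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def make_genome(
    arrays: list[ArraySpec] | None = None,
    decoys: int = 6,
    collinear_partner: bool = False,
    seed: int = 0,
    gene_len: int = 1500,
    spacing_bp: int = 8000,
    extra_records: list[ProteinRecord] | None = None,
    n_shared: int = 8,
) -> SyntheticGenome:
    """A toy chromosome with planted tandem arrays, decoy genes and
    (optionally) a partner chromosome sharing an ordered subset of genes
    for collinearity tests.

    Array members are near-copies (2% background divergence) of the Cu/Zn
    family template, so they satisfy the 70/70 duplication rule by
    construction; decoys are shuffled-composition non-homologs.
    ``extra_records`` (e.g. a generated protein family) are placed as
    additional ordinary genes.
    """
    arrays = arrays if arrays is not None else [ArraySpec()]
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    ligand_cols = frozenset(p for p, _ in CUZN_REFERENCE.ligand_positions())

    # build the gene order: extras, decoys and arrays interleaved
    entries: list[tuple[str, ProteinRecord, str | None, int | None]] = []
    # (kind, record, array_id, forced_start)
    decoy_counter = 0

    def new_decoy() -> ProteinRecord:
        nonlocal decoy_counter
        shuffled = "".join(rng.permutation(list(CUZN_REFERENCE.ref_seq)))
        rec = ProteinRecord(id=f"decoy_{decoy_counter:02d}", seq=shuffled, source="synthetic:decoy")
        decoy_counter += 1
        return rec

    for rec in extra_records or []:
        entries.append(("extra", rec, None, None))
    for _ in range(decoys):
        entries.append(("decoy", new_decoy(), None, None))

    loci: list[GeneLocus] = []
    proteins: list[ProteinRecord] = []
    rows: list[dict] = []
    cursor = 10_000
    for kind, rec, array_id, _ in entries:
        strand = "+" if rng.random() < 0.5 else "-"
        loci.append(GeneLocus(rec.id, chrom, cursor, cursor + gene_len, strand))
        proteins.append(rec)
        rows.append(_truth_row(rec.id, group=None if kind == "decoy" else "extra", seed=seed))
        cursor += spacing_bp

    for ai, spec in enumerate(arrays):
        if spec.spacing_bp < (spec.intervening + 1) * gene_len + 100:
            raise SodfamError(f"array {ai}: spacing too small for intervening genes — overlap")
        array_id = f"array_{ai}"
        founder = _mutate(CUZN_REFERENCE.ref_seq, 0.10, rng, protected=ligand_cols)
        # distinct arrays share template ancestry, so keep them farther apart
        # than the tandem window or their cross-pairs would merge them
        cursor += 120_000
        for mi in range(spec.size):
            member_seq = _mutate(founder, 0.02, rng, protected=ligand_cols)
            rec = ProteinRecord(
                id=f"{array_id}_g{mi}", seq=member_seq, source=f"synthetic:{array_id}"
            )
            start = cursor
            loci.append(GeneLocus(rec.id, chrom, start, start + gene_len, "+"))
            proteins.append(rec)
            rows.append(_truth_row(rec.id, group=GROUP_CUZN_ACTIVE, array_id=array_id, seed=seed))
            if mi < spec.size - 1:
                gap = spec.spacing_bp // (spec.intervening + 1)
                for ii in range(spec.intervening):
                    d = new_decoy()
                    dstart = start + (ii + 1) * gap
                    loci.append(GeneLocus(d.id, chrom, dstart, dstart + gene_len, "+"))
                    proteins.append(d)
                    rows.append(_truth_row(d.id, seed=seed))
                cursor += spec.spacing_bp
        cursor += spacing_bp

    loci = assign_ranks(loci)
    chrom_len = cursor + 10_000
    genome = {chrom: _random_dna(rng, chrom_len)}
    truth = pd.DataFrame(rows)

    out = SyntheticGenome(genome=genome, loci=loci, proteins=proteins, truth=truth)

    if collinear_partner:
        order = {g.gene_id: g.rank for g in loci}
        shared = sorted(proteins, key=lambda p: order[p.id])[:n_shared]
        if len(shared) < n_shared:
            raise SodfamError("not enough genes for the requested shared subset")
        p_chrom = "chrB1"
        p_loci: list[GeneLocus] = []
        p_prot: list[ProteinRecord] = []
        pairs: list[tuple[str, str]] = []
        pcursor = 5_000
        for p in shared:
            bid = p.id + "_b"
            p_prot.append(ProteinRecord(id=bid, seq=p.seq, source="synthetic:partner"))
            p_loci.append(GeneLocus(bid, p_chrom, pcursor, pcursor + gene_len, "+"))
            pairs.append((p.id, bid))
            pcursor += spacing_bp
            if rng.random() < 0.4:  # sprinkle partner-private decoys
                d = new_decoy()
                p_prot.append(d)
                p_loci.append(GeneLocus(d.id, p_chrom, pcursor, pcursor + gene_len, "+"))
                pcursor += spacing_bp
        out.partner_loci = assign_ranks(p_loci)
        out.partner_proteins = p_prot
        out.partner_genome = {p_chrom: _random_dna(rng, pcursor + 10_000)}
        out.homolog_pairs = pairs
    return out


def plant_promoter_sites(
    genome: dict[str, str],
    loci: list[GeneLocus],
    site_seq: str,
    gene_ids: list[str],
    promoter_len: int = 2000,
    offset: int = 500,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Overwrite part of each listed gene's promoter with ``site_seq`` so
    that the site starts at promoter-local position
    ``promoter_len - offset - len(site_seq)`` (i.e. ``offset`` bases
    upstream of the gene's 5' end), strand-corrected.  Returns the edited
    genome and a truth table of planted local coordinates."""
    from .motif_scan import revcomp

    by_id = {g.gene_id: g for g in loci}
    genome = dict(genome)
    rows = []
    local_start = promoter_len - offset - len(site_seq)
    if local_start < 0:
        raise SodfamError("plant_promoter_sites: offset + site length exceed the promoter")
    for gid in gene_ids:
        g = by_id[gid]
        chrom_seq = genome[g.chrom]
        if g.strand == "+":
            abs_start = g.start - offset - len(site_seq)
            planted = site_seq
        else:
            abs_start = g.end + offset
            planted = revcomp(site_seq)
        if abs_start < 0 or abs_start + len(site_seq) > len(chrom_seq):
            raise SodfamError(f"plant_promoter_sites: site for {gid} falls off the contig")
        genome[g.chrom] = (
            chrom_seq[:abs_start] + planted + chrom_seq[abs_start + len(site_seq) :]
        )
        rows.append(
            {
                "entity_id": gid,
                "site_local_start": local_start,
                "site_local_end": local_start + len(site_seq),
            }
        )
    return genome, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# count matrices


def make_counts(
    genes: list[str],
    conditions: list[str],
    n_rep: int = 3,
    planted_fold: dict[str, dict[str, float]] | None = None,
    dispersion: float = 0.04,
    seed: int = 0,
    baseline_mean: float = 200.0,
    gene_length_bp: pd.Series | None = None,
    libsize_sigma: float = 0.15,
) -> tuple[pd.DataFrame, pd.Series, pd.Series, pd.DataFrame]:
    """Negative-binomial gene x sample counts with planted per-condition
    fold effects.

    Per-gene baselines are log-uniform around ``baseline_mean``; per-sample
    library factors are log-normal(0, ``libsize_sigma``); counts for gene g
    in sample s are NB with mean baseline_g * fold_{g,cond(s)} * factor_s
    and the stated dispersion (variance mu + dispersion * mu^2).

    Returns (counts, design, gene lengths, truth).
    """
    if n_rep < 2:
        raise SodfamError("make_counts: n_rep must be >= 2")
    if dispersion < 0:
        raise SodfamError("make_counts: dispersion must be >= 0")
    planted_fold = planted_fold or {}
    rng = np.random.default_rng(seed)
    samples = [f"{c}_r{r+1}" for c in conditions for r in range(n_rep)]
    design = pd.Series([c for c in conditions for _ in range(n_rep)], index=samples)
    baselines = baseline_mean * np.exp(rng.uniform(-1.0, 1.0, size=len(genes)))
    factors = np.exp(rng.normal(0.0, libsize_sigma, size=len(samples)))
    if gene_length_bp is None:
        gene_length_bp = pd.Series(rng.integers(500, 3000, size=len(genes)), index=genes)
    counts = np.zeros((len(genes), len(samples)), dtype=int)
    for gi, gene in enumerate(genes):
        folds = planted_fold.get(gene, {})
        for si, sample in enumerate(samples):
            mu = baselines[gi] * folds.get(design.iloc[si], 1.0) * factors[si]
            if dispersion == 0:
                counts[gi, si] = rng.poisson(mu)
            else:
                r = 1.0 / dispersion
                p = r / (r + mu)
                counts[gi, si] = rng.negative_binomial(r, p)
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    rows = []
    for gene in genes:
        folds = planted_fold.get(gene, {})
        effect = ";".join(f"{c}={f}" for c, f in sorted(folds.items())) or None
        rows.append(_truth_row(gene, effect=effect, seed=seed))
    return counts_df, design, gene_length_bp, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bundles on disk


def write_bundle(
    outdir: str | Path,
    seed: int = 0,
    n_per_group: int = 2,
    arrays: list[ArraySpec] | None = None,
    decoys: int = 6,
    conditions: tuple[str, ...] = ("control", "challenge_6h", "challenge_24h"),
    n_rep: int = 3,
) -> dict[str, Path]:
    """Generate a coherent study bundle on disk: proteins + gene models +
    genome + counts/design/lengths + truth tables.  All downstream stages
    can run from these files alone."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    family, family_truth = make_protein_family(
        n_per_group=n_per_group, background_mut_rate=0.05, seed=seed
    )
    # non-array genes are dispersed beyond the tandem window so the only
    # tandem arrays in the bundle are the planted ones
    syn = make_genome(
        arrays=arrays, decoys=decoys, seed=seed + 1, extra_records=family,
        spacing_bp=110_000,
    )
    # correct the truth group labels for the extras
    group_by_id = dict(zip(family_truth["entity_id"], family_truth["planted_group"]))
    syn.truth["planted_group"] = [
        group_by_id.get(e, g) for e, g in zip(syn.truth["entity_id"], syn.truth["planted_group"])
    ]
    genes = [g.gene_id for g in syn.loci]
    up_genes = [r.id for r in family if r.id.startswith("cuzn_active")]
    planted = {g: {conditions[-1]: 4.0} for g in up_genes}
    counts, design, lengths, counts_truth = make_counts(
        genes, list(conditions), n_rep=n_rep, planted_fold=planted, seed=seed + 2
    )
    paths = {
        "proteins": outdir / "proteins.fasta",
        "genome": outdir / "genome.fasta",
        "gff3": outdir / "genes.gff3",
        "counts": outdir / "counts.tsv",
        "design": outdir / "design.tsv",
        "lengths": outdir / "gene_lengths.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_counts": outdir / "truth_counts.tsv",
    }
    write_fasta(syn.proteins, paths["proteins"])
    write_nucleotide_fasta(syn.genome, paths["genome"])
    write_gff3(syn.loci, paths["gff3"])
    counts.rename_axis("gene_id").to_csv(paths["counts"], sep="\t")
    design.rename("condition").rename_axis("sample").to_csv(paths["design"], sep="\t")
    lengths.rename("length_bp").rename_axis("gene_id").to_csv(paths["lengths"], sep="\t")
    syn.truth.to_csv(paths["truth_genes"], sep="\t", index=False)
    counts_truth.to_csv(paths["truth_counts"], sep="\t", index=False)
    return paths
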