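"""Duplicated gene pairs, tandem arrays and collinear blocks from gene
coordinates plus pairwise protein alignment.

A pair of genes is a duplicate when the aligned part covers more than the
configured fraction of the longer protein AND the aligned columns exceed
the configured identity (the 70/70 rule by default).  "Similarity" is
implemented as column identity over aligned columns with gaps excluded; a
switch selects the BLOSUM62-positive fraction instead.

Tandem arrays are connected components of duplicate pairs on one
chromosome whose members are separated by at most the configured number of
intervening genes and lie within the configured physical window (both
clauses must hold).  Collinear blocks are maximal strictly monotone chains
of cross-genome homolog anchors, found by longest-increasing-subsequence
in both orientations and reported greedily without anchor reuse.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .align import global_align
from .io_formats import GeneLocus, ProteinRecord, RunConfig, SodfamError


@dataclass(frozen=True)
class DupPair:
    gene_a: str
    gene_b: str
    coverage: float
    identity: float
    is_duplicate: bool

    def __post_init__(self) -> None:
        if not (0 <= self.coverage <= 1 and 0 <= self.identity <= 1):
            raise SodfamError("coverage and identity must lie in [0, 1]")


@dataclass(frozen=True)
class TandemArray:
    chrom: str
    member_gene_ids: tuple[str, ...]
    span_bp: int


@dataclass(frozen=True)
class CollinearBlock:
    chrom_a: str
    chrom_b: str
    anchor_pairs: tuple[tuple[str, str], ...]
    orientation: str  # "same" or "inverted"


def duplicate_pairs(
    proteins: list[ProteinRecord],
    loci: list[GeneLocus],
    config: RunConfig | None = None,
    criterion: str = "identity",
) -> list[DupPair]:
    """Evaluate all unordered protein pairs for the coverage/identity
    duplication rule.  Every protein must map to a locus by id."""
    config = config or RunConfig()
    if criterion not in ("identity", "positive"):
        raise SodfamError("criterion must be 'identity' or 'positive'")
    locus_ids = {g.gene_id for g in loci}
    missing = sorted({p.id for p in proteins} - locus_ids)
    if missing:
        raise SodfamError(f"proteins without a locus: {', '.join(missing)}")
    pairs = []
    for pa, pb in itertools.combinations(sorted(proteins, key=lambda p: p.id), 2):
        res = global_align(pa.seq, pb.seq)
        coverage = res.n_cols / max(len(pa.seq), len(pb.seq))
        similarity = res.identity if criterion == "identity" else res.positive_fraction
        pairs.append(
            DupPair(
                gene_a=pa.id,
                gene_b=pb.id,
                coverage=coverage,
                identity=similarity,
                is_duplicate=coverage > config.dup_coverage and similarity > config.dup_identity,
            )
        )
    return pairs


def tandem_arrays(
    dup_pairs: list[DupPair],
    loci: list[GeneLocus],
    config: RunConfig | None = None,
) -> list[TandemArray]:
    """Cluster qualifying duplicate pairs into tandem arrays.

    A pair qualifies when both genes sit on one chromosome, at most
    ``tandem_max_intervening`` genes lie between them (rank difference),
    and the two genes span at most ``tandem_window_bp``.  Arrays are the
    connected components of the qualifying-pair graph, with members
    ordered by rank.
    """
    config = config or RunConfig()
    by_id = {g.gene_id: g for g in loci}
    if any(g.rank is None for g in loci):
        raise SodfamError("tandem_arrays: loci must be ranked (use assign_ranks/read_gff3)")
    graph = nx.Graph()
    for p in dup_pairs:
        if not p.is_duplicate:
            continue
        ga, gb = by_id.get(p.gene_a), by_id.get(p.gene_b)
        if ga is None or gb is None or ga.chrom != gb.chrom:
            continue
        intervening = abs(ga.rank - gb.rank) - 1
        span = max(ga.end, gb.end) - min(ga.start, gb.start)
        if intervening <= config.tandem_max_intervening and span <= config.tandem_window_bp:
            graph.add_edge(p.gene_a, p.gene_b)
    arrays = []
    for comp in nx.connected_components(graph):
        members = sorted(comp, key=lambda gid: by_id[gid].rank)
        span = max(by_id[g].end for g in members) - min(by_id[g].start for g in members)
        arrays.append(
            TandemArray(
                chrom=by_id[members[0]].chrom,
                member_gene_ids=tuple(members),
                span_bp=span,
            )
        )
    arrays.sort(key=lambda a: (a.chrom, a.member_gene_ids))
    return arrays


def _longest_monotone_chain(anchors: list[tuple[int, int, int]], direction: int):
    """Longest chain strictly increasing in rank_a and strictly
    increasing (direction=+1) or decreasing (-1) in rank_b.

    ``anchors`` are (rank_a, rank_b, index) triples.  O(n^2) DP; ties are
    broken toward the lexicographically smallest index chain for
    determinism.
    """
    n = len(anchors)
    if n == 0:
        return []
    order = sorted(range(n), key=lambda i: (anchors[i][0], anchors[i][1]))
    best_len = [1] * n
    prev = [-1] * n
    for oi in range(n):
        i = order[oi]
        for oj in range(oi):
            j = order[oj]
            if anchors[j][0] < anchors[i][0] and (
                (direction > 0 and anchors[j][1] < anchors[i][1])
                or (direction < 0 and anchors[j][1] > anchors[i][1])
            ):
                if best_len[j] + 1 > best_len[i]:
                    best_len[i] = best_len[j] + 1
                    prev[i] = j
    end = max(range(n), key=lambda i: (best_len[i], -anchors[i][0]))
    chain = []
    while end != -1:
        chain.append(end)
        end = prev[end]
    return chain[::-1]


def collinear_blocks(
    homolog_pairs: list[tuple[str, str]],
    loci_a: list[GeneLocus],
    loci_b: list[GeneLocus],
    min_block: int = 3,
) -> list[CollinearBlock]:
    """Find collinear blocks between two gene sets from homologous anchor
    pairs.  For each chromosome pair, the longest strictly monotone chains
    (both orientations) are reported greedily, longest first, without
    anchor reuse, down to ``min_block`` anchors."""
    a_by_id = {g.gene_id: g for g in loci_a}
    b_by_id = {g.gene_id: g for g in loci_b}
    groups: dict[tuple[str, str], list[tuple[int, int, tuple[str, str]]]] = {}
    for ga, gb in homolog_pairs:
        la, lb = a_by_id.get(ga), b_by_id.get(gb)
        if la is None or lb is None:
            raise SodfamError(f"collinear_blocks: anchor ({ga}, {gb}) missing from loci")
        groups.setdefault((la.chrom, lb.chrom), []).append((la.rank, lb.rank, (ga, gb)))
    blocks: list[CollinearBlock] = []
    for (ca, cb), anchors in sorted(groups.items()):
        remaining = sorted(anchors)
        while len(remaining) >= min_block:
            triples = [(ra, rb, i) for i, (ra, rb, _) in enumerate(remaining)]
            up = _longest_monotone_chain(triples, +1)
            down = _longest_monotone_chain(triples, -1)
            # prefer the longer chain; tie -> same orientation
            chain, orientation = (
                (up, "same") if len(up) >= len(down) else (down, "inverted")
            )
            if len(chain) < min_block:
                break
            pair_chain = tuple(remaining[i][2] for i in chain)
            blocks.append(
                CollinearBlock(chrom_a=ca, chrom_b=cb, anchor_pairs=pair_chain,
                               orientation=orientation)
            )
            used = set(chain)
            remaining = [t for i, t in enumerate(remaining) if i not in used]
    return blocks


def pairs_table(pairs: list[DupPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "coverage": round(p.coverage, 4),
                "identity": round(p.identity, 4),
                "is_duplicate": p.is_duplicate,
            }
            for p in pairs
        ],
        columns=["gene_a", "gene_b", "coverage", "identity", "is_duplicate"],
    )


def arrays_table(arrays: list[TandemArray]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": a.chrom,
                "members": ",".join(a.member_gene_ids),
                "n_members": len(a.member_gene_ids),
                "span_bp": a.span_bp,
            }
            for a in arrays
        ],
        columns=["chrom", "members", "n_members", "span_bp"],
    )


def blocks_table(blocks: list[CollinearBlock], loci_a=None, loci_b=None) -> pd.DataFrame:
    """Block summary; with loci given, adds ribbon-plot link coordinates
    (chrom_a, start_a, end_a, chrom_b, start_b, end_b)."""
    a_by_id = {g.gene_id: g for g in loci_a} if loci_a else {}
    b_by_id = {g.gene_id: g for g in loci_b} if loci_b else {}
    rows = []
    for blk in blocks:
        row = {
            "chrom_a": blk.chrom_a,
            "chrom_b": blk.chrom_b,
            "n_anchors": len(blk.anchor_pairs),
            "orientation": blk.orientation,
            "anchors": ";".join(f"{a}|{b}" for a, b in blk.anchor_pairs),
        }
        if a_by_id and b_by_id:
            genes_a = [a_by_id[a] for a, _ in blk.anchor_pairs]
            genes_b = [b_by_id[b] for _, b in blk.anchor_pairs]
            row.update(
                start_a=min(g.start for g in genes_a),
                end_a=max(g.end for g in genes_a),
                start_b=min(g.start for g in genes_b),
                end_b=max(g.end for g in genes_b),
            )
        rows.append(row)
    return pd.DataFrame(rows)
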