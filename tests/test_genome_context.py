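import numpy as np
import pytest

from sodfam.align import global_align
from sodfam.genome_context import (
    collinear_blocks,
    duplicate_pairs,
    tandem_arrays,
)
from sodfam.io_formats import GeneLocus, ProteinRecord, RunConfig, SodfamError, assign_ranks
from sodfam.references import HUMAN_SOD1
from sodfam.synthetic_data import ArraySpec, make_genome, _mutate

from .oracles import greedy_block_count_oracle, longest_monotone_chain_oracle


def _loci(ids, chrom="chr1", spacing=10_000, start=1000, gene_len=1500):
    out = [
        GeneLocus(g, chrom, start + i * spacing, start + i * spacing + gene_len, "+")
        for i, g in enumerate(ids)
    ]
    return assign_ranks(out)


def test_identical_paralogs_are_duplicates():
    prot = [ProteinRecord("a", HUMAN_SOD1), ProteinRecord("b", HUMAN_SOD1)]
    (pair,) = duplicate_pairs(prot, _loci(["a", "b"]))
    assert pair.coverage == 1.0 and pair.identity == 1.0 and pair.is_duplicate


def test_divergent_pair_excluded_by_identity():
    """An engineered divergent pair: measure identity post hoc, confirm it
    falls below the 70% threshold and that the pair is excluded."""
    rng = np.random.default_rng(17)
    other = _mutate(HUMAN_SOD1, 0.45, rng)
    prot = [ProteinRecord("a", HUMAN_SOD1), ProteinRecord("b", other)]
    (pair,) = duplicate_pairs(prot, _loci(["a", "b"]))
    measured = global_align(HUMAN_SOD1, other).identity
    assert measured < 0.70
    assert pair.identity == pytest.approx(measured)
    assert not pair.is_duplicate


def test_fragment_excluded_by_coverage():
    full = HUMAN_SOD1 + HUMAN_SOD1 + HUMAN_SOD1[:92]  # 400 aa
    frag = full[:150]
    prot = [ProteinRecord("full", full), ProteinRecord("frag", frag)]
    (pair,) = duplicate_pairs(prot, _loci(["full", "frag"]))
    assert pair.identity == 1.0
    assert pair.coverage == pytest.approx(150 / 400)
    assert not pair.is_duplicate


def test_duplicate_pairs_symmetric():
    prot = [ProteinRecord("a", HUMAN_SOD1), ProteinRecord("b", HUMAN_SOD1)]
    fwd = duplicate_pairs(prot, _loci(["a", "b"]))
    rev = duplicate_pairs(list(reversed(prot)), _loci(["a", "b"]))
    assert [(p.gene_a, p.gene_b, p.is_duplicate) for p in fwd] == [
        (p.gene_a, p.gene_b, p.is_duplicate) for p in rev
    ]


def test_protein_without_locus_errors():
    prot = [ProteinRecord("a", HUMAN_SOD1), ProteinRecord("orphan", HUMAN_SOD1)]
    with pytest.raises(SodfamError, match="orphan"):
        duplicate_pairs(prot, _loci(["a"]))


def test_planted_three_gene_array_recovered():
    syn = make_genome(arrays=[ArraySpec(3, 10_000, 0)], decoys=6, seed=0)
    pairs = duplicate_pairs(syn.proteins, syn.loci)
    (array,) = tandem_arrays(pairs, syn.loci)
    planted = set(syn.truth.loc[syn.truth.planted_array_id == "array_0", "entity_id"])
    assert set(array.member_gene_ids) == planted
    assert array.span_bp <= 100_000


def test_six_intervening_genes_break_the_array():
    """5 intervening genes qualify, 6 do not (boundary of the tandem
    rule)."""
    ok = make_genome(arrays=[ArraySpec(2, 9_500, 5, )], decoys=0, seed=1, gene_len=1200)
    bad = make_genome(arrays=[ArraySpec(2, 11_000, 6)], decoys=0, seed=1, gene_len=1200)
    ok_pairs = duplicate_pairs(ok.proteins, ok.loci)
    bad_pairs = duplicate_pairs(bad.proteins, bad.loci)
    assert len(tandem_arrays(ok_pairs, ok.loci)) == 1
    assert tandem_arrays(bad_pairs, bad.loci) == []


def test_window_rule_breaks_distant_pairs():
    syn = make_genome(arrays=[ArraySpec(2, 120_000, 2)], decoys=0, seed=3)
    pairs = duplicate_pairs(syn.proteins, syn.loci)
    dup = [p for p in pairs if p.is_duplicate]
    assert dup  # the pair is homologous...
    assert tandem_arrays(pairs, syn.loci) == []  # ...but violates the window


def test_collinear_same_order_one_block():
    ids_a = [f"g{i}" for i in range(8)]
    ids_b = [f"h{i}" for i in range(8)]
    blocks = collinear_blocks(
        list(zip(ids_a, ids_b)), _loci(ids_a), _loci(ids_b, chrom="chr2"), min_block=3
    )
    assert len(blocks) == 1
    assert len(blocks[0].anchor_pairs) == 8
    assert blocks[0].orientation == "same"


def test_collinear_reversed_order_is_inverted():
    ids_a = [f"g{i}" for i in range(8)]
    ids_b = [f"h{i}" for i in range(8)]
    blocks = collinear_blocks(
        list(zip(ids_a, reversed(ids_b))),
        _loci(ids_a),
        _loci(ids_b, chrom="chr2"),
        min_block=3,
    )
    assert len(blocks) == 1 and blocks[0].orientation == "inverted"


def test_collinear_shuffled_matches_exhaustive_oracle():
    """Shuffled anchor order (seed 19), min_block 4: block count and sizes
    equal an exhaustive chain-search oracle on n = 12."""
    rng = np.random.default_rng(19)
    n = 12
    perm = rng.permutation(n)
    ids_a = [f"g{i}" for i in range(n)]
    ids_b = [f"h{i}" for i in range(n)]
    pairs = [(ids_a[i], ids_b[perm[i]]) for i in range(n)]
    loci_a, loci_b = _loci(ids_a), _loci(ids_b, chrom="chr2")
    blocks = collinear_blocks(pairs, loci_a, loci_b, min_block=4)
    rank_pairs = [(i + 1, int(perm[i]) + 1) for i in range(n)]
    expected_sizes = greedy_block_count_oracle(rank_pairs, min_block=4)
    assert [len(b.anchor_pairs) for b in blocks] == expected_sizes
    # the first block is a genuinely longest chain
    best_up = longest_monotone_chain_oracle(rank_pairs, +1)
    best_down = longest_monotone_chain_oracle(rank_pairs, -1)
    if blocks:
        assert len(blocks[0].anchor_pairs) == max(best_up, best_down)


def test_collinear_chains_are_maximal():
    """No reported chain can be extended by an unused anchor while keeping
    strict monotonicity on both genomes."""
    rng = np.random.default_rng(23)
    n = 12
    perm = rng.permutation(n)
    ids_a = [f"g{i}" for i in range(n)]
    ids_b = [f"h{i}" for i in range(n)]
    pairs = [(ids_a[i], ids_b[perm[i]]) for i in range(n)]
    loci_a, loci_b = _loci(ids_a), _loci(ids_b, chrom="chr2")
    rank_a = {g.gene_id: g.rank for g in loci_a}
    rank_b = {g.gene_id: g.rank for g in loci_b}
    blocks = collinear_blocks(pairs, loci_a, loci_b, min_block=3)
    used = {p for b in blocks for p in b.anchor_pairs}
    for blk in blocks:
        sign = 1 if blk.orientation == "same" else -1
        chain = [(rank_a[a], sign * rank_b[b]) for a, b in blk.anchor_pairs]
        for anchor in set(pairs) - used:
            ra, rb = rank_a[anchor[0]], sign * rank_b[anchor[1]]
            extended = sorted(chain + [(ra, rb)])
            ok = all(
                x2 > x1 and y2 > y1 for (x1, y1), (x2, y2) in zip(extended, extended[1:])
            )
            assert not ok, f"{blk.orientation} chain extendable by {anchor}"


def test_synthetic_partner_block_of_eight():
    syn = make_genome(
        arrays=[ArraySpec(3, 10_000, 0)], decoys=6, seed=0, collinear_partner=True
    )
    blocks = collinear_blocks(syn.homolog_pairs, syn.loci, syn.partner_loci, min_block=3)
    assert len(blocks) == 1
    assert len(blocks[0].anchor_pairs) == 8
    assert blocks[0].orientation == "same"
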