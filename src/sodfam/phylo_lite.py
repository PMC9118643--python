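"""Distance-based phylogeny with bootstrap support and clade cutting.

This module is a deliberately desk-scale stand-in for heavyweight
maximum-likelihood inference: pairwise Poisson-corrected distances feed
canonical neighbour joining (exact on additive distances), supports come
from column-resampling bootstrap over a multiple alignment, and clades are
cut at a support threshold.  Clade labels from this stand-in are
qualitative groupings, not a numeric reproduction of an ML topology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .align import global_align
from .io_formats import ProteinRecord, SodfamError

#: identity floor guarding the log; caps distances at -ln(floor)
DISTANCE_FLOOR = 1e-4


def protein_distance(a: ProteinRecord | str, b: ProteinRecord | str) -> float:
    """Poisson-corrected distance from global-alignment identity:
    d = -ln(max(identity, floor))."""
    seq_a = a.seq if isinstance(a, ProteinRecord) else a
    seq_b = b.seq if isinstance(b, ProteinRecord) else b
    if seq_a == seq_b:
        return 0.0
    res = global_align(seq_a, seq_b)
    return -math.log(max(res.identity, DISTANCE_FLOOR))


def distance_matrix(records: list[ProteinRecord]) -> DistanceMatrix:
    ids = [r.id for r in records]
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = protein_distance(records[i], records[j])
    return DistanceMatrix(d, ids)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Canonical neighbour joining.  On additive distances the generating
    topology and branch lengths are recovered exactly."""
    if dm.shape[0] < 3:
        raise SodfamError("nj_tree: need at least 3 taxa")
    asymmetry = np.abs(dm.data - dm.data.T).max()
    if asymmetry > 1e-9:
        raise SodfamError("nj_tree: distance matrix is not symmetric")
    return nj(dm)


# ---------------------------------------------------------------------------
# Multiple alignment and bootstrap


def progressive_align(records: list[ProteinRecord]) -> dict[str, str]:
    """Progressive multiple alignment (guide tree + profile merging) via
    biotite; returns id -> gapped sequence.  Deterministic for a fixed
    input."""
    import biotite.sequence as bioseq
    import biotite.sequence.align as bioalign

    seqs = [bioseq.ProteinSequence(r.seq) for r in records]
    matrix = bioalign.SubstitutionMatrix.std_protein_matrix()
    alignment, *_ = bioalign.align_multiple(seqs, matrix, gap_penalty=(-10, -1))
    gapped = alignment.get_gapped_sequences()
    return {r.id: g for r, g in zip(records, gapped)}


def alignment_distance_matrix(aligned: dict[str, str]) -> DistanceMatrix:
    """Poisson-corrected p-distances over the columns of a multiple
    alignment, ignoring columns where either sequence is gapped."""
    ids = list(aligned)
    arrs = {i: np.frombuffer(aligned[i].encode(), dtype="S1") for i in ids}
    lengths = {len(aligned[i]) for i in ids}
    if len(lengths) != 1:
        raise SodfamError("alignment_distance_matrix: unequal alignment lengths")
    n = len(ids)
    d = np.zeros((n, n))
    gap = np.bytes_(b"-")
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrs[ids[i]], arrs[ids[j]]
            valid = (a != gap) & (b != gap)
            nv = int(valid.sum())
            if nv == 0:
                dij = -math.log(DISTANCE_FLOOR)
            else:
                ident = float((a[valid] == b[valid]).mean())
                dij = -math.log(max(ident, DISTANCE_FLOOR))
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(d, ids)


def _bipartitions(tree: TreeNode, taxa: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an (arbitrarily rooted) tree, each
    canonicalised to the smaller side (lexicographic tie-break)."""
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = taxa - side
        if len(side) < 2 or len(other) < 2:
            continue
        if len(side) < len(other) or (
            len(side) == len(other) and sorted(side) < sorted(other)
        ):
            out.add(side)
        else:
            out.add(other)
    return out


def bootstrap_support(
    aligned: dict[str, str],
    n_reps: int = 100,
    seed: int = 0,
) -> TreeNode:
    """NJ tree from the full alignment with internal-node supports (0-100)
    from ``n_reps`` column-resampling replicates.  Supports are stored on
    ``node.support`` and mirrored into internal node names for newick
    export.  Reproducible under a fixed seed and invariant to taxon input
    order (taxa are sorted internally)."""
    if n_reps < 1:
        raise SodfamError("bootstrap_support: n_reps must be >= 1")
    aligned = {k: aligned[k] for k in sorted(aligned)}
    taxa = frozenset(aligned)
    base = nj_tree(alignment_distance_matrix(aligned))
    ncol = len(next(iter(aligned.values())))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    ids = list(aligned)
    mat = np.array([np.frombuffer(aligned[i].encode(), dtype="S1") for i in ids])
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        res = mat[:, cols]
        resampled = {i: res[k].tobytes().decode() for k, i in enumerate(ids)}
        rep_tree = nj_tree(alignment_distance_matrix(resampled))
        for bip in _bipartitions(rep_tree, taxa):
            counts[bip] = counts.get(bip, 0) + 1
    for node in base.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = taxa - side
        if len(side) < 2 or len(other) < 2:
            node.support = None
            continue
        key = side if (
            len(side) < len(other)
            or (len(side) == len(other) and sorted(side) < sorted(other))
        ) else other
        node.support = 100.0 * counts.get(key, 0) / n_reps
        node.name = f"{node.support:.0f}"
    return base


def cut_clades(tree: TreeNode, min_support: float) -> dict[str, int]:
    """Cut a supported tree into clades: maximal subtrees whose subtending
    edge support is at least ``min_support`` become clades; every remaining
    taxon is a singleton clade.  Returns taxon -> clade index."""
    assignment: dict[str, int] = {}
    next_id = [0]

    def claim(leaves) -> None:
        for name in leaves:
            assignment[name] = next_id[0]
        next_id[0] += 1

    def walk(node: TreeNode) -> None:
        for child in node.children:
            if child.is_tip():
                claim([child.name])
            elif getattr(child, "support", None) is not None and child.support >= min_support:
                claim([t.name for t in child.tips()])
            else:
                walk(child)

    walk(tree)
    return assignment


def family_bipartition_support(tree: TreeNode, family_a: set[str]) -> float | None:
    """Support of the bipartition separating ``family_a`` from the rest,
    or None if the base tree does not contain it."""
    taxa = frozenset(t.name for t in tree.tips())
    target = frozenset(family_a)
    other = taxa - target
    canon = target if (
        len(target) < len(other) or (len(target) == len(other) and sorted(target) < sorted(other))
    ) else other
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if side == canon or (taxa - side) == canon:
            return getattr(node, "support", None)
    return None


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")
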