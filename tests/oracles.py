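"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from first principles (quadratic DP,
exhaustive chain search, direct counting) so that the fast implementation
paths are checked against something that shares no code with them.
"""

from __future__ import annotations

import numpy as np


def sw_score_oracle(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Quadratic-space affine-gap Smith-Waterman (Gotoh) best score.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``, matching
    the implementation's convention.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (consuming b)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (consuming a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            diag = H[i - 1, j - 1] + matrix[a[i - 1], b[j - 1]]
            H[i, j] = max(0.0, diag, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


def longest_monotone_chain_oracle(anchors, direction: int) -> int:
    """Length of the longest chain strictly increasing in the first rank
    and strictly monotone (direction +1/-1) in the second, by exhaustive
    depth-first search.  Usable for n <= ~14."""

    def extendable(last, cand):
        la, lb = last
        ca, cb = cand
        return ca > la and (cb > lb if direction > 0 else cb < lb)

    best = 0

    def dfs(last, remaining, length):
        nonlocal best
        best = max(best, length)
        for k, cand in enumerate(remaining):
            if last is None or extendable(last, cand):
                dfs(cand, remaining[k + 1 :], length + 1)

    ordered = sorted(anchors)
    dfs(None, ordered, 0)
    return best


def greedy_block_count_oracle(anchors, min_block: int) -> list[int]:
    """Block sizes from repeated exhaustive longest-chain extraction
    (either orientation, longest wins, ties to the increasing one)."""

    def best_chain(pool, direction):
        bestc: list = []

        def dfs(last, remaining, chain):
            nonlocal bestc
            if len(chain) > len(bestc):
                bestc = list(chain)
            for k, cand in enumerate(remaining):
                la_ok = last is None or (
                    cand[0] > last[0]
                    and (cand[1] > last[1] if direction > 0 else cand[1] < last[1])
                )
                if la_ok:
                    chain.append(cand)
                    dfs(cand, remaining[k + 1 :], chain)
                    chain.pop()

        dfs(None, sorted(pool), [])
        return bestc

    pool = sorted(anchors)
    sizes = []
    while len(pool) >= min_block:
        up = best_chain(pool, +1)
        down = best_chain(pool, -1)
        chain = up if len(up) >= len(down) else down
        if len(chain) < min_block:
            break
        sizes.append(len(chain))
        used = set(chain)
        pool = [p for p in pool if p not in used]
    return sizes


def pi_grid_oracle(seq: str, step: float = 0.001) -> float:
    """Isoelectric point by grid search over pH: the pH minimising the
    absolute Bjellqvist net charge, computed directly from the pKa tables
    (vectorised Henderson-Hasselbalch, independent of the bisection
    path)."""
    from Bio.SeqUtils import IsoelectricPoint as IPmod

    pos_pks = dict(IPmod.positive_pKs)
    neg_pks = dict(IPmod.negative_pKs)
    nterm = IPmod.pKnterminal.get(seq[0], pos_pks["Nterm"])
    cterm = IPmod.pKcterminal.get(seq[-1], neg_pks["Cterm"])
    ph = np.arange(0.0, 14.0 + step, step)

    def pos_term(pk, count):
        return count / (1.0 + 10.0 ** (ph - pk))

    def neg_term(pk, count):
        return count / (1.0 + 10.0 ** (pk - ph))

    charge = pos_term(nterm, 1) - neg_term(cterm, 1)
    for aa, pk in pos_pks.items():
        if aa != "Nterm":
            charge = charge + pos_term(pk, seq.count(aa))
    for aa, pk in neg_pks.items():
        if aa != "Cterm":
            charge = charge - neg_term(pk, seq.count(aa))
    return float(ph[np.abs(charge).argmin()])
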