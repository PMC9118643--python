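"""Expression normalisation (FPKM/TPM), log2 heat values and fold changes,
and responsive-gene calling by one-way ANOVA followed by Duncan's multiple
range test.

The ANOVA/Duncan stage runs on log2(x + 1) abundances by default (the
scale on which family expression heatmaps are drawn; variance-stabilising),
switchable to the raw scale.  Duncan's critical range for a span of p
ordered means uses the studentized-range quantile at the stepwise
protection level 1 - (1 - alpha)^(p-1), with the harmonic mean of group
sizes under unequal replication.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import SodfamError


@dataclass
class ExpressionMatrix:
    """Raw gene x sample counts with gene lengths and a sample -> condition
    design."""

    counts: pd.DataFrame  # genes x samples, non-negative
    gene_length_bp: pd.Series  # per gene, > 0
    sample_condition: pd.Series  # per sample
    library_size: pd.Series | None = None  # per sample; default column sums

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise SodfamError("counts must be non-negative")
        if not self.counts.index.equals(self.gene_length_bp.index):
            self.gene_length_bp = self.gene_length_bp.reindex(self.counts.index)
        if self.gene_length_bp.isna().any() or (self.gene_length_bp <= 0).any():
            raise SodfamError("every gene needs a positive length")
        self.sample_condition = self.sample_condition.reindex(self.counts.columns)
        if self.sample_condition.isna().any():
            raise SodfamError("every sample needs a condition label")
        if self.library_size is None:
            self.library_size = self.counts.sum(axis=0).astype(float)
        else:
            self.library_size = self.library_size.reindex(self.counts.columns).astype(float)
        if (self.library_size <= 0).any():
            bad = list(self.library_size.index[self.library_size <= 0])
            raise SodfamError(f"non-positive library size for samples: {bad}")


def fpkm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Fragments per kilobase of model per million mapped:
    counts * 1e9 / (library_size * gene_length)."""
    scale = 1e9 / (
        matrix.library_size.to_numpy()[None, :] * matrix.gene_length_bp.to_numpy()[:, None]
    )
    return matrix.counts * scale


def tpm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Transcripts per million: length-normalised rates rescaled so every
    sample column sums to 1e6."""
    rate = matrix.counts.div(matrix.gene_length_bp, axis=0)
    colsum = rate.sum(axis=0)
    zero = colsum[colsum == 0]
    if not zero.empty:
        raise SodfamError(f"tpm: all-zero sample column(s): {list(zero.index)}")
    return rate * (1e6 / colsum)


def heat_values(abundance: pd.DataFrame, pseudo: float = 1.0) -> pd.DataFrame:
    """log2(x + pseudo) heatmap values."""
    if (abundance.to_numpy() < 0).any():
        raise SodfamError("heat_values: negative abundances")
    return np.log2(abundance + pseudo)


def fold_change(
    abundance: pd.DataFrame,
    design: pd.Series,
    control: str,
    pseudo: float = 1.0,
) -> pd.DataFrame:
    """Per-gene, per-condition (mean + pseudo) / (control mean + pseudo)
    ratios on the abundance scale."""
    design = design.reindex(abundance.columns)
    if control not in set(design):
        raise SodfamError(f"fold_change: control condition {control!r} not in design")
    means = abundance.T.groupby(design).mean().T
    ctrl = means[control]
    out = (means.add(pseudo)).div(ctrl + pseudo, axis=0)
    return out.drop(columns=[control])


@dataclass(frozen=True)
class ResponseCall:
    gene_id: str
    f_stat: float
    p_value: float
    duncan_groups: dict  # condition -> letter string
    direction: dict  # condition -> "up" | "down" | "none"


def duncan_critical_range(p_span: int, df_error: int, mse: float, n_h: float, alpha: float) -> float:
    """Duncan's least significant range for a span of ``p_span`` ordered
    means: q at protection level 1-(1-alpha)^(p-1) times sqrt(MSE / n_h)."""
    protection = (1.0 - alpha) ** (p_span - 1)
    q = stats.studentized_range.ppf(protection, p_span, df_error)
    return float(q * np.sqrt(mse / n_h))


def _duncan_nonsig(sorted_means: np.ndarray, mse: float, df_error: int, n_h: float, alpha: float):
    """Boolean matrix over sorted (descending) means: True where the pair is
    NOT significantly different under the stepwise protected procedure."""
    k = len(sorted_means)
    nonsig = np.zeros((k, k), dtype=bool)
    np.fill_diagonal(nonsig, True)
    decided = np.zeros((k, k), dtype=bool)
    np.fill_diagonal(decided, True)

    def test(i: int, j: int) -> None:
        # i < j over descending means
        if j <= i or decided[i, j]:
            return
        span = j - i + 1
        rng = duncan_critical_range(span, df_error, mse, n_h, alpha)
        if sorted_means[i] - sorted_means[j] <= rng:
            # shielded: the whole stretch is declared homogeneous
            for a in range(i, j + 1):
                for b in range(a, j + 1):
                    nonsig[a, b] = nonsig[b, a] = True
                    decided[a, b] = decided[b, a] = True
        else:
            decided[i, j] = decided[j, i] = True
            test(i, j - 1)
            test(i + 1, j)

    test(0, k - 1)
    return nonsig


def duncan_letters(
    means: dict[str, float], mse: float, df_error: int, n_h: float, alpha: float
) -> dict[str, str]:
    """Letter display: conditions sharing a letter are not declared
    different.  Letters label the maximal homogeneous stretches of the
    ranked means ('a' = highest mean)."""
    names = sorted(means, key=lambda c: -means[c])
    vals = np.array([means[c] for c in names])
    nonsig = _duncan_nonsig(vals, mse, df_error, n_h, alpha)
    k = len(names)
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and nonsig[i, i : j + 2].all() and nonsig[i : j + 2, j + 1].all():
            j += 1
        intervals.append((i, j))
    maximal = [
        iv for iv in intervals
        if not any(o != iv and o[0] <= iv[0] and iv[1] <= o[1] for o in intervals)
    ]
    # deduplicate, keep order of appearance
    seen = []
    for iv in maximal:
        if iv not in seen:
            seen.append(iv)
    letters = {c: "" for c in names}
    for letter, (i, j) in zip(string.ascii_lowercase, seen):
        for idx in range(i, j + 1):
            letters[names[idx]] += letter
    return letters


def anova_duncan(
    abundance: pd.DataFrame,
    design: pd.Series,
    control: str,
    alpha: float = 0.05,
    log_transform: bool = True,
) -> list[ResponseCall]:
    """Per-gene one-way fixed-effects ANOVA across conditions; genes with
    P < alpha get Duncan's multiple range test and up/down calls against
    the control condition (direction is ``none`` unless the condition and
    the control carry disjoint letter sets)."""
    design = design.reindex(abundance.columns)
    if design.isna().any():
        raise SodfamError("anova_duncan: design does not cover all samples")
    conditions = sorted(design.unique())
    if len(conditions) < 2:
        raise SodfamError("anova_duncan: need at least 2 conditions")
    if control not in conditions:
        raise SodfamError(f"anova_duncan: control {control!r} not among conditions")
    groups = {c: abundance.loc[:, design[design == c].index].to_numpy() for c in conditions}
    sizes = {c: g.shape[1] for c, g in groups.items()}
    if min(sizes.values()) < 2:
        bad = [c for c, n in sizes.items() if n < 2]
        raise SodfamError(f"anova_duncan: condition(s) with fewer than 2 replicates: {bad}")
    if log_transform:
        groups = {c: np.log2(g + 1.0) for c, g in groups.items()}

    f_stat, p_value = stats.f_oneway(*groups.values(), axis=1)
    # groups with zero variance everywhere give nan; treat as no effect
    f_stat = np.nan_to_num(f_stat, nan=0.0)
    p_value = np.where(np.isnan(p_value), 1.0, p_value)

    n_total = sum(sizes.values())
    k = len(conditions)
    df_error = n_total - k
    n_h = k / sum(1.0 / n for n in sizes.values())

    calls = []
    gene_ids = list(abundance.index)
    for gi, gene in enumerate(gene_ids):
        means = {c: float(groups[c][gi].mean()) for c in conditions}
        direction = {c: "none" for c in conditions if c != control}
        letters: dict[str, str] = {}
        if p_value[gi] < alpha:
            sse = sum(((groups[c][gi] - means[c]) ** 2).sum() for c in conditions)
            mse = sse / df_error
            letters = duncan_letters(means, mse, df_error, n_h, alpha)
            for c in conditions:
                if c == control:
                    continue
                if set(letters[c]).isdisjoint(letters[control]):
                    direction[c] = "up" if means[c] > means[control] else "down"
        calls.append(
            ResponseCall(
                gene_id=gene,
                f_stat=float(f_stat[gi]),
                p_value=float(p_value[gi]),
                duncan_groups=letters,
                direction=direction,
            )
        )
    return calls


def calls_table(calls: list[ResponseCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {"gene_id": c.gene_id, "f_stat": round(c.f_stat, 4), "p_value": c.p_value}
        row["letters"] = ";".join(f"{k}={v}" for k, v in sorted(c.duncan_groups.items()))
        row["direction"] = ";".join(f"{k}={v}" for k, v in sorted(c.direction.items()))
        rows.append(row)
    return pd.DataFrame(rows, columns=["gene_id", "f_stat", "p_value", "letters", "direction"])


def load_expression(counts_tsv, design_tsv, lengths_tsv) -> ExpressionMatrix:
    """Assemble an :class:`ExpressionMatrix` from a genes x samples count
    TSV, a (sample, condition) design TSV and a (gene_id, length_bp) TSV."""
    counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
    design = pd.read_csv(design_tsv, sep="\t", index_col=0).iloc[:, 0]
    lengths = pd.read_csv(lengths_tsv, sep="\t", index_col=0).iloc[:, 0]
    return ExpressionMatrix(
        counts=counts, gene_length_bp=lengths, sample_condition=design
    )
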