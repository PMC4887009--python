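"""geNorm expression-stability analysis.

The method rests on the principle that the expression ratio of two ideal
reference genes is identical in all samples.  On the log2 scale a ratio is
a difference, so the pairwise variation of two genes is the sample SD of
the per-sample difference of their log2 quantities.  A gene's stability
measure M is the mean of its pairwise variations with every other
candidate; lower M = more stable.  Candidates are ranked by stepwise
exclusion of the highest-M gene until two remain (those two are tied:
the method cannot separate them).

To decide how many reference genes a normalization factor (NF — the
arithmetic mean of the selected genes' log2 quantities, i.e. the log of
the geometric mean of their relative quantities) needs, the pairwise
variation V_n/n+1 between sequential factors NF_n and NF_{n+1} is
computed; a V below the conventional cutoff 0.15 means the (n+1)-th gene
adds nothing of consequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .data_model import StabilityReport, TraceStep

__all__ = [
    "pairwise_sd",
    "m_value",
    "m_values",
    "stepwise_rank",
    "normalization_factor",
    "pairwise_variation_series",
    "OptimalSet",
    "select_optimal_set",
    "V_CUTOFF",
]

#: Conventional cutoff on V_n/n+1 below which an extra gene is unnecessary.
V_CUTOFF = 0.15


def _check_matrix(m: pd.DataFrame, min_genes: int = 2) -> None:
    if m.isna().any().any():
        raise ValueError("stability input must be complete (no missing values)")
    if m.shape[0] < min_genes:
        raise ValueError(f"need at least {min_genes} genes, got {m.shape[0]}")
    if m.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if m.index.has_duplicates:
        raise ValueError("duplicate gene ids")


def pairwise_sd(m: pd.DataFrame, g1: str, g2: str) -> float:
    """Sample SD (n-1 denominator) over samples of the log2 ratio g1/g2."""
    _check_matrix(m)
    if g1 == g2:
        raise ValueError("pairwise variation needs two distinct genes")
    diff = m.loc[g1].to_numpy() - m.loc[g2].to_numpy()
    return float(np.std(diff, ddof=1))


def m_values(m: pd.DataFrame) -> pd.Series:
    """M for every gene: mean pairwise SD with all other candidates."""
    _check_matrix(m)
    genes = list(m.index)
    g = len(genes)
    sds = pd.DataFrame(0.0, index=genes, columns=genes)
    for a, b in combinations(genes, 2):
        s = pairwise_sd(m, a, b)
        sds.at[a, b] = s
        sds.at[b, a] = s
    return sds.sum(axis=1) / (g - 1)


def m_value(m: pd.DataFrame, gene: str) -> float:
    """Stability measure M of one gene (lower = more stable)."""
    _check_matrix(m)
    if gene not in m.index:
        raise KeyError(gene)
    others = [g for g in m.index if g != gene]
    return float(np.mean([pairwise_sd(m, gene, k) for k in others]))


def stepwise_rank(m: pd.DataFrame) -> StabilityReport:
    """Rank genes by stepwise exclusion of the least stable candidate.

    At each step M is recomputed on the remaining genes and the highest-M
    gene is removed (ties broken by removing the alphabetically last gene)
    until two are left; those two share the top ranks, alphabetically
    ordered.  The trace records, per step, the remaining set, the mean M
    over it, and the removed gene with its M.  The report also carries the
    V_n/n+1 series and the M each gene had when it was eliminated (for the
    final pair: their mutual pairwise SD).
    """
    _check_matrix(m)
    if m.shape[0] == 2:
        pair = sorted(m.index)
        tied = pairwise_sd(m, pair[0], pair[1])
        trace = [TraceStep(tuple(pair), tied, None, None)]
        return StabilityReport(
            method="genorm",
            per_gene={pair[0]: tied, pair[1]: tied},
            ranking=pair,
            trace=trace,
        )

    remaining = m.copy()
    removal_order: list[str] = []
    per_gene: dict[str, float] = {}
    trace: list[TraceStep] = []
    while remaining.shape[0] > 2:
        mv = m_values(remaining)
        worst_m = mv.max()
        worst = max(mv.index[mv == worst_m])  # alphabetically last among ties
        trace.append(
            TraceStep(tuple(sorted(remaining.index)), float(mv.mean()), worst, float(worst_m))
        )
        per_gene[worst] = float(worst_m)
        removal_order.append(worst)
        remaining = remaining.drop(index=worst)

    pair = sorted(remaining.index)
    tied = pairwise_sd(remaining, pair[0], pair[1])
    trace.append(TraceStep(tuple(pair), tied, None, None))
    per_gene[pair[0]] = tied
    per_gene[pair[1]] = tied

    ranking = pair + removal_order[::-1]
    report = StabilityReport(
        method="genorm", per_gene=per_gene, ranking=ranking, trace=trace
    )
    report.pairwise_variation = pairwise_variation_series(report, m)
    return report


def normalization_factor(genes: list[str], m: pd.DataFrame) -> pd.Series:
    """Per-sample NF: arithmetic mean of the listed genes' log2 quantities."""
    if not genes:
        raise ValueError("normalization factor needs at least one gene")
    missing = set(genes) - set(m.index)
    if missing:
        raise KeyError(f"genes absent from matrix: {sorted(missing)}")
    return m.loc[list(genes)].mean(axis=0)


def pairwise_variation_series(
    report: StabilityReport, m: pd.DataFrame
) -> list[tuple[int, float]]:
    """V_n/n+1 for n = 2 .. n_genes-1, following the report's ranking.

    V_n/n+1 is the sample SD over samples of NF_{n+1} - NF_n, where NF_k
    uses the k most stable genes.
    """
    _check_matrix(m, min_genes=3)
    ranking = report.ranking
    series: list[tuple[int, float]] = []
    for n in range(2, len(ranking)):
        nf_n = normalization_factor(ranking[:n], m)
        nf_n1 = normalization_factor(ranking[: n + 1], m)
        v = float(np.std((nf_n1 - nf_n).to_numpy(), ddof=1))
        series.append((n, v))
    return series


@dataclass
class OptimalSet:
    """Outcome of the V-cutoff set-size decision."""

    genes: list[str]
    n: int
    v: float | None  # the decisive V_n/n+1 (None when none fell below cutoff)
    cutoff: float
    all_above_cutoff: bool = False  # warning flag: no V under the cutoff


def select_optimal_set(
    series: list[tuple[int, float]],
    ranking: list[str],
    cutoff: float = V_CUTOFF,
    min_genes: int = 2,
) -> OptimalSet:
    """Choose the number of reference genes from the V series.

    Returns the smallest n >= ``min_genes`` with V_n/n+1 < ``cutoff`` —
    adding gene n+1 past that point has no significant effect on the
    normalization factor.  If no V falls below the cutoff, all genes are
    returned with a warning flag.  ``min_genes`` defaults to 2; pipelines
    aimed at a final reference panel conventionally require at least 3
    reference genes and pass ``min_genes=3``.
    """
    if not series:
        raise ValueError("empty pairwise-variation series")
    for n, v in series:
        if n >= min_genes and v < cutoff:
            return OptimalSet(genes=list(ranking[:n]), n=n, v=v, cutoff=cutoff)
    return OptimalSet(
        genes=list(ranking), n=len(ranking), v=None, cutoff=cutoff, all_above_cutoff=True
    )
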