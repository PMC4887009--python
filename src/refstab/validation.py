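"""Post-selection validation of a reference-gene set.

Once a reference panel is fixed, its suitability is checked on target
genes known to respond to hypoxia: normalized qPCR expression should
agree with the array platform (Spearman), correlate negatively with the
imaging hypoxia covariate A_Brix (low A_Brix = more hypoxic tumor,
hypoxia-induced genes up), split the cohort into high/low expression
tertile groups for outcome analysis, and classify repeated biopsies of
the same tumor consistently.

The survival comparison itself (cumulative incidence under competing
risks, Gray's test, Cox PH) is routine statistics and is only exported as
a grouped table for standard survival routines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CorrelationResult, ExpressionMatrix, NormalizedExpression, SampleAnnotations

__all__ = [
    "cross_platform_correlation",
    "hypoxia_association",
    "tertile_split",
    "heterogeneity_concordance",
    "ConcordanceResult",
    "export_survival_table",
]

#: Percentile defining the "high expression" tertile group.
TERTILE_PERCENTILE = 67.0


def _spearman(gene: str, x: pd.Series, y: pd.Series, min_n: int = 5) -> CorrelationResult:
    shared = x.dropna().index.intersection(y.dropna().index)
    if len(shared) < min_n:
        raise ValueError(f"gene {gene!r}: only {len(shared)} shared samples (< {min_n})")
    xv = x.loc[shared].to_numpy(dtype=float)
    yv = y.loc[shared].to_numpy(dtype=float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError(f"gene {gene!r}: constant variable, correlation undefined")
    res = stats.spearmanr(xv, yv)
    return CorrelationResult(gene=gene, rho=float(res.statistic), p_value=float(res.pvalue), n=len(shared))


def cross_platform_correlation(
    ndcq: NormalizedExpression, array: ExpressionMatrix, genes: list[str]
) -> list[CorrelationResult]:
    """Spearman correlation of -dCq against log2 array expression per gene
    over the samples both platforms measured."""
    results = []
    for gene in genes:
        if gene not in ndcq.values.index:
            raise KeyError(f"gene {gene!r} absent from normalized expression")
        if gene not in array.values.index:
            raise KeyError(f"gene {gene!r} absent from array matrix")
        results.append(_spearman(gene, ndcq.values.loc[gene], array.values.loc[gene]))
    return results


def hypoxia_association(
    ndcq: NormalizedExpression, covariate: pd.Series, genes: list[str]
) -> list[CorrelationResult]:
    """Spearman correlation of -dCq against the hypoxia covariate.

    Negative rho means higher expression in tumors with lower A_Brix
    (i.e. more hypoxic) — the signature expected of hypoxia-induced
    target genes.
    """
    results = []
    for gene in genes:
        if gene not in ndcq.values.index:
            raise KeyError(f"gene {gene!r} absent from normalized expression")
        results.append(_spearman(gene, ndcq.values.loc[gene], covariate))
    return results


def tertile_split(values: pd.Series, cut: float | None = None) -> pd.Series:
    """Label each sample 'high' (value >= cut) or 'low'.

    Without an explicit cut the 67th percentile of the values (linear
    interpolation between order statistics) is used, so roughly the top
    third of the cohort is 'high'.  Values exactly at the cut are 'high';
    an all-equal input is therefore entirely 'high'.
    """
    vals = values.dropna()
    if cut is None:
        if len(vals) < 3:
            raise ValueError("need >= 3 samples to place a tertile cut")
        cut = float(np.percentile(vals.to_numpy(), TERTILE_PERCENTILE))
    labels = pd.Series(
        np.where(vals >= cut, "high", "low"), index=vals.index, dtype=object
    )
    return labels.reindex(values.index)


@dataclass
class ConcordanceResult:
    """Within-tumor classification agreement across repeated biopsies."""

    per_tumor: pd.Series  # bool per multi-biopsy tumor
    fraction_concordant: float
    cut: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_concordant <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")


def heterogeneity_concordance(
    values: pd.Series, tumor_ids: pd.Series, cut: float
) -> ConcordanceResult:
    """Classify biopsies at the cut and ask, per tumor with >= 2 biopsies,
    whether all its biopsies land on the same side."""
    labels = tertile_split(values, cut=cut)
    frame = pd.DataFrame({"label": labels, "tumor": tumor_ids.reindex(labels.index)}).dropna()
    counts = frame.groupby("tumor")["label"].nunique()
    sizes = frame.groupby("tumor").size()
    multi = sizes.index[sizes >= 2]
    if len(multi) == 0:
        raise ValueError("no tumor has >= 2 biopsies")
    per_tumor = (counts.loc[multi] == 1).rename("concordant")
    return ConcordanceResult(
        per_tumor=per_tumor,
        fraction_concordant=float(per_tumor.mean()),
        cut=cut,
    )


def export_survival_table(
    labels: pd.Series, annotations: SampleAnnotations
) -> pd.DataFrame:
    """Grouped (sample, group, time, event) table for external survival
    routines (cumulative incidence with competing risks, Gray's test)."""
    surv = annotations.survival
    out = pd.DataFrame(
        {
            "sample": labels.index,
            "group": labels.to_numpy(),
            "time_months": surv.reindex(labels.index)["time_months"].to_numpy(),
            "event": surv.reindex(labels.index)["event"].to_numpy(),
        }
    )
    return out.dropna(subset=["group", "time_months", "event"]).reset_index(drop=True)
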