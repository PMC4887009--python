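"""Technical-replicate collapsing, QC exclusion, and comparative-dCq
normalization.

qPCR samples are run in duplicate; the mean quantification cycle per
(sample, gene) is used downstream.  Pairs whose mean Cq exceeds 37 (too
close to the detection limit) or whose replicate SD exceeds 0.4 cycles
(poor technical precision) are flagged and excluded, not errored: QC
failure is an observation, not a bug.

The comparative-Cq method normalizes a target gene against the arithmetic
mean Cq of the reference genes:

    dCq_gene = Cq_gene - mean(Cq_ref1, ..., Cq_refk)

and -dCq is reported as the relative expression value (log2-quantity
scale, higher = more abundant).  This assumes an amplification efficiency
of 2 (one cycle per doubling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CqTable, NormalizedExpression

__all__ = [
    "CollapsedCq",
    "collapse_replicates",
    "delta_cq",
    "cq_to_log_quantity",
    "log_quantity_matrix",
]

logger = logging.getLogger(__name__)

EXCLUSION_REASONS = ("none", "high_cq", "high_sd", "all_missing")


@dataclass
class CollapsedCq:
    """Replicate-collapsed Cq values with QC flags.

    ``data`` is indexed by (sample, gene) with columns ``mean_cq``,
    ``replicate_sd`` (NaN when fewer than 2 usable replicates),
    ``n_replicates``, ``excluded`` and ``exclusion_reason``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        bad = set(self.data["exclusion_reason"]) - set(EXCLUSION_REASONS)
        if bad:
            raise ValueError(f"unknown exclusion reasons: {sorted(bad)}")
        if not (self.data["excluded"] == (self.data["exclusion_reason"] != "none")).all():
            raise ValueError("excluded flag inconsistent with exclusion_reason")

    @property
    def retained(self) -> pd.DataFrame:
        return self.data.loc[~self.data["excluded"]]

    @property
    def genes(self) -> list[str]:
        return sorted(self.data.index.get_level_values("gene").unique())

    @property
    def samples(self) -> list[str]:
        return sorted(self.data.index.get_level_values("sample").unique())


def collapse_replicates(
    table: CqTable, max_mean_cq: float = 37.0, max_sd: float = 0.4
) -> CollapsedCq:
    """Average technical replicates per (sample, gene) and apply QC.

    Exclusion rules (strict inequalities, thresholds in cycles):
    mean Cq > ``max_mean_cq`` -> ``high_cq``; replicate SD (n-1
    denominator) > ``max_sd`` -> ``high_sd``; every replicate
    undetermined -> ``all_missing``.
    """
    if len(table) == 0:
        raise ValueError("empty Cq table")
    grouped = table.data.groupby(["sample", "gene"])["cq"]
    mean_cq = grouped.mean()  # skips NaN replicates
    n_rep = grouped.count()
    sd = grouped.std(ddof=1)  # NaN when < 2 non-missing replicates

    reason = pd.Series("none", index=mean_cq.index, dtype=object)
    reason[sd > max_sd] = "high_sd"
    reason[mean_cq > max_mean_cq] = "high_cq"  # high_cq takes precedence
    reason[n_rep == 0] = "all_missing"

    frame = pd.DataFrame(
        {
            "mean_cq": mean_cq,
            "replicate_sd": sd,
            "n_replicates": n_rep,
            "excluded": reason != "none",
            "exclusion_reason": reason,
        }
    )
    frame.index.names = ["sample", "gene"]
    return CollapsedCq(frame)


def delta_cq(collapsed: CollapsedCq, reference_genes: list[str]) -> NormalizedExpression:
    """Comparative-Cq normalization against the mean of the reference genes.

    Samples in which any reference gene is missing or QC-excluded are
    dropped entirely (and listed in ``excluded``); for retained samples,
    each retained gene's value is -dCq = -(Cq_gene - mean Cq of the
    references).  Non-reference genes failing QC in a retained sample are
    reported as NaN and listed with their reason.
    """
    if not reference_genes:
        raise ValueError("reference gene list must be nonempty")
    refs = sorted(set(reference_genes))
    genes = collapsed.genes
    missing_refs = set(refs) - set(genes)
    if missing_refs:
        raise ValueError(f"reference genes absent from the data: {sorted(missing_refs)}")

    wide_cq = collapsed.retained["mean_cq"].unstack("gene").T  # gene x sample
    excluded: list[tuple[str, str, str]] = []

    keep_samples = []
    for sample in collapsed.samples:
        # a sample is retained only if every reference gene passed QC there
        ok = True
        for r in refs:
            val = wide_cq.at[r, sample] if (r in wide_cq.index and sample in wide_cq.columns) else np.nan
            if pd.isna(val):
                reason = "reference_gene_failed_qc"
                row = collapsed.data.loc[(sample, r)] if (sample, r) in collapsed.data.index else None
                if row is not None and row["exclusion_reason"] != "none":
                    reason = f"reference_{row['exclusion_reason']}"
                excluded.append((sample, r, reason))
                ok = False
        if ok:
            keep_samples.append(sample)
    if not keep_samples:
        raise ValueError("no sample retains all reference genes")

    cq = wide_cq.reindex(index=genes, columns=keep_samples)
    ref_mean = cq.loc[refs].mean(axis=0)
    ndcq = -(cq - ref_mean)

    for sample in keep_samples:
        for gene in genes:
            if pd.isna(cq.at[gene, sample]):
                idx = (sample, gene)
                reason = (
                    collapsed.data.at[idx, "exclusion_reason"]
                    if idx in collapsed.data.index
                    else "not_measured"
                )
                excluded.append((sample, gene, str(reason)))

    dropped = sorted(set(collapsed.samples) - set(keep_samples))
    if dropped:
        logger.warning("dropped %d sample(s) lacking a reference gene: %s", len(dropped), dropped)
    return NormalizedExpression(values=ndcq, reference_genes=refs, excluded=excluded)


def cq_to_log_quantity(cq, efficiency: float = 2.0):
    """Convert Cq to a log2 relative quantity (up to an additive constant).

    Each PCR cycle multiplies the template by ``efficiency``; a perfect
    reaction doubles (efficiency 2), giving -Cq directly.  Accepts scalars
    or arrays.
    """
    if not (1.0 < efficiency <= 2.0):
        raise ValueError("efficiency must lie in (1, 2]")
    return -np.asarray(cq, dtype=float) * np.log2(efficiency) if np.ndim(cq) else -float(cq) * np.log2(efficiency)


def log_quantity_matrix(
    collapsed: CollapsedCq,
    efficiency: float = 2.0,
    genes: list[str] | None = None,
    drop: str = "samples",
) -> tuple[pd.DataFrame, list[str]]:
    """Build the complete gene x sample log2-quantity matrix for stability
    analysis.

    QC-excluded pairs propagate as missing, and the stability algorithms
    assume a complete matrix, so the matrix is completed by complete-case
    deletion along one axis: ``drop="samples"`` (default) removes samples
    with any missing candidate measurement, preserving the candidate panel
    under evaluation; ``drop="genes"`` removes the affected genes instead.
    Returns the complete matrix and the dropped ids, with a logged count.
    """
    if not (1.0 < efficiency <= 2.0):
        raise ValueError("efficiency must lie in (1, 2]")
    cq = collapsed.retained["mean_cq"].unstack("gene").T  # gene x sample
    cq = cq.reindex(index=collapsed.genes, columns=collapsed.samples)
    if genes is not None:
        present = [g for g in genes if g in cq.index]
        cq = cq.loc[present]
    if drop == "samples":
        dropped = sorted(cq.columns[cq.isna().any(axis=0)])
        complete = cq.drop(columns=dropped)
        what = "sample(s)"
    elif drop == "genes":
        dropped = sorted(cq.index[cq.isna().any(axis=1)])
        complete = cq.drop(index=dropped)
        what = "gene(s)"
    else:
        raise ValueError("drop must be 'samples' or 'genes'")
    if dropped:
        logger.warning(
            "dropped %d %s with QC-missing values from stability input: %s",
            len(dropped), what, dropped,
        )
    return -complete * np.log2(efficiency), dropped
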