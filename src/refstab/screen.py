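"""Array-based candidate pre-screening cascade.

Starting from a literature-derived candidate list measured on bead
arrays, the cascade removes genes that are unsuitable as reference genes
for hypoxia studies: genes regulated by hypoxia in paired
normoxic/hypoxic cell-line cultures, genes whose expression tracks the
imaging hypoxia covariate (A_Brix) or clinical parameters (stage, lymph
node status, tumor volume) or outcome in the patient cohort, and genes
expressed too low for reliable qPCR detection.  Survivors are ranked by
coefficient of variation within expression-level bins to support panel
design across abundance ranges.

Gene-level decisions use the "at least one probe" rule throughout: a gene
is excluded as soon as any of its array probes trips a filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    EXCLUSION_FLAGS,
    ExpressionMatrix,
    ProbeGeneMap,
    SampleAnnotations,
    ScreenReport,
)

__all__ = [
    "CellLinePairing",
    "ScreenConfig",
    "hypoxia_fold_filter",
    "covariate_correlation_filter",
    "group_association_filter",
    "outcome_association_filter",
    "expression_floor_filter",
    "cv_rank",
    "run_screen",
]

logger = logging.getLogger(__name__)


@dataclass
class CellLinePairing:
    """Per cell line, the (normoxic, hypoxic) sample ids of a matrix."""

    pairs: dict[str, tuple[str, str]]

    def validate_against(self, m: ExpressionMatrix) -> None:
        samples = set(m.sample_ids)
        for line, (norm, hyp) in self.pairs.items():
            if norm == hyp:
                raise ValueError(f"cell line {line!r}: identical sample ids")
            missing = {norm, hyp} - samples
            if missing:
                raise ValueError(f"cell line {line!r}: samples {sorted(missing)} absent")


@dataclass
class ScreenConfig:
    """Thresholds of the cascade (defaults mirror the screening design)."""

    fold_threshold: float = 1.5  # hypoxia |FC| beyond which a gene is out
    alpha: float = 0.05  # two-sided significance level of all tests
    min_mean_log2: float = 7.0  # detection floor on mean log2 expression
    abrix_covariate: str = "a_brix"
    volume_covariate: str = "tumor_volume"
    dichotomies: tuple[str, ...] = ("stage_low_high", "ln_status")
    bh_correction: bool = False  # optional Benjamini-Hochberg per filter
    min_events: int = 10


def _maybe_bh(pvals: pd.Series, enabled: bool) -> pd.Series:
    if not enabled or pvals.dropna().empty:
        return pvals
    from statsmodels.stats.multitest import multipletests

    ok = pvals.dropna()
    adj = pd.Series(
        multipletests(ok.to_numpy(), method="fdr_bh")[1], index=ok.index
    )
    return adj.reindex(pvals.index)


def hypoxia_fold_filter(
    m: ExpressionMatrix, pairs: CellLinePairing, fold_threshold: float = 1.5
) -> tuple[set[str], pd.Series]:
    """Exclude features more than ``fold_threshold``-fold up- or
    downregulated under hypoxia in at least one cell line.

    On the log2 scale the criterion is max over lines of
    |hypoxic - normoxic| strictly greater than log2(fold_threshold).
    Returns (excluded features, per-feature max |log2 FC|).
    """
    pairs.validate_against(m)
    log_cut = np.log2(fold_threshold)
    fcs = pd.DataFrame(
        {
            line: (m.values[hyp] - m.values[norm]).abs()
            for line, (norm, hyp) in pairs.pairs.items()
        }
    )
    max_fc = fcs.max(axis=1)
    excluded = set(max_fc.index[max_fc > log_cut])
    return excluded, max_fc


def covariate_correlation_filter(
    m: ExpressionMatrix,
    covariate: pd.Series,
    probe_map: ProbeGeneMap,
    alpha: float = 0.05,
    bh: bool = False,
) -> tuple[set[str], pd.Series, list[str]]:
    """Exclude genes with at least one probe whose expression correlates
    (Spearman, two-sided p < alpha) with the continuous covariate.

    Only samples with an observed covariate enter; constant probes have an
    undefined correlation and never exclude (warned).  Returns (excluded
    genes, per-gene min p over probes, warnings).
    """
    cov = covariate.dropna()
    shared = [s for s in m.sample_ids if s in cov.index]
    if len(shared) < 5:
        raise ValueError("covariate observed on fewer than 5 matrix samples")
    warnings: list[str] = []
    if cov.loc[shared].nunique() == 1:
        warnings.append("covariate constant: correlation undefined, no exclusions")
        return set(), pd.Series(dtype=float), warnings

    gene_of = probe_map.as_series()
    pvals = {}
    for probe in m.feature_ids:
        x = m.values.loc[probe, shared].to_numpy()
        if np.ptp(x) == 0:
            warnings.append(f"probe {probe!r} constant: correlation undefined, kept")
            pvals[probe] = np.nan
            continue
        pvals[probe] = stats.spearmanr(x, cov.loc[shared].to_numpy()).pvalue
    pseries = _maybe_bh(pd.Series(pvals), bh)
    frame = pd.DataFrame({"p": pseries, "gene": gene_of.reindex(pseries.index)}).dropna(
        subset=["gene"]
    )
    min_p = frame.groupby("gene")["p"].min()
    excluded = set(min_p.index[min_p < alpha])
    return excluded, min_p, warnings


def group_association_filter(
    m: ExpressionMatrix,
    annotations: SampleAnnotations,
    probe_map: ProbeGeneMap,
    dichotomies: tuple[str, ...] = ("stage_low_high", "ln_status"),
    continuous: tuple[str, ...] = ("tumor_volume",),
    alpha: float = 0.05,
    bh: bool = False,
) -> tuple[set[str], pd.Series]:
    """Exclude genes associated with clinical groups or continuous
    clinical covariates.

    Dichotomies are tested per probe with the two-sided Mann-Whitney U
    (rank-sum) test; continuous covariates with Spearman correlation.  A
    gene is excluded if any probe is significant for any variable.
    Returns (excluded genes, per-gene min p).
    """
    gene_of = probe_map.as_series()
    all_p: list[pd.Series] = []
    for name in dichotomies:
        labels = annotations.group(name).reindex(m.sample_ids)
        levels = sorted(labels.dropna().unique())
        if len(levels) != 2:
            raise ValueError(f"group {name!r} is not a dichotomy: {levels}")
        a_cols = labels.index[labels == levels[0]]
        b_cols = labels.index[labels == levels[1]]
        if min(len(a_cols), len(b_cols)) < 3:
            raise ValueError(f"group {name!r}: a level has fewer than 3 samples")
        a = m.values[a_cols].to_numpy()
        b = m.values[b_cols].to_numpy()
        p = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided").pvalue
        all_p.append(_maybe_bh(pd.Series(p, index=m.feature_ids), bh))
    for name in continuous:
        cov = annotations.covariate(name).reindex(m.sample_ids).dropna()
        shared = list(cov.index)
        p = {}
        for probe in m.feature_ids:
            x = m.values.loc[probe, shared].to_numpy()
            p[probe] = (
                np.nan if np.ptp(x) == 0 else stats.spearmanr(x, cov.to_numpy()).pvalue
            )
        all_p.append(_maybe_bh(pd.Series(p), bh))
    stacked = pd.concat(all_p, axis=1)
    probe_min = stacked.min(axis=1)
    frame = pd.DataFrame({"p": probe_min, "gene": gene_of.reindex(probe_min.index)}).dropna(
        subset=["gene"]
    )
    min_p = frame.groupby("gene")["p"].min()
    excluded = set(min_p.index[min_p < alpha])
    return excluded, min_p


def outcome_association_filter(
    m: ExpressionMatrix,
    annotations: SampleAnnotations,
    probe_map: ProbeGeneMap,
    alpha: float = 0.05,
    min_events: int = 10,
    bh: bool = False,
) -> tuple[set[str], pd.Series, list[str]]:
    """Exclude genes related to progression-free survival.

    Per probe, a univariate Cox proportional-hazards fit on the continuous
    expression value; disease progression is the event, competing death
    and censoring count as censored.  Skipped with a warning when fewer
    than ``min_events`` progressions are observed.
    """
    from lifelines import CoxPHFitter

    surv = annotations.survival.reindex(m.sample_ids).dropna()
    event = (surv["event"] == "progression").astype(int)
    warnings: list[str] = []
    if int(event.sum()) < min_events:
        warnings.append(
            f"only {int(event.sum())} progression events (<{min_events}): outcome filter skipped"
        )
        return set(), pd.Series(dtype=float), warnings

    gene_of = probe_map.as_series()
    pvals = {}
    for probe in m.feature_ids:
        x = m.values.loc[probe, surv.index]
        if np.ptp(x.to_numpy()) == 0:
            pvals[probe] = np.nan
            continue
        df = pd.DataFrame(
            {"time": surv["time_months"], "event": event, "x": x}
        )
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        pvals[probe] = float(cph.summary.loc["x", "p"])
    pseries = _maybe_bh(pd.Series(pvals), bh)
    frame = pd.DataFrame({"p": pseries, "gene": gene_of.reindex(pseries.index)}).dropna(
        subset=["gene"]
    )
    min_p = frame.groupby("gene")["p"].min()
    excluded = set(min_p.index[min_p < alpha])
    return excluded, min_p, warnings


def expression_floor_filter(
    m: ExpressionMatrix, min_mean_log2: float = 7.0
) -> tuple[set[str], pd.Series]:
    """Exclude features whose mean log2 expression falls strictly below
    the detection floor (too dim for reliable qPCR assay design)."""
    means = m.values.mean(axis=1)
    return set(means.index[means < min_mean_log2]), means


def cv_rank(m: ExpressionMatrix, survivors: list[str]) -> pd.DataFrame:
    """CV (SD/mean of log2 values) per surviving gene, binned by
    expression level.

    Genes are assigned to tertile bins of mean log2 expression among
    survivors ("low"/"mid"/"high") so a final panel can represent
    different abundance ranges, and sorted ascending by CV within bin.
    Note the CV is computed on the log2 scale: it is not invariant to
    rescaling the log2 values, only to multiplicative scaling of the raw
    quantities' variation relative to their log-mean.
    """
    if not survivors:
        raise ValueError("no surviving genes to rank")
    sub = m.values.loc[[g for g in survivors if g in m.values.index]]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    cv = sd / mean
    lo, hi = np.percentile(mean, [100 / 3, 200 / 3])
    bins = pd.Series(
        np.where(mean <= lo, "low", np.where(mean <= hi, "mid", "high")),
        index=mean.index,
    )
    out = pd.DataFrame({"cv": cv, "mean_log2": mean, "expression_bin": bins})
    order = {"low": 0, "mid": 1, "high": 2}
    return out.sort_values(
        by=["expression_bin", "cv"], key=lambda s: s.map(order) if s.name == "expression_bin" else s
    )


def run_screen(
    candidates: list[str],
    m_patients: ExpressionMatrix,
    m_celllines: ExpressionMatrix,
    pairs: CellLinePairing,
    annotations: SampleAnnotations,
    probe_map: ProbeGeneMap,
    config: ScreenConfig | None = None,
) -> ScreenReport:
    """Run the full screening cascade over a candidate gene list.

    Stage order: hypoxia fold change (cell lines) -> covariate correlation
    (A_Brix) -> clinical group / tumor-volume association -> outcome
    association -> expression floor.  The filters are independent, so the
    order only affects the stage-count bookkeeping, not the survivor set.
    """
    cfg = config or ScreenConfig()
    if not candidates:
        raise ValueError("empty candidate list")
    gene_of = probe_map.as_series()
    cand = sorted(dict.fromkeys(candidates))
    warnings: list[str] = []

    probes_by_gene = {
        g: [p for p in probe_map.probes_of(g) if p in m_patients.feature_ids]
        for g in cand
    }
    measured = [g for g in cand if probes_by_gene[g]]
    not_measured = sorted(set(cand) - set(measured))
    if not_measured:
        warnings.append(f"candidates absent from patient matrix: {not_measured}")

    all_probes = [p for g in measured for p in probes_by_gene[g]]
    m_pat = ExpressionMatrix(m_patients.values.loc[all_probes])
    cl_probes = [p for p in all_probes if p in m_celllines.feature_ids]
    m_cl = ExpressionMatrix(m_celllines.values.loc[cl_probes])

    report = pd.DataFrame(index=pd.Index(cand, name="gene"))
    for flag in EXCLUSION_FLAGS:
        report[flag] = False
    report.loc[not_measured, "not_measured"] = True

    # -- stage 1: hypoxia regulation in paired cell-line cultures
    hyp_probes, max_fc = hypoxia_fold_filter(m_cl, pairs, cfg.fold_threshold)
    fc_frame = pd.DataFrame({"fc": max_fc, "gene": gene_of.reindex(max_fc.index)})
    gene_fc = fc_frame.groupby("gene")["fc"].max()
    hyp_genes = {gene_of[p] for p in hyp_probes}
    report["max_abs_log2_fold_change"] = gene_fc.reindex(report.index)
    report.loc[sorted(hyp_genes & set(measured)), "hypoxia_fold_excluded"] = True

    # -- stage 2: correlation with the imaging hypoxia covariate
    abrix = annotations.covariate(cfg.abrix_covariate)
    corr_genes, corr_p, w = covariate_correlation_filter(
        m_pat, abrix, probe_map, cfg.alpha, cfg.bh_correction
    )
    warnings += w
    report.loc[sorted(corr_genes & set(measured)), "covariate_corr_excluded"] = True

    # -- stage 3: clinical group & tumor-volume association
    grp_genes, grp_p = group_association_filter(
        m_pat,
        annotations,
        probe_map,
        cfg.dichotomies,
        (cfg.volume_covariate,),
        cfg.alpha,
        cfg.bh_correction,
    )
    report.loc[sorted(grp_genes & set(measured)), "group_assoc_excluded"] = True

    # -- stage 4: outcome (progression-free survival) association
    out_genes, out_p, w = outcome_association_filter(
        m_pat, annotations, probe_map, cfg.alpha, cfg.min_events, cfg.bh_correction
    )
    warnings += w
    report.loc[sorted(out_genes & set(measured)), "outcome_assoc_excluded"] = True

    min_p = pd.concat([corr_p, grp_p, out_p], axis=1).min(axis=1)
    report["min_covariate_p"] = min_p.reindex(report.index)

    # -- stage 5: expression floor
    floor_probes, probe_means = expression_floor_filter(m_pat, cfg.min_mean_log2)
    mean_frame = pd.DataFrame(
        {"mean": probe_means, "gene": gene_of.reindex(probe_means.index)}
    )
    gene_mean = mean_frame.groupby("gene")["mean"].mean()
    floor_genes = {gene_of[p] for p in floor_probes}
    report["mean_log2_expression"] = gene_mean.reindex(report.index)
    report.loc[sorted(floor_genes & set(measured)), "low_expression_excluded"] = True

    flag_cols = [c for c in EXCLUSION_FLAGS if c in report.columns]
    report["survivor"] = ~report[flag_cols].any(axis=1)

    # stage-count bookkeeping along the cascade
    def count(after_flags: list[str]) -> tuple[int, int]:
        alive = report.index[~report[after_flags].any(axis=1)]
        alive = [g for g in alive if g in measured]
        n_probes = sum(len(probes_by_gene[g]) for g in alive)
        return len(alive), n_probes

    stages = [
        ("input", ["not_measured"]),
        ("hypoxia_fold", ["not_measured", "hypoxia_fold_excluded"]),
        ("covariate_correlation", ["not_measured", "hypoxia_fold_excluded", "covariate_corr_excluded"]),
        (
            "group_association",
            ["not_measured", "hypoxia_fold_excluded", "covariate_corr_excluded", "group_assoc_excluded"],
        ),
        (
            "outcome_association",
            [
                "not_measured",
                "hypoxia_fold_excluded",
                "covariate_corr_excluded",
                "group_assoc_excluded",
                "outcome_assoc_excluded",
            ],
        ),
        ("expression_floor", flag_cols),
    ]
    stage_counts = [(name, *count(flags)) for name, flags in stages]

    survivors = report.index[report["survivor"]].tolist()
    if survivors:
        gene_level = ExpressionMatrix(
            pd.DataFrame(
                {
                    g: m_pat.values.loc[probes_by_gene[g]].mean(axis=0)
                    for g in measured
                }
            ).T
        )
        cv = cv_rank(gene_level, survivors)
        report["cv"] = cv["cv"].reindex(report.index)
        report["expression_bin"] = cv["expression_bin"].reindex(report.index)
    else:
        report["cv"] = np.nan
        report["expression_bin"] = pd.NA

    for msg in warnings:
        logger.warning(msg)
    return ScreenReport(per_gene=report, stage_counts=stage_counts, warnings=warnings)
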