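"""Model-based (ANOVA-style) stability estimation with intra- and
inter-group variance decomposition.

The log2 quantity of gene i in sample j of group g is modelled as

    y_igj = alpha_i + b_gj + d_ig + eps_igj

with a gene level alpha_i, a per-sample loading effect b_gj shared by all
genes, a gene-by-group deviation d_ig constrained to sum to zero over
genes within each group, and noise eps with gene-by-group variance
sigma2_ig.  Moment estimators (no iterative fitting):

* residuals  r_igj = y_igj - mean_j(y_ig.) - mean_i(y_.gj) + mean_ij(y_..g)
* sigma2_ig  = [G/(G-1)] * sum_j r_igj^2 / (n_g - 1), truncated at 0
* d_ig       = mean_j(y_ig.) - mean_gj(y_i..) - (mean_ij(y_..g) - mean(y))
* the d_ig are shrunk toward zero empirical-Bayes style with prior
  variance gamma2 = max(0, var_ig(d) - mean_ig(sigma2_ig / n_g)), each
  deviation scaled by gamma2 / (gamma2 + sigma2_ig / n_g).

A gene's stability value combines the magnitude of its (shrunk)
inter-group deviation with the uncertainty of its intra-group variation;
lower = more stable.  Without groups the stability value is simply the
residual SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import SampleAnnotations, StabilityReport

__all__ = ["NormFinderFit", "fit", "stability", "rank", "subgroup_scan", "median_dichotomy"]


@dataclass
class NormFinderFit:
    """Variance-decomposition estimates. Frames are gene x group."""

    genes: list[str]
    groups: list[str]
    n_per_group: pd.Series  # per group
    sigma2: pd.DataFrame  # intragroup noise variance per (gene, group)
    d_hat: pd.DataFrame  # raw gene-by-group deviations
    d_tilde: pd.DataFrame  # shrunk deviations
    gamma2: float  # prior variance of the deviations
    grouped: bool

    def __post_init__(self) -> None:
        if (self.sigma2.to_numpy() < 0).any():
            raise ValueError("intragroup variances must be non-negative")
        if self.gamma2 < 0:
            raise ValueError("prior variance must be non-negative")
        if (np.abs(self.d_tilde.to_numpy()) > np.abs(self.d_hat.to_numpy()) + 1e-12).any():
            raise ValueError("shrinkage must contract the deviations")


def fit(m: pd.DataFrame, groups: pd.Series | None = None) -> NormFinderFit:
    """Fit the variance-decomposition model on a complete gene x sample
    log2 matrix, optionally with per-sample group labels."""
    if m.isna().any().any():
        raise ValueError("NormFinder input must be complete (no missing values)")
    if m.shape[0] < 3:
        raise ValueError("need at least 3 genes")
    genes = list(m.index)
    n_genes = len(genes)

    if groups is None:
        labels = pd.Series("all", index=m.columns)
        grouped = False
    else:
        labels = groups.reindex(m.columns).astype(str)
        if labels.isna().any():
            raise ValueError("every sample needs a group label")
        grouped = True
    group_names = sorted(labels.unique())

    sigma2 = pd.DataFrame(index=genes, columns=group_names, dtype=float)
    d_hat = pd.DataFrame(index=genes, columns=group_names, dtype=float)
    n_per_group = pd.Series(0, index=group_names, dtype=int)

    grand_mean = float(m.to_numpy().mean())
    gene_means = m.mean(axis=1)  # over all samples

    for g in group_names:
        cols = labels.index[labels == g]
        n_g = len(cols)
        if n_g < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        n_per_group[g] = n_g
        block = m[cols].to_numpy()
        gene_mean_g = block.mean(axis=1, keepdims=True)  # y_ig.
        sample_mean_g = block.mean(axis=0, keepdims=True)  # y_.gj
        group_mean = block.mean()  # y_..g
        resid = block - gene_mean_g - sample_mean_g + group_mean
        rss = (resid**2).sum(axis=1)
        sigma2[g] = np.maximum(
            0.0, (n_genes / (n_genes - 1)) * rss / (n_g - 1)
        )
        d_hat[g] = gene_mean_g.ravel() - gene_means.to_numpy() - (group_mean - grand_mean)

    if grouped:
        sampling_var = sigma2.div(n_per_group, axis=1)  # var of d_hat approx
        gamma2 = max(
            0.0,
            float(np.var(d_hat.to_numpy(), ddof=1)) - float(sampling_var.to_numpy().mean()),
        )
        d_tilde = d_hat * (gamma2 / (gamma2 + sampling_var)) if gamma2 > 0 else d_hat * 0.0
    else:
        gamma2 = 0.0
        d_hat.loc[:, :] = 0.0
        d_tilde = d_hat.copy()

    return NormFinderFit(
        genes=genes,
        groups=group_names,
        n_per_group=n_per_group,
        sigma2=sigma2,
        d_hat=d_hat,
        d_tilde=d_tilde,
        gamma2=gamma2,
        grouped=grouped,
    )


def stability(fitted: NormFinderFit) -> StabilityReport:
    """Combine the variance components into a per-gene stability value.

    Grouped designs: mean over groups of |shrunk deviation| plus an
    uncertainty term sqrt(s + gamma2*s/(gamma2 + s)) with s = sigma2/n_g.
    Ungrouped: the residual SD.  Ranking ascends in the stability value,
    ties broken alphabetically.
    """
    if fitted.grouped:
        s = fitted.sigma2.div(fitted.n_per_group, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            extra = np.where(
                (fitted.gamma2 + s) > 0,
                fitted.gamma2 * s / (fitted.gamma2 + s),
                0.0,
            )
        term = fitted.d_tilde.abs() + np.sqrt(s + extra)
        rho = term.mean(axis=1)
    else:
        rho = np.sqrt(fitted.sigma2.iloc[:, 0])
    per_gene = {g: float(rho[g]) for g in fitted.genes}
    ranking = sorted(fitted.genes, key=lambda g: (per_gene[g], g))
    return StabilityReport(method="normfinder", per_gene=per_gene, ranking=ranking)


def rank(m: pd.DataFrame, groups: pd.Series | None = None) -> StabilityReport:
    """Convenience: fit + stability in one call."""
    return stability(fit(m, groups))


def median_dichotomy(values: pd.Series, name: str = "covariate") -> pd.Series:
    """Split a continuous covariate at its median; values equal to the
    median land in the 'low' (below-or-equal) group."""
    med = float(values.median())
    return pd.Series(
        np.where(values <= med, f"{name}_low", f"{name}_high"), index=values.index
    )


def subgroup_scan(
    m: pd.DataFrame,
    annotations: SampleAnnotations,
    groupings: list[str],
) -> dict[str, StabilityReport]:
    """Grouped stability analysis per clinical dichotomy.

    Each grouping names either a declared discrete group or a continuous
    covariate (dichotomized at the cohort median).  One grouped report per
    grouping, on the samples the matrix and annotations share.
    """
    reports: dict[str, StabilityReport] = {}
    for name in groupings:
        if name in annotations.group_names:
            labels = annotations.group(name).reindex(m.columns)
        elif name in annotations.covariate_names:
            cov = annotations.covariate(name).reindex(m.columns)
            if cov.isna().any():
                keep = cov.dropna().index
                labels = median_dichotomy(cov.loc[keep], name)
                reports[name] = rank(m[keep], labels)
                continue
            labels = median_dichotomy(cov, name)
        else:
            raise KeyError(f"grouping {name!r} not found in annotations")
        reports[name] = rank(m, labels)
    return reports
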