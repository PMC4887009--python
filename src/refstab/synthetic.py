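"""Seeded generators of synthetic qPCR / array cohorts.

The generators emulate the statistical structure the analysis assumes so
every pipeline stage can be exercised without access to the (undeposited)
clinical data: per-gene biological and technical variance, per-sample
global loading shifts in the Cq data, gene-by-group regulation, hypoxia
fold changes in paired cell-line cultures, duplicate technical
replicates, an imaging hypoxia covariate (A_Brix, lognormal, observed on
a subcohort), clinical dichotomies, competing-risk survival, and
multi-biopsy tumors with within- and between-tumor variance.

Default parameters mirror the study design being emulated: a 74-patient
qPCR cohort (150 for array screening), eight cell lines under
normoxia/hypoxia, duplicate reactions, and a 9-gene candidate panel in
which three genes (CHCHD1, SRSF9, TMBIM6) are planted stable and the
rest carry noise, covariate links or group shifts, plus three
hypoxia-induced target genes (DDIT3, ERO1A, STC2).

Cq orientation: one cycle per doubling, higher abundance = lower Cq;
``Cq = cq_offset - log2 signal + loading + technical noise``.  The offset
is arbitrary (it cancels in every downstream contrast) and defaults to 35
so simulated Cq values land in the realistic 18-30 range.

All randomness flows from one explicitly passed seed; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import CqTable, ExpressionMatrix, ProbeGeneMap, SampleAnnotations
from .screen import CellLinePairing

__all__ = [
    "GeneSpec",
    "SimConfig",
    "default_panel",
    "null_panel",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_cell_lines",
    "simulate_heterogeneity",
]


@dataclass(frozen=True)
class GeneSpec:
    """Planted generative parameters of one gene.

    ``base``: mean log2 expression; ``bio_sd``: per-sample biological SD
    (log2); ``abrix_slope``: log2 change per SD of the latent hypoxia
    covariate; ``group_shifts``: log2 shift added in the second (``high``
    / ``positive``) level of a named dichotomy; ``hazard_beta``:
    log-hazard-ratio per log2 unit of expression; ``hypoxia_fc``: log2
    fold change in hypoxic cell-line cultures.
    """

    base: float
    bio_sd: float = 0.3
    abrix_slope: float = 0.0
    group_shifts: dict[str, float] = field(default_factory=dict)
    hazard_beta: float = 0.0
    hypoxia_fc: float = 0.0

    def __post_init__(self) -> None:
        if self.bio_sd < 0:
            raise ValueError("biological SD must be >= 0")


def default_panel() -> dict[str, GeneSpec]:
    """The emulated candidate panel: three stable reference genes, six
    unstable candidates (noise, hypoxia/covariate links, group shifts),
    and three hypoxia-induced targets.

    Base levels span the study panel's 7.4-14.0 log2 range.  Unstable
    candidates have a total SD near 0.6 log2 units; hypoxia-induced
    targets respond to the latent hypoxia covariate (negative A_Brix
    association) and carry an outcome link for the strongest (STC2).
    """
    return {
        # planted-stable reference trio
        "CHCHD1": GeneSpec(base=9.5, bio_sd=0.15),
        "SRSF9": GeneSpec(base=10.5, bio_sd=0.15),
        "TMBIM6": GeneSpec(base=13.0, bio_sd=0.15),
        # unstable: pure biological noise
        "GNB2L1": GeneSpec(base=14.0, bio_sd=0.6),
        "IPO8": GeneSpec(base=8.0, bio_sd=0.6),
        # unstable: tracks the hypoxia covariate
        "LASP1": GeneSpec(base=11.5, bio_sd=0.4, abrix_slope=0.45),
        "RPL27A": GeneSpec(base=12.5, bio_sd=0.4, abrix_slope=-0.45),
        # unstable: clinical-group regulation
        "RPS12": GeneSpec(base=12.0, bio_sd=0.4, group_shifts={"ln_status": 0.8}),
        "SOD1": GeneSpec(base=10.0, bio_sd=0.4, group_shifts={"stage_low_high": 0.8}),
        # hypoxia-induced validation targets (low A_Brix = hypoxic = high expression)
        "DDIT3": GeneSpec(base=8.5, bio_sd=0.5, abrix_slope=-0.5, hypoxia_fc=1.5),
        "ERO1A": GeneSpec(base=9.0, bio_sd=0.5, abrix_slope=-0.5, hypoxia_fc=1.2),
        "STC2": GeneSpec(base=8.0, bio_sd=0.5, abrix_slope=-0.5, hypoxia_fc=2.0, hazard_beta=0.6),
    }


def null_panel(n_genes: int, bio_sd: float = 0.3, base_range: tuple[float, float] = (7.5, 14.0), seed: int = 0) -> dict[str, GeneSpec]:
    """``n_genes`` independent genes with no planted effects (global null)."""
    rng = np.random.default_rng(seed)
    bases = rng.uniform(*base_range, size=n_genes)
    return {f"G{i:04d}": GeneSpec(base=float(b), bio_sd=bio_sd) for i, b in enumerate(bases)}


@dataclass
class SimConfig:
    """Cohort-level generative parameters (defaults = emulated study design)."""

    seed: int
    n_samples: int = 74
    genes: dict[str, GeneSpec] = field(default_factory=default_panel)
    # qPCR technical layer
    sample_loading_sd: float = 0.5  # log2 / Cq units, global per-sample shift
    tech_rep_sd: float = 0.15  # Cq units, per technical replicate
    n_replicates: int = 2
    cq_offset: float = 35.0
    # array layer
    array_noise_sd: float = 0.1  # log2, per probe measurement
    n_probes_per_gene: int = 1
    # annotation model
    abrix_meanlog: float = float(np.log(1.51))
    abrix_sdlog: float = 0.40
    n_abrix: int | None = 32  # samples with an observed A_Brix (None = all)
    group_prevalence: dict[str, tuple[str, str, float]] = field(
        default_factory=lambda: {
            "stage_low_high": ("low", "high", 0.34),
            "ln_status": ("negative", "positive", 0.43),
        }
    )
    progression_rate: float = 0.0095  # per month; ~43% progress by 60 months
    competing_rate: float = 0.0012  # non-disease death; ~5/74 by 60 months
    dropout_prob: float = 0.15
    dropout_window: tuple[float, float] = (24.0, 60.0)
    followup_months: float = 60.0
    # cell-line design
    n_cell_lines: int = 8
    line_effect_sd: float = 0.3  # per-line baseline shift
    cell_noise_sd: float = 0.1  # per-culture measurement noise
    # heterogeneity cohort
    n_tumors: int = 8
    biopsies_per_tumor: tuple[int, ...] = (3, 3, 3, 3, 3, 3, 2, 2)
    within_tumor_sd: float = 0.3
    between_tumor_sd: float = 1.5
    heterogeneity_gene: str = "STC2"

    def __post_init__(self) -> None:
        for name, val in [
            ("sample_loading_sd", self.sample_loading_sd),
            ("tech_rep_sd", self.tech_rep_sd),
            ("array_noise_sd", self.array_noise_sd),
            ("within_tumor_sd", self.within_tumor_sd),
            ("between_tumor_sd", self.between_tumor_sd),
        ]:
            if val < 0:
                raise ValueError(f"{name} must be >= 0")
        for _, (_, _, p) in self.group_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError("prevalences must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        bad = [
            g
            for spec in self.genes.values()
            for g in spec.group_shifts
            if g not in self.group_prevalence
        ]
        if bad:
            raise ValueError(f"group shifts reference undeclared groups: {sorted(set(bad))}")


@dataclass
class SimulatedCohort:
    """Synthetic patient cohort plus the ground truth that generated it."""

    array: ExpressionMatrix  # probe level, log2
    cq: CqTable
    annotations: SampleAnnotations
    probe_map: ProbeGeneMap
    truth: dict


def _probe_ids(cfg: SimConfig, gene: str) -> list[str]:
    if cfg.n_probes_per_gene == 1:
        return [gene]
    return [f"{gene}_p{k + 1}" for k in range(cfg.n_probes_per_gene)]


def simulate_cohort(cfg: SimConfig) -> SimulatedCohort:
    """Generate one patient cohort: log2 array matrix, replicate-level Cq
    table, clinical annotations and probe map, with full ground truth."""
    rng = np.random.default_rng([cfg.seed, 11])
    genes = list(cfg.genes)
    n = cfg.n_samples
    samples = [f"P{i + 1:03d}" for i in range(n)]

    # latent hypoxia covariate, standardized for effect injection
    abrix = rng.lognormal(cfg.abrix_meanlog, cfg.abrix_sdlog, size=n)
    z = (abrix - abrix.mean()) / abrix.std()

    group_labels: dict[str, np.ndarray] = {}
    for name, (lo, hi, prev) in cfg.group_prevalence.items():
        group_labels[name] = np.where(rng.random(n) < prev, hi, lo)

    signal = pd.DataFrame(index=genes, columns=samples, dtype=float)
    for gene, spec in cfg.genes.items():
        mu = spec.base + spec.abrix_slope * z
        for gname, shift in spec.group_shifts.items():
            hi = cfg.group_prevalence[gname][1]
            mu = mu + shift * (group_labels[gname] == hi)
        signal.loc[gene] = mu + rng.normal(0.0, spec.bio_sd, size=n)

    # competing-risk survival driven by outcome-linked genes
    log_hr = np.zeros(n)
    for gene, spec in cfg.genes.items():
        if spec.hazard_beta:
            log_hr += spec.hazard_beta * (signal.loc[gene].to_numpy() - spec.base)
    t_prog = rng.exponential(1.0, size=n) / (cfg.progression_rate * np.exp(log_hr))
    t_comp = rng.exponential(1.0, size=n) / cfg.competing_rate
    censor = np.full(n, cfg.followup_months)
    drop = rng.random(n) < cfg.dropout_prob
    censor[drop] = rng.uniform(*cfg.dropout_window, size=int(drop.sum()))
    time = np.minimum.reduce([t_prog, t_comp, censor])
    event = np.where(
        t_prog <= time, "progression", np.where(t_comp <= time, "competing_death", "censored")
    )

    # array layer: probes = gene signal + probe noise
    probe_rows, probe_names, probe_genes = [], [], []
    for gene in genes:
        for pid in _probe_ids(cfg, gene):
            probe_rows.append(
                signal.loc[gene].to_numpy() + rng.normal(0.0, cfg.array_noise_sd, size=n)
            )
            probe_names.append(pid)
            probe_genes.append(gene)
    array = ExpressionMatrix(pd.DataFrame(probe_rows, index=probe_names, columns=samples))
    probe_map = ProbeGeneMap(pd.DataFrame({"probe": probe_names, "gene": probe_genes}))

    # qPCR layer: Cq = offset - signal + loading + technical noise
    loading = rng.normal(0.0, cfg.sample_loading_sd, size=n)
    records = []
    for gene in genes:
        base_cq = cfg.cq_offset - signal.loc[gene].to_numpy() + loading
        for rep in range(1, cfg.n_replicates + 1):
            noise = (
                rng.normal(0.0, cfg.tech_rep_sd, size=n) if cfg.tech_rep_sd > 0 else 0.0
            )
            cq_vals = base_cq + noise
            records.append(
                pd.DataFrame(
                    {"sample": samples, "gene": gene, "replicate": rep, "cq": cq_vals}
                )
            )
    cq = CqTable(pd.concat(records, ignore_index=True))

    observed_abrix = abrix.copy()
    if cfg.n_abrix is not None and cfg.n_abrix < n:
        hidden = rng.choice(n, size=n - cfg.n_abrix, replace=False)
        observed_abrix[hidden] = np.nan

    ann_frame = pd.DataFrame(
        {
            **{name: labels for name, labels in group_labels.items()},
            "recurrence": np.where(event == "progression", "yes", "no"),
            "a_brix": observed_abrix,
            "tumor_volume": rng.lognormal(np.log(44.0), 0.8, size=n),
            "time_months": time,
            "event": event,
        },
        index=pd.Index(samples, name="sample"),
    )
    annotations = SampleAnnotations(
        ann_frame,
        group_names=list(cfg.group_prevalence) + ["recurrence"],
        covariate_names=["a_brix", "tumor_volume"],
    )

    truth = {
        "signal": signal,
        "loading": pd.Series(loading, index=samples),
        "abrix_latent": pd.Series(abrix, index=samples),
        "abrix_z": pd.Series(z, index=samples),
        "log_hazard": pd.Series(log_hr, index=samples),
        "genes": dict(cfg.genes),
    }
    return SimulatedCohort(array=array, cq=cq, annotations=annotations, probe_map=probe_map, truth=truth)


def simulate_cell_lines(
    cfg: SimConfig,
) -> tuple[ExpressionMatrix, CellLinePairing, dict]:
    """Paired normoxic/hypoxic log2 profiles for each cell line; planted
    hypoxia fold changes are applied in the hypoxic cultures only."""
    rng = np.random.default_rng([cfg.seed, 23])
    lines = [f"CL{i + 1}" for i in range(cfg.n_cell_lines)]
    cols = [f"{ln}_{cond}" for ln in lines for cond in ("N", "H")]
    probe_rows, probe_names, probe_genes = [], [], []
    line_effects = {
        gene: rng.normal(0.0, cfg.line_effect_sd, size=cfg.n_cell_lines)
        for gene in cfg.genes
    }
    for gene, spec in cfg.genes.items():
        for pid in _probe_ids(cfg, gene):
            row = []
            for i, _line in enumerate(lines):
                base = spec.base + line_effects[gene][i]
                row.append(base + rng.normal(0.0, cfg.cell_noise_sd))  # normoxic
                row.append(base + spec.hypoxia_fc + rng.normal(0.0, cfg.cell_noise_sd))
            probe_rows.append(row)
            probe_names.append(pid)
            probe_genes.append(gene)
    matrix = ExpressionMatrix(pd.DataFrame(probe_rows, index=probe_names, columns=cols))
    pairing = CellLinePairing({ln: (f"{ln}_N", f"{ln}_H") for ln in lines})
    truth = {
        "hypoxia_fc": {g: s.hypoxia_fc for g, s in cfg.genes.items()},
        "line_effects": line_effects,
    }
    return matrix, pairing, truth


def simulate_heterogeneity(cfg: SimConfig) -> tuple[CqTable, pd.Series, dict]:
    """Multi-biopsy tumors for intra-tumor concordance analysis.

    The heterogeneity gene gets a per-tumor latent level
    ~ Normal(0, between-tumor SD) shared by its biopsies; each biopsy adds
    Normal(0, within-tumor SD).  Reference genes keep their configured
    biological SD per biopsy.  Output is a replicate-level Cq table over
    all biopsies plus the biopsy -> tumor assignment.
    """
    if len(cfg.biopsies_per_tumor) != cfg.n_tumors:
        raise ValueError("biopsies_per_tumor length must equal n_tumors")
    if cfg.heterogeneity_gene not in cfg.genes:
        raise ValueError(f"heterogeneity gene {cfg.heterogeneity_gene!r} not in panel")
    rng = np.random.default_rng([cfg.seed, 37])

    biopsy_ids, tumor_of = [], []
    for t, n_b in enumerate(cfg.biopsies_per_tumor, start=1):
        for b in range(1, n_b + 1):
            biopsy_ids.append(f"T{t}B{b}")
            tumor_of.append(f"T{t}")
    n = len(biopsy_ids)
    tumor_ids = pd.Series(tumor_of, index=biopsy_ids, name="tumor_id")

    latent = rng.normal(0.0, cfg.between_tumor_sd, size=cfg.n_tumors)
    latent_of_biopsy = np.array(
        [latent[int(t[1:]) - 1] for t in tumor_of]
    )

    signal = {}
    target = cfg.heterogeneity_gene
    for gene, spec in cfg.genes.items():
        if gene == target:
            signal[gene] = (
                spec.base + latent_of_biopsy + rng.normal(0.0, cfg.within_tumor_sd, size=n)
            )
        else:
            signal[gene] = spec.base + rng.normal(0.0, spec.bio_sd, size=n)

    loading = rng.normal(0.0, cfg.sample_loading_sd, size=n)
    records = []
    for gene, vals in signal.items():
        base_cq = cfg.cq_offset - vals + loading
        for rep in range(1, cfg.n_replicates + 1):
            noise = (
                rng.normal(0.0, cfg.tech_rep_sd, size=n) if cfg.tech_rep_sd > 0 else 0.0
            )
            records.append(
                pd.DataFrame(
                    {"sample": biopsy_ids, "gene": gene, "replicate": rep, "cq": base_cq + noise}
                )
            )
    cq = CqTable(pd.concat(records, ignore_index=True))
    truth = {
        "tumor_latent": pd.Series(latent, index=[f"T{t + 1}" for t in range(cfg.n_tumors)]),
        "signal": pd.DataFrame(signal, index=biopsy_ids).T,
        "loading": pd.Series(loading, index=biopsy_ids),
    }
    return cq, tumor_ids, truth
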