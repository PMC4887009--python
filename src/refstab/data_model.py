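"""Domain types and delimited-text I/O shared by all pipeline stages.

All tabular formats are plain CSV/TSV (dialect chosen from the file
extension, UTF-8).  Missing quantification-cycle values are represented as
``NaN`` in memory; on disk any of the tokens in :data:`MISSING_CQ_TOKENS`
is accepted and ``Undetermined`` is written back.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING_CQ_TOKENS",
    "SURVIVAL_EVENTS",
    "CqTable",
    "ExpressionMatrix",
    "ProbeGeneMap",
    "SampleAnnotations",
    "StabilityReport",
    "TraceStep",
    "ScreenReport",
    "NormalizedExpression",
    "CorrelationResult",
    "read_cq_table",
    "write_cq_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_annotations",
    "write_annotations",
    "read_probe_map",
    "write_probe_map",
]

#: Tokens interpreted as a missing ("undetermined") Cq on input.
MISSING_CQ_TOKENS = frozenset({"undetermined", "Undetermined", "NA", ""})

#: Admissible survival event labels (competing-risk coding).
SURVIVAL_EVENTS = frozenset({"progression", "competing_death", "censored"})


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".txt", ".tab")) else ","


# ---------------------------------------------------------------------------
# Cq table
# ---------------------------------------------------------------------------

@dataclass
class CqTable:
    """Replicate-level quantification cycles, one row per (sample, gene, replicate).

    ``data`` has columns ``sample``, ``gene``, ``replicate`` (int >= 1) and
    ``cq`` (float; ``NaN`` encodes an undetermined reaction).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample", "gene", "replicate", "cq"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"CqTable missing columns: {missing}")
        df = self.data.loc[:, required].copy()
        df["sample"] = df["sample"].astype(str).str.strip()
        df["gene"] = df["gene"].astype(str).str.strip()
        df["replicate"] = df["replicate"].astype(int)
        df["cq"] = df["cq"].astype(float)
        if (df["replicate"] < 1).any():
            raise ValueError("replicate indices must be >= 1")
        dup = df.duplicated(subset=["sample", "gene", "replicate"])
        if dup.any():
            first = df.loc[dup.idxmax(), ["sample", "gene", "replicate"]]
            raise ValueError(
                "duplicate Cq entry for "
                f"({first['sample']}, {first['gene']}, {first['replicate']})"
            )
        finite = df["cq"].dropna()
        if not np.isfinite(finite).all():
            raise ValueError("Cq values must be finite or undetermined")
        if (finite <= 0).any():
            raise ValueError("Cq values must be positive")
        self.data = df.reset_index(drop=True)

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    @property
    def samples(self) -> list[str]:
        return sorted(self.data["sample"].unique())

    def __len__(self) -> int:
        return len(self.data)


def read_cq_table(path: str | Path, dialect: str = "long") -> CqTable:
    """Read a Cq table from delimited text.

    ``long`` dialect: columns ``sample,gene,replicate,cq``.  ``wide``
    dialect: one row per gene, columns ``gene`` then ``<sample>_<rep>``.
    Missing tokens (``Undetermined``/``NA``/empty) map to undetermined.
    """
    sep = _sep_for(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    raw.columns = [c.strip() for c in raw.columns]
    if dialect == "long":
        rows = raw
    elif dialect == "wide":
        if "gene" not in raw.columns:
            raise ValueError("wide Cq table needs a 'gene' column")
        long_rows = []
        for col in raw.columns:
            if col == "gene":
                continue
            sample, _, rep = col.rpartition("_")
            if not sample or not rep.isdigit():
                raise ValueError(
                    f"wide Cq column {col!r} is not of the form <sample>_<replicate>"
                )
            part = pd.DataFrame(
                {
                    "sample": sample,
                    "gene": raw["gene"],
                    "replicate": int(rep),
                    "cq": raw[col],
                }
            )
            long_rows.append(part)
        rows = pd.concat(long_rows, ignore_index=True)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    def parse_cq(value: str, row: int) -> float:
        token = value.strip()
        if token in MISSING_CQ_TOKENS:
            return np.nan
        try:
            return float(token)
        except ValueError:
            raise ValueError(f"non-numeric Cq value {value!r} in data row {row}") from None

    cq = [parse_cq(v, i) for i, v in enumerate(rows["cq"], start=1)]
    frame = pd.DataFrame(
        {
            "sample": rows["sample"].astype(str),
            "gene": rows["gene"].astype(str),
            "replicate": rows["replicate"].astype(int),
            "cq": cq,
        }
    )
    return CqTable(frame)


def write_cq_table(table: CqTable, path: str | Path) -> None:
    out = table.data.copy()
    out["cq"] = out["cq"].map(lambda v: "Undetermined" if pd.isna(v) else repr(float(v)))
    out.to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """log2 expression, features (probes or genes) x samples."""

    values: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        vals = self.values
        if vals.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if vals.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        arr = vals.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        vals = vals.astype(float)
        vals.index = vals.index.astype(str).str.strip()
        vals.columns = vals.columns.astype(str).str.strip()
        self.values = vals
        if self.scale != "log2":
            raise ValueError("only log2-scale matrices are supported")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    frame = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return ExpressionMatrix(frame)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep=_sep_for(path), index_label="feature")


# ---------------------------------------------------------------------------
# Probe -> gene map
# ---------------------------------------------------------------------------

@dataclass
class ProbeGeneMap:
    """Many-to-one mapping of array probes to gene symbols."""

    pairs: pd.DataFrame  # columns probe, gene

    def __post_init__(self) -> None:
        df = self.pairs.loc[:, ["probe", "gene"]].copy()
        df["probe"] = df["probe"].astype(str).str.strip()
        df["gene"] = df["gene"].astype(str).str.strip()
        if df["probe"].duplicated().any():
            dup = df.loc[df["probe"].duplicated(), "probe"].iloc[0]
            raise ValueError(f"probe {dup!r} mapped more than once")
        self.pairs = df.reset_index(drop=True)

    def gene_of(self, probe: str) -> str:
        return dict(zip(self.pairs["probe"], self.pairs["gene"]))[probe]

    def probes_of(self, gene: str) -> list[str]:
        return list(self.pairs.loc[self.pairs["gene"] == gene, "probe"])

    @property
    def genes(self) -> list[str]:
        return sorted(self.pairs["gene"].unique())

    def as_series(self) -> pd.Series:
        return self.pairs.set_index("probe")["gene"]


def read_probe_map(path: str | Path) -> ProbeGeneMap:
    return ProbeGeneMap(pd.read_csv(path, sep=_sep_for(path), dtype=str))


def write_probe_map(m: ProbeGeneMap, path: str | Path) -> None:
    m.pairs.to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# Sample annotations
# ---------------------------------------------------------------------------

@dataclass
class SampleAnnotations:
    """Per-sample clinical annotation: group labels, continuous covariates,
    survival triples and (optionally) tumor ids for multi-biopsy cohorts.

    ``data`` is indexed by sample id.  ``group_names`` columns hold discrete
    labels, ``covariate_names`` columns hold reals (NaN allowed: e.g. the
    imaging covariate is observed only in a subcohort).  Survival columns,
    when present, are ``time_months`` (> 0) and ``event`` (one of
    :data:`SURVIVAL_EVENTS`).
    """

    data: pd.DataFrame
    group_names: list[str] = field(default_factory=list)
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.data.copy()
        df.index = df.index.astype(str).str.strip()
        if df.index.has_duplicates:
            raise ValueError("duplicate sample ids in annotations")
        for name in self.group_names:
            if name not in df.columns:
                raise ValueError(f"group column {name!r} missing")
            df[name] = df[name].astype(str)
        for name in self.covariate_names:
            if name not in df.columns:
                raise ValueError(f"covariate column {name!r} missing")
            df[name] = df[name].astype(float)
        if "time_months" in df.columns:
            df["time_months"] = df["time_months"].astype(float)
            if (df["time_months"] <= 0).any():
                raise ValueError("survival times must be positive")
            bad = set(df["event"].astype(str)) - SURVIVAL_EVENTS
            if bad:
                raise ValueError(f"unknown survival event labels: {sorted(bad)}")
            df["event"] = df["event"].astype(str)
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def group(self, name: str) -> pd.Series:
        if name not in self.group_names:
            raise KeyError(f"unknown group {name!r}")
        return self.data[name]

    def covariate(self, name: str) -> pd.Series:
        if name not in self.covariate_names:
            raise KeyError(f"unknown covariate {name!r}")
        return self.data[name]

    @property
    def survival(self) -> pd.DataFrame:
        if "time_months" not in self.data.columns:
            raise KeyError("annotations carry no survival columns")
        return self.data[["time_months", "event"]]


def read_annotations(
    path: str | Path,
    group_names: Sequence[str] = (),
    covariate_names: Sequence[str] = (),
) -> SampleAnnotations:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    reserved = ["time_months", "event", "tumor_id"]
    groups = list(group_names) if group_names else [
        c
        for c in df.columns
        if c not in reserved and not pd.api.types.is_numeric_dtype(df[c])
    ]
    covs = list(covariate_names) if covariate_names else [
        c
        for c in df.columns
        if c not in groups + reserved and pd.api.types.is_numeric_dtype(df[c])
    ]
    return SampleAnnotations(df, group_names=groups, covariate_names=covs)


def write_annotations(ann: SampleAnnotations, path: str | Path) -> None:
    ann.data.to_csv(path, sep=_sep_for(path), index_label="sample")


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceStep:
    """One stepwise-exclusion step: genes still in play, their mean M, and
    the gene removed at the end of the step (None for the terminal pair)."""

    remaining: tuple[str, ...]
    average_m: float
    removed: str | None
    removed_m: float | None


@dataclass
class StabilityReport:
    """Per-gene stability statistics from geNorm or NormFinder."""

    method: str  # "genorm" | "normfinder"
    per_gene: dict[str, float]
    ranking: list[str]  # most -> least stable
    trace: list[TraceStep] = field(default_factory=list)
    pairwise_variation: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.method not in {"genorm", "normfinder"}:
            raise ValueError(f"unknown method {self.method!r}")
        if sorted(self.ranking) != sorted(self.per_gene):
            raise ValueError("ranking must be a permutation of the scored genes")
        if any(v < 0 for _, v in self.pairwise_variation):
            raise ValueError("pairwise variation must be non-negative")
        rem = [set(s.remaining) for s in self.trace]
        for a, b in zip(rem, rem[1:]):
            if not a >= b:
                raise ValueError("trace sets must be nested")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "per_gene": self.per_gene,
            "ranking": self.ranking,
            "trace": [
                {
                    "remaining": list(s.remaining),
                    "average_m": s.average_m,
                    "removed": s.removed,
                    "removed_m": s.removed_m,
                }
                for s in self.trace
            ],
            "pairwise_variation": [[n, v] for n, v in self.pairwise_variation],
        }


EXCLUSION_FLAGS = [
    "not_measured",
    "hypoxia_fold_excluded",
    "covariate_corr_excluded",
    "group_assoc_excluded",
    "outcome_assoc_excluded",
    "low_expression_excluded",
]


@dataclass
class ScreenReport:
    """Outcome of the candidate screening cascade.

    ``per_gene`` is indexed by gene with boolean exclusion-flag columns,
    a ``survivor`` column, and summary statistics; ``stage_counts`` lists
    (stage name, surviving genes, surviving probes) along the cascade.
    """

    per_gene: pd.DataFrame
    stage_counts: list[tuple[str, int, int]]
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        flags = [c for c in EXCLUSION_FLAGS if c in self.per_gene.columns]
        excluded = self.per_gene[flags].any(axis=1)
        if not (self.per_gene["survivor"] == ~excluded).all():
            raise ValueError("survivor flag inconsistent with exclusion flags")
        genes = [n for _, n, _ in self.stage_counts]
        if any(a < b for a, b in zip(genes, genes[1:])):
            raise ValueError("stage gene counts must be non-increasing")

    @property
    def survivors(self) -> list[str]:
        return sorted(self.per_gene.index[self.per_gene["survivor"]])

    def to_dict(self) -> dict:
        return {
            "per_gene": self.per_gene.reset_index()
            .rename(columns={"index": "gene"})
            .to_dict(orient="records"),
            "stage_counts": [
                {"stage": s, "n_genes": g, "n_probes": p}
                for s, g, p in self.stage_counts
            ],
            "warnings": self.warnings,
        }


@dataclass
class NormalizedExpression:
    """-dCq relative expression (gene x sample; higher = more abundant)."""

    values: pd.DataFrame
    reference_genes: list[str]
    excluded: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.reference_genes:
            raise ValueError("reference gene list must be nonempty")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation of one gene against a second variable."""

    gene: str
    rho: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.rho) > 1 + 1e-12:
            raise ValueError("|rho| must not exceed 1")
        if self.n < 3:
            raise ValueError("need at least 3 paired observations")
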