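import numpy as np
import pandas as pd
import pytest

from refstab import SimConfig, null_panel, simulate_cell_lines, simulate_cohort
from refstab.data_model import ExpressionMatrix, ProbeGeneMap, SampleAnnotations
from refstab.screen import (
    CellLinePairing,
    ScreenConfig,
    covariate_correlation_filter,
    cv_rank,
    expression_floor_filter,
    group_association_filter,
    hypoxia_fold_filter,
    outcome_association_filter,
    run_screen,
)


def identity_map(genes):
    return ProbeGeneMap(pd.DataFrame({"probe": genes, "gene": genes}))


def test_hypoxia_fold_filter_threshold_semantics():
    m = ExpressionMatrix(
        pd.DataFrame(
            {
                "L1_N": [8.0, 8.0, 8.0],
                "L1_H": [8.7, 8.0 + np.log2(1.5), 8.0],
            },
            index=["up", "boundary", "flat"],
        )
    )
    pairs = CellLinePairing({"L1": ("L1_N", "L1_H")})
    excluded, max_fc = hypoxia_fold_filter(m, pairs)
    assert excluded == {"up"}  # 0.7 > log2(1.5) ~ 0.585
    assert "boundary" not in excluded  # exactly 1.5-fold: "more than" is strict
    assert max_fc["flat"] == 0.0


def test_hypoxia_fold_filter_checks_sample_ids():
    m = ExpressionMatrix(pd.DataFrame({"a": [1.0]}, index=["g"]))
    with pytest.raises(ValueError, match="absent"):
        hypoxia_fold_filter(m, CellLinePairing({"L1": ("a", "missing")}))


def test_covariate_filter_excludes_monotone_probe_keeps_constant_probe():
    cov = pd.Series(np.arange(10, dtype=float), index=[f"S{i}" for i in range(10)])
    m = ExpressionMatrix(
        pd.DataFrame(
            {s: [np.exp(cov[s] / 5), 3.0] for s in cov.index},
            index=["tracker", "flatliner"],
        )
    )
    excluded, min_p, warnings = covariate_correlation_filter(
        m, cov, identity_map(["tracker", "flatliner"])
    )
    assert excluded == {"tracker"}
    assert any("flatliner" in w for w in warnings)


def test_constant_covariate_warns_and_excludes_nothing(rng):
    cov = pd.Series(2.0, index=[f"S{i}" for i in range(8)])
    m = ExpressionMatrix(
        pd.DataFrame(rng.normal(8, 1, size=(2, 8)), index=["a", "b"], columns=cov.index)
    )
    excluded, _, warnings = covariate_correlation_filter(m, cov, identity_map(["a", "b"]))
    assert excluded == set()
    assert any("constant" in w for w in warnings)


def make_annotations(n, rng, events="mixed"):
    idx = pd.Index([f"S{i}" for i in range(n)], name="sample")
    if events == "none":
        event = ["censored"] * n
        time = rng.uniform(10, 60, size=n)
    else:
        event = rng.choice(["progression", "censored"], size=n, p=[0.45, 0.55])
        time = rng.uniform(5, 60, size=n)
    return SampleAnnotations(
        pd.DataFrame(
            {
                "stage_low_high": rng.choice(["low", "high"], size=n),
                "ln_status": rng.choice(["negative", "positive"], size=n),
                "tumor_volume": rng.lognormal(3.7, 0.8, size=n),
                "time_months": time,
                "event": event,
            },
            index=idx,
        ),
        group_names=["stage_low_high", "ln_status"],
        covariate_names=["tumor_volume"],
    )


def test_group_filter_keeps_constant_gene_excludes_shifted_gene(rng):
    ann = make_annotations(40, rng)
    samples = ann.sample_ids
    shifted = rng.normal(9, 0.3, size=40)
    shifted[(ann.group("ln_status") == "positive").to_numpy()] += 2.0
    m = ExpressionMatrix(
        pd.DataFrame(
            [np.full(40, 8.0), shifted], index=["flat", "shifted"], columns=samples
        )
    )
    excluded, min_p = group_association_filter(
        m, ann, identity_map(["flat", "shifted"]), continuous=()
    )
    assert "shifted" in excluded
    assert "flat" not in excluded


def test_outcome_filter_skips_without_events_and_catches_strong_effects(rng):
    ann_none = make_annotations(30, rng, events="none")
    m = ExpressionMatrix(
        pd.DataFrame(rng.normal(8, 1, size=(2, 30)), index=["a", "b"], columns=ann_none.sample_ids)
    )
    excluded, _, warnings = outcome_association_filter(m, ann_none, identity_map(["a", "b"]))
    assert excluded == set() and any("skipped" in w for w in warnings)

    # strong planted hazard link: simulate via the cohort generator
    cfg = SimConfig(seed=5, n_samples=150, n_abrix=None)
    cohort = simulate_cohort(cfg)
    excluded, _, _ = outcome_association_filter(
        cohort.array, cohort.annotations, cohort.probe_map
    )
    assert "STC2" in excluded  # hazard_beta = 0.6 planted


def test_expression_floor_strict_threshold():
    m = ExpressionMatrix(
        pd.DataFrame(
            {"S1": [6.8, 6.9, 7.3], "S2": [7.0, 7.1, 7.5]},
            index=["dim", "edge", "bright"],
        )
    )
    excluded, means = expression_floor_filter(m)
    assert excluded == {"dim"}
    assert means["edge"] == pytest.approx(7.0)  # boundary kept: strict '<'
    assert "bright" not in excluded


def test_cv_rank_hand_computed_values(rng):
    m = ExpressionMatrix(
        pd.DataFrame(
            {
                "S1": [8.0, 5.0, 12.0],
                "S2": [8.0, 5.0, 12.0],
                "S3": [12.0, 5.0, 12.0],
                "S4": [12.0, 5.0, 12.0],
            },
            index=["wobbly", "lowflat", "hiflat"],
        )
    )
    out = cv_rank(m, ["wobbly", "lowflat", "hiflat"])
    # (8,8,12,12): mean 10, sd sqrt(16/3) -> cv ~ 0.2309
    assert out.at["wobbly", "cv"] == pytest.approx(np.sqrt(16 / 3) / 10, abs=1e-9)
    assert out.at["lowflat", "cv"] == 0.0
    assert set(out["expression_bin"]) == {"low", "mid", "high"}
    # log2-scale CV is not scale-free: shifting the log values changes it
    shifted = ExpressionMatrix(m.values + 10.0)
    out2 = cv_rank(shifted, ["wobbly"])
    assert out2.at["wobbly", "cv"] == pytest.approx(np.sqrt(16 / 3) / 20, abs=1e-9)


def test_run_screen_flags_planted_violators_and_keeps_clean_genes():
    cfg = SimConfig(seed=8, n_samples=150, n_abrix=42)
    cohort = simulate_cohort(cfg)
    cl, pairs, _ = simulate_cell_lines(cfg)
    report = run_screen(
        list(cfg.genes), cohort.array, cl, pairs, cohort.annotations, cohort.probe_map
    )
    flags = report.per_gene
    # hypoxia-induced targets go out at the fold-change stage
    for g in ("DDIT3", "ERO1A", "STC2"):
        assert flags.at[g, "hypoxia_fold_excluded"]
    # covariate-linked candidates go out at the correlation stage
    for g in ("LASP1", "RPL27A"):
        assert not flags.at[g, "survivor"]
    # group-shifted candidates are caught by the association stage
    for g in ("RPS12", "SOD1"):
        assert flags.at[g, "group_assoc_excluded"]
    genes = [n for _, n, _ in report.stage_counts]
    assert genes == sorted(genes, reverse=True)  # non-increasing cascade


def test_run_screen_handles_unmeasured_candidate(cohort):
    cfg = SimConfig(seed=20)
    cl, pairs, _ = simulate_cell_lines(cfg)
    report = run_screen(
        ["CHCHD1", "GHOSTGENE"], cohort.array, cl, pairs, cohort.annotations, cohort.probe_map
    )
    assert report.per_gene.at["GHOSTGENE", "not_measured"]
    assert not report.per_gene.at["GHOSTGENE", "survivor"]
    assert any("GHOSTGENE" in w for w in report.warnings)


def test_screen_is_deterministic_and_order_independent():
    cfg = SimConfig(seed=13, n_samples=60, n_abrix=None, genes=null_panel(20, seed=4))
    cohort = simulate_cohort(cfg)
    cl, pairs, _ = simulate_cell_lines(cfg)
    args = (list(cfg.genes), cohort.array, cl, pairs, cohort.annotations, cohort.probe_map)
    r1, r2 = run_screen(*args), run_screen(*args)
    pd.testing.assert_frame_equal(r1.per_gene, r2.per_gene)
    # survivor set equals the intersection of per-filter keeps, so stage
    # order cannot change it: verify survivors match the flag union
    flags = r1.per_gene[
        [c for c in r1.per_gene.columns if c.endswith("_excluded") or c == "not_measured"]
    ]
    assert set(r1.survivors) == set(r1.per_gene.index[~flags.any(axis=1)])
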