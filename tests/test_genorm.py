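import numpy as np
import pandas as pd
import pytest

from refstab.genorm import (
    m_value,
    m_values,
    normalization_factor,
    pairwise_sd,
    pairwise_variation_series,
    select_optimal_set,
    stepwise_rank,
)
from .conftest import brute_m_values, brute_stepwise, random_log_matrix

TOY = pd.DataFrame(
    {"S1": [1.0, 2.0], "S2": [2.0, 4.0], "S3": [3.0, 3.0], "S4": [4.0, 5.0]},
    index=["GA", "GB"],
)


def test_pairwise_sd_hand_computed_toy():
    # ratios (log2 differences): (-1, -2, 0, -1) -> sd = sqrt(2/3)
    assert pairwise_sd(TOY, "GA", "GB") == pytest.approx(np.sqrt(2 / 3))


def test_pairwise_sd_of_identical_profiles_is_zero():
    m = pd.concat([TOY.loc[["GA"]], TOY.loc[["GA"]].set_index(pd.Index(["GC"]))])
    assert pairwise_sd(m, "GA", "GC") == 0.0


def test_pairwise_sd_shift_invariance():
    shifted = TOY.copy()
    shifted.loc["GB"] += 5.0
    assert pairwise_sd(shifted, "GA", "GB") == pytest.approx(pairwise_sd(TOY, "GA", "GB"))


def test_two_gene_m_values_both_equal_the_pairwise_sd():
    expect = pairwise_sd(TOY, "GA", "GB")
    assert m_value(TOY, "GA") == pytest.approx(expect)
    assert m_value(TOY, "GB") == pytest.approx(expect)


def test_identical_profiles_give_zero_m():
    m = pd.DataFrame(np.tile([5.0, 6.0, 7.0], (4, 1)), index=list("ABCD"))
    assert np.allclose(m_values(m), 0.0)


def test_m_values_match_bruteforce_on_random_matrix(rng):
    m = random_log_matrix(rng, 5, 12)
    brute = brute_m_values(m)
    ours = m_values(m)
    for g in m.index:
        assert ours[g] == pytest.approx(brute[g], abs=1e-12)


def test_stepwise_keeps_the_duplicated_gene_pair(rng):
    m = random_log_matrix(rng, 2, 10)
    m.loc["GA_copy"] = m.loc["GA"] + 1.0  # constant offset: still zero ratio variance
    m.loc["noisy"] = m.loc["GA"] + rng.normal(0, 2.0, size=m.shape[1])
    report = stepwise_rank(m)
    assert set(report.ranking[:2]) == {"GA", "GA_copy"}
    assert report.ranking[-1] == "noisy"


@pytest.mark.parametrize("seed", range(12))
def test_stepwise_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    m = random_log_matrix(rng, int(rng.integers(3, 9)), int(rng.integers(4, 21)))
    assert stepwise_rank(m).ranking == brute_stepwise(m)


def test_stepwise_trace_is_nested_and_records_removed_gene(rng):
    m = random_log_matrix(rng, 6, 15)
    report = stepwise_rank(m)
    assert len(report.trace) == 5  # 6 genes -> steps at 6,5,4,3 and the pair
    for step in report.trace[:-1]:
        assert step.removed in step.remaining
    assert report.trace[-1].removed is None
    assert len(report.trace[-1].remaining) == 2


def test_per_sample_offsets_leave_ranking_trace_and_v_unchanged(rng):
    m = random_log_matrix(rng, 6, 15)
    shifted = m + rng.normal(0, 3.0, size=m.shape[1])  # per-sample loading
    a, b = stepwise_rank(m), stepwise_rank(shifted)
    assert a.ranking == b.ranking
    for s, t in zip(a.trace, b.trace):
        assert s.remaining == t.remaining
        assert s.average_m == pytest.approx(t.average_m, abs=1e-9)
    for (n1, v1), (n2, v2) in zip(a.pairwise_variation, b.pairwise_variation):
        assert n1 == n2 and v1 == pytest.approx(v2, abs=1e-9)


def test_normalization_factor_trivial_cases(rng):
    m = random_log_matrix(rng, 3, 8)
    pd.testing.assert_series_equal(
        normalization_factor(["GA"], m), m.loc["GA"], check_names=False
    )
    m2 = m.copy()
    m2.loc["GB"] = m2.loc["GA"]  # duplicate gene: NF equals the gene itself
    pd.testing.assert_series_equal(
        normalization_factor(["GA", "GB"], m2), m2.loc["GA"], check_names=False
    )
    with pytest.raises(ValueError):
        normalization_factor([], m)


def fixed_ranking_report(ranking):
    from refstab.data_model import StabilityReport

    return StabilityReport(
        method="genorm", per_gene={g: 0.0 for g in ranking}, ranking=list(ranking)
    )


def test_v_is_zero_when_next_gene_equals_current_nf(rng):
    m = random_log_matrix(rng, 2, 10)
    m.loc["GC"] = normalization_factor(["GA", "GB"], m)  # GC cannot move the factor
    series = pairwise_variation_series(fixed_ranking_report(["GA", "GB", "GC"]), m)
    assert dict(series)[2] == pytest.approx(0.0, abs=1e-12)


def test_v_at_n2_matches_noise_closed_form():
    # gene 3 = NF_2 + noise of SD s  =>  V_2/3 = s / 3 (the new gene enters
    # the factor with weight 1/3).  Checked against a direct computation.
    rng = np.random.default_rng(1)
    n, s = 4000, 0.9
    noise = rng.normal(0, s, size=n)
    m = pd.DataFrame(rng.normal(0, 1.0, size=(2, n)), index=["GA", "GB"])
    m.loc["GC"] = m.mean(axis=0) + noise
    series = pairwise_variation_series(fixed_ranking_report(["GA", "GB", "GC"]), m)
    v2 = dict(series)[2]
    assert v2 == pytest.approx(np.std(noise, ddof=1) / 3, rel=1e-9)
    assert v2 == pytest.approx(s / 3, rel=0.05)


def test_monotone_noise_raises_m(rng):
    # as a gene's independent noise SD grows, its M must not decrease
    base = random_log_matrix(rng, 4, 40)
    noise = rng.normal(0, 1.0, size=base.shape[1])
    last = -1.0
    for sd in [0.0, 0.3, 0.6, 1.2]:
        m = base.copy()
        m.loc["GX"] = 8.0 + sd * noise
        current = m_value(m, "GX")
        assert current >= last - 1e-12
        last = current


@pytest.mark.parametrize(
    "series, expected_n",
    [
        ([(2, 0.20), (3, 0.12), (4, 0.10)], 3),
        ([(2, 0.05)], 2),
        ([(2, 0.149)], 2),  # strict '<' at the cutoff boundary
    ],
)
def test_select_optimal_set_cutoff_rule(series, expected_n):
    ranking = ["G1", "G2", "G3", "G4", "G5"][: max(n for n, _ in series) + 1]
    chosen = select_optimal_set(series, ranking)
    assert chosen.n == expected_n
    assert chosen.genes == ranking[:expected_n]
    assert not chosen.all_above_cutoff


def test_select_optimal_set_flags_when_no_v_below_cutoff():
    chosen = select_optimal_set([(2, 0.3), (3, 0.2)], ["G1", "G2", "G3", "G4"])
    assert chosen.all_above_cutoff
    assert chosen.genes == ["G1", "G2", "G3", "G4"]


def test_select_optimal_set_respects_minimum_panel_size():
    series = [(2, 0.05), (3, 0.10), (4, 0.20)]
    ranking = ["G1", "G2", "G3", "G4", "G5"]
    assert select_optimal_set(series, ranking, min_genes=2).n == 2
    assert select_optimal_set(series, ranking, min_genes=3).n == 3


def test_degenerate_two_gene_report_is_tied():
    report = stepwise_rank(TOY)
    assert report.ranking == ["GA", "GB"]
    assert report.per_gene["GA"] == report.per_gene["GB"]
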