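import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refstab.data_model import ExpressionMatrix, NormalizedExpression, SampleAnnotations
from refstab.validation import (
    cross_platform_correlation,
    export_survival_table,
    heterogeneity_concordance,
    hypoxia_association,
    tertile_split,
)


def make_ndcq(values_by_gene, samples):
    return NormalizedExpression(
        values=pd.DataFrame(values_by_gene, index=samples).T,
        reference_genes=["R1"],
    )


def test_cross_platform_rho_is_one_under_monotone_transform():
    samples = [f"S{i}" for i in range(8)]
    vals = np.linspace(-5, -1, 8)
    ndcq = make_ndcq({"STC2": vals}, samples)
    array = ExpressionMatrix(pd.DataFrame({"STC2": np.exp(vals)}, index=samples).T)
    (res,) = cross_platform_correlation(ndcq, array, ["STC2"])
    assert res.rho == pytest.approx(1.0)
    assert res.n == 8


def test_cross_platform_requires_five_shared_samples():
    samples = [f"S{i}" for i in range(4)]
    ndcq = make_ndcq({"STC2": [1.0, 2.0, 3.0, 4.0]}, samples)
    array = ExpressionMatrix(pd.DataFrame({"STC2": [1.0, 2.0, 3.0, 4.0]}, index=samples).T)
    with pytest.raises(ValueError, match="shared samples"):
        cross_platform_correlation(ndcq, array, ["STC2"])


def test_hypoxia_association_sign_convention():
    samples = [f"S{i}" for i in range(10)]
    expr = np.linspace(0, 3, 10)
    covariate = pd.Series(3.0 - expr, index=samples)  # high expression at low A_Brix
    ndcq = make_ndcq({"DDIT3": expr}, samples)
    (res,) = hypoxia_association(ndcq, covariate, ["DDIT3"])
    assert res.rho == pytest.approx(-1.0)


def test_constant_covariate_is_an_error():
    samples = [f"S{i}" for i in range(6)]
    ndcq = make_ndcq({"DDIT3": np.arange(6.0)}, samples)
    with pytest.raises(ValueError, match="constant"):
        hypoxia_association(ndcq, pd.Series(1.0, index=samples), ["DDIT3"])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_spearman_invariant_under_strictly_monotone_transforms(seed):
    rng = np.random.default_rng(seed)
    samples = [f"S{i}" for i in range(12)]
    x = rng.normal(size=12)
    y = rng.normal(size=12)
    ndcq = make_ndcq({"G": x}, samples)
    cov = pd.Series(y, index=samples)
    (base,) = hypoxia_association(ndcq, cov, ["G"])
    ndcq_t = make_ndcq({"G": np.exp(2 * x)}, samples)
    cov_t = pd.Series(y**3 + 5 * y, index=samples)  # strictly increasing
    (trans,) = hypoxia_association(ndcq_t, cov_t, ["G"])
    assert trans.rho == pytest.approx(base.rho, abs=1e-12)
    assert trans.p_value == pytest.approx(base.p_value, abs=1e-9)


def test_tertile_split_nine_distinct_values_gives_three_high():
    values = pd.Series(np.arange(9.0), index=[f"S{i}" for i in range(9)])
    labels = tertile_split(values)
    assert (labels == "high").sum() == 3
    assert set(labels.unique()) == {"high", "low"}


def test_tertile_split_all_equal_is_all_high():
    values = pd.Series(2.0, index=list("abcd"))
    assert (tertile_split(values) == "high").all()


def test_tertile_split_explicit_cut_boundary_is_high():
    values = pd.Series([-5.0, -4.46, -3.0], index=list("abc"))
    labels = tertile_split(values, cut=-4.46)
    assert labels["b"] == "high"  # value == cut -> high (">=")
    assert labels["a"] == "low" and labels["c"] == "high"


def test_tertile_split_explicit_cut_at_67th_percentile_matches_default(rng):
    values = pd.Series(rng.normal(size=30), index=[f"S{i}" for i in range(30)])
    cut = float(np.percentile(values, 67))
    pd.testing.assert_series_equal(tertile_split(values), tertile_split(values, cut=cut))


def test_concordance_identical_biopsies_is_perfect():
    values = pd.Series([1.0, 1.0, -2.0, -2.0], index=["T1B1", "T1B2", "T2B1", "T2B2"])
    tumors = pd.Series(["T1", "T1", "T2", "T2"], index=values.index)
    res = heterogeneity_concordance(values, tumors, cut=0.0)
    assert res.fraction_concordant == 1.0


def test_concordance_flags_straddling_tumor_and_ignores_singletons():
    values = pd.Series([1.0, -1.0, 2.0, 2.5, 9.9], index=["T1B1", "T1B2", "T2B1", "T2B2", "T3B1"])
    tumors = pd.Series(["T1", "T1", "T2", "T2", "T3"], index=values.index)
    res = heterogeneity_concordance(values, tumors, cut=0.0)
    assert not res.per_tumor["T1"]
    assert res.per_tumor["T2"]
    assert "T3" not in res.per_tumor.index  # single biopsy: uninformative
    assert res.fraction_concordant == 0.5


def test_concordance_is_invariant_to_biopsy_order(rng):
    values = pd.Series(rng.normal(size=9), index=[f"T{1 + i // 3}B{i % 3}" for i in range(9)])
    tumors = pd.Series([f"T{1 + i // 3}" for i in range(9)], index=values.index)
    res = heterogeneity_concordance(values, tumors, cut=0.2)
    perm = rng.permutation(9)
    res_p = heterogeneity_concordance(values.iloc[perm], tumors.iloc[perm], cut=0.2)
    assert res.fraction_concordant == res_p.fraction_concordant


def test_concordance_matches_direct_enumeration_on_simulated_tumors():
    from refstab import SimConfig, simulate_heterogeneity
    from refstab.qc import collapse_replicates, delta_cq

    cq, tumor_ids, _ = simulate_heterogeneity(SimConfig(seed=2))
    ndcq = delta_cq(collapse_replicates(cq), ["CHCHD1", "SRSF9", "TMBIM6"])
    values = ndcq.values.loc["STC2"]
    cut = float(np.percentile(values.dropna(), 67))
    res = heterogeneity_concordance(values, tumor_ids, cut)
    # independent enumeration
    expected = []
    for tumor in sorted(tumor_ids.unique()):
        biopsies = [b for b in values.index if tumor_ids.get(b) == tumor]
        if len(biopsies) < 2:
            continue
        sides = {values[b] >= cut for b in biopsies}
        expected.append(len(sides) == 1)
    assert res.fraction_concordant == pytest.approx(np.mean(expected))


def test_export_survival_table_schema(cohort):
    labels = tertile_split(cohort.annotations.covariate("tumor_volume"))
    table = export_survival_table(labels, cohort.annotations)
    assert list(table.columns) == ["sample", "group", "time_months", "event"]
    assert set(table["event"]).issubset({"progression", "competing_death", "censored"})
    assert len(table) == len(cohort.annotations.sample_ids)
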