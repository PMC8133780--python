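"""Two-group tests, the lineage filter and cross-stratum correlation."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_table
from purinedelta import (SimulationDesign, cross_stratum_correlation, diff_test,
                         lineage_specific, simulate_intensity_table)


def test_identical_groups_give_zero_fc_and_p_one():
    t = make_table([[1.0, 1.0, 1.0, 1.0, 1.0, 1.0]], ["A"] * 3 + ["B"] * 3)
    res = diff_test(t, "A", "B")
    assert res.loc[0, "log_fc"] == 0.0
    assert res.loc[0, "p_value"] == 1.0
    assert res.loc[0, "direction"] == "none"


def test_t_oracle_hand_computed():
    """Closed-form Welch t on A={2,2.1,1.9}, B={1,1.1,0.9}."""
    a = np.array([2.0, 2.1, 1.9])
    b = np.array([1.0, 1.1, 0.9])
    t = make_table(np.concatenate([a, b])[None, :], ["A"] * 3 + ["B"] * 3)
    res = diff_test(t, "A", "B")
    # independent route: textbook formulas, not the package's code path
    se2 = a.var(ddof=1) / 3 + b.var(ddof=1) / 3
    t_stat = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((a.var(ddof=1) / 3) ** 2 / 2 + (b.var(ddof=1) / 3) ** 2 / 2)
    p_expected = 2 * stats.t.sf(abs(t_stat), df)
    assert res.loc[0, "log_fc"] == pytest.approx(1.0)
    assert res.loc[0, "p_value"] == pytest.approx(p_expected, rel=1e-12)
    assert res.loc[0, "n_a"] == 3 and res.loc[0, "n_b"] == 3


def test_t_matches_scipy_with_missingness():
    rng = np.random.default_rng(12)
    values = rng.normal(3, 0.3, size=(50, 16))
    values[rng.random(values.shape) < 0.2] = np.nan
    t = make_table(values, ["A"] * 8 + ["B"] * 8)
    res = diff_test(t, "A", "B").set_index("metabolite_id")
    for m in res.index:
        row = t.values.loc[m]
        a = row.iloc[:8].dropna()
        b = row.iloc[8:].dropna()
        p_ref = stats.ttest_ind(a, b, equal_var=False).pvalue
        assert res.loc[m, "p_value"] == pytest.approx(p_ref, rel=1e-10)


def test_wilcoxon_matches_exact_enumeration():
    """Most extreme split {1,2,3} vs {4,5,6}: enumerate all 20 assignments."""
    pooled = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    t = make_table(np.array(pooled)[None, :], ["A"] * 3 + ["B"] * 3)
    res = diff_test(t, "A", "B", test="wilcoxon")
    # enumeration oracle: distribution of the rank-sum of group A
    obs = sum(sorted(pooled).index(v) + 1 for v in pooled[:3])
    sums = [sum(idx) + 3 for idx in combinations(range(6), 3)]
    mu = np.mean(sums)
    p_exact = np.mean([abs(s - mu) >= abs(obs - mu) for s in sums])
    assert p_exact == pytest.approx(0.1)
    assert res.loc[0, "p_value"] == pytest.approx(p_exact, abs=1e-12)


def test_relabel_antisymmetry(two_group_table):
    ab = diff_test(two_group_table, "A", "B")
    ba = diff_test(two_group_table, "B", "A")
    assert np.allclose(ab["log_fc"], -ba["log_fc"])
    assert np.allclose(ab["p_value"], ba["p_value"])


def test_sample_order_invariance(two_group_table):
    shuffled = two_group_table.subset_samples(two_group_table.sample_ids[::-1])
    pd.testing.assert_frame_equal(diff_test(two_group_table, "A", "B"),
                                  diff_test(shuffled, "A", "B"))


def test_bh_adjustment_monotone_and_gates_direction():
    rng = np.random.default_rng(3)
    values = rng.normal(3, 0.3, size=(100, 12))
    values[:10, 6:] += 1.0
    t = make_table(values, ["A"] * 6 + ["B"] * 6)
    res = diff_test(t, "A", "B", adjust="BH")
    # monotone: ordering by p preserves ordering of adj_p
    by_p = res.sort_values("p_value")["adj_p"].to_numpy()
    assert (np.diff(by_p) >= -1e-15).all()
    # direction assigned from adj_p when BH requested
    sig = res["direction"] != "none"
    assert (res.loc[sig, "adj_p"] < 0.05).all()
    assert (res.loc[~sig, "adj_p"] >= 0.05).all()


def test_min_group_n_skips_metabolite():
    values = np.ones((2, 6)) * 3.0
    values[0, 0] = np.nan  # only 2 observed in group A for m0001
    t = make_table(values, ["A"] * 3 + ["B"] * 3)
    res = diff_test(t, "A", "B", min_group_n=3)
    assert list(res["metabolite_id"]) == ["m0002"]


def test_unknown_group_rejected(two_group_table):
    with pytest.raises(KeyError):
        diff_test(two_group_table, "A", "Z")


def test_type_i_error_calibrated():
    design = SimulationDesign(groups=[("a", 10), ("b", 10)],
                              n_metabolites=2000, seed=17)
    table, _ = simulate_intensity_table(design)
    res = diff_test(table, "a", "b")
    rate = float((res["p_value"] < 0.05).mean())
    assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 2000)


# -- lineage filter ----------------------------------------------------------

def test_direction_mismatch_is_not_focal_specific():
    rng = np.random.default_rng(5)
    base = rng.normal(0, 0.05, size=(1, 30))
    values = base.repeat(1, axis=0).copy()
    values[0, :10] += 0.0  # focal
    values[0, 10:20] -= 2.0  # out1: focal >> out1 (up)
    values[0, 20:] += 2.0  # out2: focal << out2 (down)
    t = make_table(values, ["H"] * 10 + ["C"] * 10 + ["M"] * 10)
    calls = lineage_specific(t, "H", "C", "M")
    assert not calls.loc[0, "is_focal_specific"]


def test_planted_focal_shift_called():
    """Focal group shifted by 0.5 log10; outgroups identical, n=10/group.

    The expected call rate is capped at 0.95 by the requirement that the
    (null) outgroup comparison be non-significant at alpha=0.05."""
    rng = np.random.default_rng(6)
    m = 300
    values = rng.normal(3, 0.2, size=(m, 30))
    values[:, :10] += 0.5
    t = make_table(values, ["H"] * 10 + ["C"] * 10 + ["M"] * 10)
    calls = lineage_specific(t, "H", "C", "M")
    assert calls["is_focal_specific"].mean() > 0.90


def test_null_focal_specific_rate_is_small_but_exceeds_independence():
    """Null three-group data: the focal-specific rate reflects the
    correlation (rho=0.5) between the two focal contrasts, staying far
    below alpha yet not below alpha^2."""
    rng = np.random.default_rng(7)
    values = rng.normal(3, 0.2, size=(4000, 30))
    t = make_table(values, ["H"] * 10 + ["C"] * 10 + ["M"] * 10)
    calls = lineage_specific(t, "H", "C", "M")
    rate = calls["is_focal_specific"].mean()
    assert rate < 0.02


def test_overlapping_labels_rejected(two_group_table):
    with pytest.raises(ValueError):
        lineage_specific(two_group_table, "A", "A", "B")


# -- cross-stratum correlation ----------------------------------------------

def _diffs(metabolites, log_fc):
    return pd.DataFrame({"metabolite_id": metabolites, "log_fc": log_fc,
                         "p_value": 0.5, "adj_p": np.nan, "direction": "none",
                         "n_a": 5, "n_b": 5})


def test_correlation_identity_and_antisymmetry():
    ids = [f"m{i}" for i in range(10)]
    fc = np.linspace(-1, 1, 10)
    r, p, n = cross_stratum_correlation(_diffs(ids, fc), _diffs(ids, fc))
    assert r == pytest.approx(1.0)
    assert n == 10
    r2, _, _ = cross_stratum_correlation(_diffs(ids, fc), _diffs(ids, -fc))
    assert r2 == pytest.approx(-1.0)


def test_correlation_uses_intersection_and_needs_three():
    a = _diffs(["m1", "m2", "m3", "m4"], [0.1, 0.2, 0.3, 0.4])
    b = _diffs(["m2", "m3", "m4", "m5"], [0.2, 0.1, 0.4, 0.9])
    _, _, n = cross_stratum_correlation(a, b)
    assert n == 3
    with pytest.raises(ValueError):
        cross_stratum_correlation(_diffs(["m1", "m2"], [0.1, 0.2]),
                                  _diffs(["m1", "m2"], [0.1, 0.2]))


def test_correlation_matches_analytic_attenuation():
    """Two strata sharing true effects: expected r = tau^2/(tau^2 + 2*sd^2/n)."""
    rng = np.random.default_rng(8)
    m, n, sd, tau = 400, 10, 0.2, 0.3
    delta = rng.normal(0, tau, size=m)
    ids = [f"m{i:04d}" for i in range(m)]
    out = []
    for stratum_seed in (1, 2):
        srng = np.random.default_rng(stratum_seed)
        values = srng.normal(3, sd, size=(m, 2 * n))
        values[:, n:] += delta[:, None]
        t = make_table(values, ["wt"] * n + ["hum"] * n)
        out.append(diff_test(t, "hum", "wt"))
    r, p, n_common = cross_stratum_correlation(out[0], out[1])
    expected = tau ** 2 / (tau ** 2 + 2 * sd ** 2 / n)
    assert n_common == m
    assert r == pytest.approx(expected, abs=0.05)
    assert p < 1e-10
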