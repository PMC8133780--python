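"""Normalization, filtering, outlier and run-order QC."""

import numpy as np
import pytest

from conftest import make_table
from purinedelta import (SimulationDesign, detect_outlier_samples,
                         filter_missingness, flag_run_order_confounded,
                         normalize_internal_standard, simulate_intensity_table,
                         upper_quartile_normalize)


# -- internal standard -------------------------------------------------------

def test_internal_standard_hand_value():
    # value 2.0 over standard 1.0 scaled by 3000 → log10(6000)
    t = make_table([[2.0, 4.0], [1.0, 2.0]], ["A", "B"], scale="linear")
    out = normalize_internal_standard(t, "m0002", scale_factor=3000.0)
    assert out.scale == "log10"
    assert "m0002" not in out.metabolite_ids
    assert out.values.loc["m0001"].to_numpy() == pytest.approx(
        [np.log10(6000.0), np.log10(6000.0)])


def test_internal_standard_identity_when_equal():
    t = make_table([[5.0, 7.0], [5.0, 7.0]], ["A", "B"], scale="linear")
    out = normalize_internal_standard(t, "m0002", scale_factor=1.0)
    assert np.allclose(out.values.loc["m0001"], 0.0)


def test_internal_standard_default_factor_is_3000():
    import inspect
    sig = inspect.signature(normalize_internal_standard)
    assert sig.parameters["scale_factor"].default == 3000.0


def test_internal_standard_missing_names_sample():
    t = make_table([[2.0, 4.0], [1.0, np.nan]], ["A", "B"], scale="linear")
    with pytest.raises(ValueError, match="s02"):
        normalize_internal_standard(t, "m0002")


def test_internal_standard_zero_rejected():
    t = make_table([[2.0, 4.0], [1.0, 0.0]], ["A", "B"], scale="linear")
    with pytest.raises(ValueError):
        normalize_internal_standard(t, "m0002")


def test_internal_standard_requires_linear_scale():
    t = make_table([[2.0, 4.0], [1.0, 2.0]], ["A", "B"], scale="log10")
    with pytest.raises(ValueError):
        normalize_internal_standard(t, "m0002")


# -- missingness filter ------------------------------------------------------

def _eight_sample_table(n_missing_first_row):
    values = np.ones((2, 8)) * 3.0
    values[0, :n_missing_first_row] = np.nan
    return make_table(values, ["A"] * 4 + ["B"] * 4)


def test_half_missing_is_removed():
    out = filter_missingness(_eight_sample_table(4), 0.5)
    assert out.metabolite_ids == ["m0002"]


def test_below_threshold_retained():
    out = filter_missingness(_eight_sample_table(3), 0.5)
    assert set(out.metabolite_ids) == {"m0001", "m0002"}


def test_threshold_one_drops_only_all_missing():
    values = np.ones((3, 8)) * 3.0
    values[0, :] = np.nan
    values[1, :7] = np.nan
    out = filter_missingness(make_table(values, ["A"] * 4 + ["B"] * 4), 1.0)
    assert set(out.metabolite_ids) == {"m0002", "m0003"}


def test_stratified_filter_keeps_metabolite_detected_in_one_stratum():
    values = np.ones((1, 8)) * 3.0
    values[0, :4] = np.nan  # fully missing in tissue X, complete in Y
    t = make_table(values, ["A", "A", "B", "B"] * 2,
                   tissue=["X"] * 4 + ["Y"] * 4)
    assert filter_missingness(t, 0.5, stratify_by="tissue").n_metabolites == 1
    with pytest.warns(UserWarning):
        assert filter_missingness(t, 0.5).n_metabolites == 0


def test_empty_result_warns_not_raises():
    values = np.full((1, 8), np.nan)
    t = make_table(values, ["A"] * 4 + ["B"] * 4)
    with pytest.warns(UserWarning):
        out = filter_missingness(t, 0.5)
    assert out.n_metabolites == 0


# -- upper-quartile normalization -------------------------------------------

def test_uq_definition():
    t = make_table(np.array([[1.0], [2.0], [3.0], [4.0]]), ["A"])
    out = upper_quartile_normalize(t)
    assert float(out.values.quantile(0.75, axis=0).iloc[0]) == pytest.approx(0.0)


def test_uq_offset_invariance():
    rng = np.random.default_rng(0)
    col = rng.normal(3, 0.5, size=10)
    t = make_table(np.column_stack([col, col + 1.7]), ["A", "B"])
    out = upper_quartile_normalize(t)
    assert np.allclose(out.values.iloc[:, 0], out.values.iloc[:, 1])


def test_uq_all_equal_sample_becomes_zero():
    t = make_table(np.full((5, 1), 2.5), ["A"])
    assert np.allclose(upper_quartile_normalize(t).values, 0.0)


def test_uq_idempotent_and_mask_preserved():
    rng = np.random.default_rng(1)
    values = rng.normal(3, 0.5, size=(20, 6))
    values[rng.random(values.shape) < 0.2] = np.nan
    t = make_table(values, ["A"] * 3 + ["B"] * 3)
    once = upper_quartile_normalize(t)
    twice = upper_quartile_normalize(once)
    assert np.allclose(once.values, twice.values, equal_nan=True)
    assert once.missing_mask.equals(t.missing_mask)


def test_uq_rejects_linear_scale_and_starved_samples():
    with pytest.raises(ValueError):
        upper_quartile_normalize(make_table(np.ones((5, 2)), ["A", "B"],
                                            scale="linear"))
    values = np.full((5, 2), 3.0)
    values[2:, 1] = np.nan  # second sample has only 2 detected
    with pytest.raises(ValueError, match="s02"):
        upper_quartile_normalize(make_table(values, ["A", "B"]))


def test_uq_commutes_with_sample_reordering():
    rng = np.random.default_rng(4)
    t = make_table(rng.normal(3, 0.5, size=(10, 6)), ["A"] * 3 + ["B"] * 3)
    reordered = t.subset_samples(t.sample_ids[::-1])
    a = upper_quartile_normalize(t).values
    b = upper_quartile_normalize(reordered).values
    assert np.allclose(a, b[a.columns])


# -- PCA outlier detection ---------------------------------------------------

def test_planted_outlier_detected():
    design = SimulationDesign(groups=[("a", 8), ("b", 8)], n_metabolites=100,
                              n_outliers=1, outlier_shift_sd=5.0, seed=21)
    table, truth = simulate_intensity_table(design)
    found = detect_outlier_samples(table, sd_threshold=3.0)
    assert truth.outlier_samples <= found
    assert len(found) <= 2


def test_homogeneous_table_has_no_outliers():
    design = SimulationDesign(groups=[("a", 10), ("b", 10)], n_metabolites=100,
                              seed=22)
    table, _ = simulate_intensity_table(design)
    assert detect_outlier_samples(table, sd_threshold=3.0) == set()


def test_infinite_threshold_returns_empty():
    design = SimulationDesign(groups=[("a", 5), ("b", 5)], n_metabolites=50,
                              n_outliers=2, seed=23)
    table, _ = simulate_intensity_table(design)
    assert detect_outlier_samples(table, sd_threshold=np.inf) == set()


def test_too_few_samples_rejected():
    t = make_table(np.ones((5, 3)), ["A", "A", "B"])
    with pytest.raises(ValueError):
        detect_outlier_samples(t)


def test_impute_mode_handles_missing():
    design = SimulationDesign(groups=[("a", 8), ("b", 8)], n_metabolites=60,
                              dropout_rate=0.3, n_outliers=1,
                              outlier_shift_sd=6.0, seed=24)
    table, truth = simulate_intensity_table(design)
    found = detect_outlier_samples(table, sd_threshold=3.0, missing="impute")
    assert truth.outlier_samples <= found


# -- run-order confounding ---------------------------------------------------

def _run_order_table(signals):
    n = signals.shape[1]
    return make_table(signals, ["A"] * (n // 2) + ["B"] * (n - n // 2),
                      run_order=list(range(n)))


def test_pure_sinusoid_flagged():
    order = np.arange(50)
    wave = np.sin(2 * np.pi * order / 50)
    t = _run_order_table(wave[None, :] + 3.0)
    assert flag_run_order_confounded(t, r2_threshold=0.3) == {"m0001"}


def test_white_noise_not_flagged():
    rng = np.random.default_rng(31)
    t = _run_order_table(rng.normal(3, 0.3, size=(40, 50)))
    flagged = flag_run_order_confounded(t, r2_threshold=0.3)
    assert len(flagged) <= 2  # null flagging is rare


def test_constant_metabolite_not_flagged():
    t = _run_order_table(np.full((1, 50), 3.0))
    assert flag_run_order_confounded(t, r2_threshold=0.3) == set()


def test_missing_run_order_rejected():
    t = make_table(np.ones((2, 6)), ["A"] * 3 + ["B"] * 3)
    with pytest.raises(ValueError):
        flag_run_order_confounded(t)
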