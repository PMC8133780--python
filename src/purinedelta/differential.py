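"""Per-metabolite two-group statistics and the lineage-specific filter.

The fold change of a metabolite between groups A and B is the difference
of mean log intensities over the observed (non-missing) values, so it is
a log fold change on whatever log base the table carries.  P-values come
from a two-sided two-sample t-test (Welch by default) or the rank-sum
(Mann–Whitney/Wilcoxon) test; Benjamini–Hochberg adjustment is optional
and applied across all metabolites tested in the stratum.

A metabolite is *lineage specific* for a focal group when it differs
significantly, in the same direction, from both outgroups while the two
outgroups do not differ from each other — the three-way filter used to
call metabolite changes unique to one species.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import IntensityTable

logger = logging.getLogger(__name__)

DIFF_COLUMNS = ["metabolite_id", "log_fc", "p_value", "adj_p", "direction",
                "n_a", "n_b"]


def _two_sample_t(A: np.ndarray, B: np.ndarray, equal_var: bool):
    """Row-wise two-sided t-test on matrices with NaN as missing.

    Returns (log_fc, p, n_a, n_b).  Degenerate rows (both groups constant)
    get p = 1 when the means agree and p = 0 when they differ.
    """
    n_a = np.sum(~np.isnan(A), axis=1)
    n_b = np.sum(~np.isnan(B), axis=1)
    with np.errstate(all="ignore"):
        mean_a = np.nanmean(A, axis=1)
        mean_b = np.nanmean(B, axis=1)
        var_a = np.nanvar(A, axis=1, ddof=1)
        var_b = np.nanvar(B, axis=1, ddof=1)
    log_fc = mean_a - mean_b
    with np.errstate(all="ignore"):
        if equal_var:
            df = n_a + n_b - 2
            sp2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df
            se2 = sp2 * (1.0 / n_a + 1.0 / n_b)
        else:
            va, vb = var_a / n_a, var_b / n_b
            se2 = va + vb
            df = se2 ** 2 / (va ** 2 / (n_a - 1) + vb ** 2 / (n_b - 1))
        t = log_fc / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0
    p = np.where(degenerate, np.where(log_fc == 0, 1.0, 0.0), p)
    p = np.where(np.isnan(p) & (log_fc == 0), 1.0, p)
    return log_fc, p, n_a, n_b


def _rank_sum_rows(A: np.ndarray, B: np.ndarray):
    """Row-wise two-sided rank-sum test (exact where scipy chooses it)."""
    out = np.empty(A.shape[0])
    for i in range(A.shape[0]):
        a = A[i][~np.isnan(A[i])]
        b = B[i][~np.isnan(B[i])]
        if np.ptp(np.concatenate([a, b])) == 0:
            out[i] = 1.0
            continue
        out[i] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    return out


def diff_test(table: IntensityTable, group_a: str, group_b: str,
              test: str = "t", alpha: float = 0.05, adjust: str = "none",
              min_group_n: int = 3, equal_var: bool = False) -> pd.DataFrame:
    """Two-group differential test for every eligible metabolite.

    Returns a DataFrame with columns ``metabolite_id, log_fc, p_value,
    adj_p, direction, n_a, n_b``; ``log_fc`` is mean(log A) − mean(log B)
    over observed values.  Metabolites with fewer than ``min_group_n``
    observed values in either group are skipped (logged).  ``direction``
    is ``up``/``down`` by the sign of ``log_fc`` when the metabolite
    passes ``alpha`` (on ``adj_p`` when BH adjustment was requested),
    else ``none``.
    """
    if table.scale == "linear":
        raise ValueError("differential testing expects a log-scale table")
    if test not in ("t", "wilcoxon"):
        raise ValueError("test must be 't' or 'wilcoxon'")
    if adjust not in ("none", "BH"):
        raise ValueError("adjust must be 'none' or 'BH'")
    if group_a == group_b:
        raise ValueError("group labels must differ")
    ids_a = table.group_samples(group_a)
    ids_b = table.group_samples(group_b)
    A = table.values[ids_a].to_numpy()
    B = table.values[ids_b].to_numpy()

    n_a = np.sum(~np.isnan(A), axis=1)
    n_b = np.sum(~np.isnan(B), axis=1)
    eligible = (n_a >= min_group_n) & (n_b >= min_group_n)
    skipped = np.asarray(table.metabolite_ids)[~eligible]
    for m in skipped:
        logger.debug("diff_test skipped %s: fewer than %d observed per group",
                     m, min_group_n)

    A, B = A[eligible], B[eligible]
    log_fc, p, na, nb = _two_sample_t(A, B, equal_var=equal_var)
    if test == "wilcoxon":
        p = _rank_sum_rows(A, B)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    res = pd.DataFrame({
        "metabolite_id": np.asarray(table.metabolite_ids)[eligible],
        "log_fc": log_fc,
        "p_value": p,
        "adj_p": np.nan,
        "direction": "none",
        "n_a": na.astype(int),
        "n_b": nb.astype(int),
    })
    if adjust == "BH" and len(res):
        res["adj_p"] = multipletests(res["p_value"], method="fdr_bh")[1]
        crit = res["adj_p"]
    else:
        crit = res["p_value"]
    sig = crit < alpha
    res.loc[sig & (res["log_fc"] > 0), "direction"] = "up"
    res.loc[sig & (res["log_fc"] < 0), "direction"] = "down"
    return res.reset_index(drop=True)


def lineage_specific(table: IntensityTable, focal: str, out1: str, out2: str,
                     alpha: float = 0.05, test: str = "t",
                     min_group_n: int = 3, adjust: str = "none") -> pd.DataFrame:
    """Three-way filter for metabolites changed only on the focal lineage.

    A metabolite is called focal-specific when focal-vs-out1 and
    focal-vs-out2 are both significant at ``alpha`` with the same sign of
    log fold change while out1-vs-out2 is not significant.  Returns one
    row per metabolite testable in all three contrasts with the three
    p-values, fold changes and the boolean call.
    """
    labels = [focal, out1, out2]
    if len(set(labels)) != 3:
        raise ValueError("focal and outgroup labels must be distinct")
    kw = dict(test=test, alpha=alpha, adjust=adjust, min_group_n=min_group_n)
    d1 = diff_test(table, focal, out1, **kw).set_index("metabolite_id")
    d2 = diff_test(table, focal, out2, **kw).set_index("metabolite_id")
    d3 = diff_test(table, out1, out2, **kw).set_index("metabolite_id")
    common = d1.index.intersection(d2.index).intersection(d3.index)
    d1, d2, d3 = d1.loc[common], d2.loc[common], d3.loc[common]
    crit = "adj_p" if adjust == "BH" else "p_value"
    call = ((d1[crit] < alpha) & (d2[crit] < alpha)
            & (np.sign(d1["log_fc"]) == np.sign(d2["log_fc"]))
            & (d1["log_fc"] != 0)
            & (d3[crit] >= alpha))
    return pd.DataFrame({
        "metabolite_id": common,
        "log_fc_focal_out1": d1["log_fc"].to_numpy(),
        "p_focal_out1": d1[crit].to_numpy(),
        "log_fc_focal_out2": d2["log_fc"].to_numpy(),
        "p_focal_out2": d2[crit].to_numpy(),
        "log_fc_out1_out2": d3["log_fc"].to_numpy(),
        "p_out1_out2": d3[crit].to_numpy(),
        "is_focal_specific": call.to_numpy(),
    }).reset_index(drop=True)


def cross_stratum_correlation(diffs_a: pd.DataFrame, diffs_b: pd.DataFrame):
    """Pearson correlation of log fold changes across two strata.

    Pairs metabolites present in both result tables and correlates their
    log fold changes; returns ``(r, p, n)`` with a two-sided p-value.
    """
    a = diffs_a.set_index("metabolite_id")["log_fc"]
    b = diffs_b.set_index("metabolite_id")["log_fc"]
    common = a.index.intersection(b.index)
    n = len(common)
    if n < 3:
        raise ValueError(f"only {n} shared metabolites; need at least 3")
    r, p = stats.pearsonr(a.loc[common], b.loc[common])
    return float(r), float(p), int(n)
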