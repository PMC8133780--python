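"""Label-shuffling null for the count of significantly different metabolites.

A single t-test per metabolite says little when hundreds of metabolites
are screened; the quantity of interest is whether the *number* of
nominally significant metabolites exceeds what label noise alone
produces.  Group labels are shuffled (preserving group sizes), the count
of metabolites with inner-test p below the nominal cutoff is recomputed
for each shuffle, and the permutation p-value is the add-one ratio of
shuffles reaching the observed count:

    p = (1 + #{null counts >= observed}) / (1 + B)

which never returns an exact zero.  When the design admits fewer
distinct label assignments than requested, the null is enumerated
exhaustively instead of sampled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

from .tables import IntensityTable

DEFAULT_B = 1000


@dataclass
class PermutationResult:
    observed_count: int
    null_counts: np.ndarray
    p_value: float
    alpha_inner: float
    B: int
    seed: int
    exhaustive: bool = False
    n_metabolites_tested: int = 0
    group_sizes: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.null_counts = np.asarray(self.null_counts, dtype=int)
        if len(self.null_counts) != self.B:
            raise ValueError("null_counts length must equal B")


def _count_significant(values: np.ndarray, mask: np.ndarray,
                       in_a: np.ndarray, alpha: float, min_group_n: int,
                       equal_var: bool) -> np.ndarray:
    """Significant-metabolite count per label assignment.

    ``in_a`` is an (n_samples × B) boolean matrix of group-A membership;
    the Welch (or pooled) t statistic is computed for every metabolite ×
    assignment pair with missing values handled by pairwise deletion.
    Metabolites falling below ``min_group_n`` observed values in either
    group under a given assignment contribute p = 1 for that assignment.
    """
    V = np.where(mask, 0.0, values)  # zero-filled values
    V2 = V * V
    O = (~mask).astype(float)  # observed indicator
    in_a = in_a.astype(float)
    in_b = 1.0 - in_a

    def moments(G):
        n = O @ G
        s = V @ G
        s2 = V2 @ G
        with np.errstate(all="ignore"):
            mean = s / n
            var = (s2 - n * mean ** 2) / (n - 1)
        return n, mean, np.maximum(var, 0.0)

    na, ma, va = moments(in_a)
    nb, mb, vb = moments(in_b)
    with np.errstate(all="ignore"):
        if equal_var:
            df = na + nb - 2
            sp2 = ((na - 1) * va + (nb - 1) * vb) / df
            se2 = sp2 * (1 / na + 1 / nb)
        else:
            ua, ub = va / na, vb / nb
            se2 = ua + ub
            df = se2 ** 2 / (ua ** 2 / (na - 1) + ub ** 2 / (nb - 1))
        t = (ma - mb) / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    diff = ma - mb
    p = np.where(se2 == 0, np.where(diff == 0, 1.0, 0.0), p)
    p = np.where(np.isnan(p), 1.0, p)
    p = np.where((na < min_group_n) | (nb < min_group_n), 1.0, p)
    return (p < alpha).sum(axis=0)


def permutation_count_test(table: IntensityTable, group_a: str, group_b: str,
                           alpha_inner: float = 0.05, B: int = DEFAULT_B,
                           seed: int = 0, min_group_n: int = 3,
                           equal_var: bool = False) -> PermutationResult:
    """Permutation test on the number of significant metabolites.

    The eligible metabolite set (>= ``min_group_n`` observed per group
    under the true labels) is fixed before shuffling and reused for every
    permutation.  Samples are canonicalised by sorting on sample id, so
    the result is invariant to the input sample order for a fixed seed.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    if not 0 < alpha_inner < 1:
        raise ValueError("alpha_inner must lie in (0, 1)")
    if table.scale == "linear":
        raise ValueError("permutation testing expects a log-scale table")
    ids_a = sorted(table.group_samples(group_a))
    ids_b = sorted(table.group_samples(group_b))
    n_a, n = len(ids_a), len(ids_a) + len(ids_b)
    sub = table.values[ids_a + ids_b]
    values = sub.to_numpy()
    mask = np.isnan(values)

    obs_a = np.sum(~mask[:, :n_a], axis=1)
    obs_b = np.sum(~mask[:, n_a:], axis=1)
    eligible = (obs_a >= min_group_n) & (obs_b >= min_group_n)
    values, mask = values[eligible], mask[eligible]
    if values.shape[0] == 0:
        raise ValueError("no metabolite testable under the true labels")

    true_in_a = np.zeros((n, 1), dtype=bool)
    true_in_a[:n_a, 0] = True
    observed = int(_count_significant(values, mask, true_in_a, alpha_inner,
                                      min_group_n, equal_var)[0])

    n_assignments = comb(n, n_a)
    exhaustive = n_assignments <= B
    if exhaustive:
        if n_assignments < B:
            warnings.warn(
                f"only {n_assignments} distinct label assignments; "
                f"enumerating exhaustively instead of sampling B={B}")
        B = n_assignments
        in_a = np.zeros((n, B), dtype=bool)
        for j, idx in enumerate(combinations(range(n), n_a)):
            in_a[list(idx), j] = True
    else:
        rng = np.random.default_rng(seed)
        keys = rng.random((B, n))
        order = np.argsort(keys, axis=1)
        in_a = np.zeros((n, B), dtype=bool)
        rows = order[:, :n_a]
        in_a[rows.ravel(), np.repeat(np.arange(B), n_a)] = True

    null_counts = _count_significant(values, mask, in_a, alpha_inner,
                                     min_group_n, equal_var)
    if exhaustive:
        p_value = float(np.sum(null_counts >= observed)) / B
    else:
        p_value = (1.0 + float(np.sum(null_counts >= observed))) / (1.0 + B)
    return PermutationResult(
        observed_count=observed, null_counts=null_counts, p_value=p_value,
        alpha_inner=alpha_inner, B=B, seed=seed, exhaustive=exhaustive,
        n_metabolites_tested=int(values.shape[0]),
        group_sizes=(n_a, n - n_a),
    )
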