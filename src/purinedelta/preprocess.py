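"""Normalization, filtering and quality-control steps for intensity tables.

The sequence mirrors the standard handling of quantified MS metabolite
tables: ratio to an internal standard and log10 transform, removal of
metabolites detected in fewer than half the samples, per-sample
upper-quartile normalization, PCA-based outlier-sample detection, and
flagging of metabolites confounded by instrument run order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.svm import SVR

from .tables import IntensityTable

logger = logging.getLogger(__name__)

#: default linear-scale multiplier applied before log10 so that
#: metabolite/standard ratios stay positive after the transform
DEFAULT_SCALE_FACTOR = 3000.0


def normalize_internal_standard(table: IntensityTable, standard_id: str,
                                scale_factor: float = DEFAULT_SCALE_FACTOR,
                                ) -> IntensityTable:
    """Ratio each sample to its internal standard and log10 transform.

    Every value becomes ``log10(scale_factor · value / standard)`` where
    ``standard`` is the intensity of ``standard_id`` in the same sample.
    The standard row is removed from the output; the scale flag becomes
    ``log10``.
    """
    if table.scale != "linear":
        raise ValueError("internal-standard normalization expects a linear-scale table")
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    if standard_id not in table.values.index:
        raise KeyError(f"internal standard {standard_id!r} not in table")
    std = table.values.loc[standard_id]
    absent = std.index[std.isna()]
    if len(absent):
        raise ValueError(
            f"internal standard {standard_id!r} missing in sample(s) "
            f"{list(absent)}")
    if (std <= 0).any():
        bad = list(std.index[std <= 0])
        raise ValueError(f"non-positive standard intensity in sample(s) {bad}")
    with np.errstate(divide="ignore", invalid="ignore"):
        logged = np.log10(scale_factor * table.values.div(std, axis=1))
    return replace(table,
                   values=logged.drop(index=standard_id),
                   samples=table.samples.copy(),
                   scale="log10")


def filter_missingness(table: IntensityTable, max_missing_fraction: float = 0.5,
                       stratify_by: str | None = None) -> IntensityTable:
    """Drop metabolites whose missing fraction reaches the threshold.

    A metabolite is removed when the fraction of missing entries is
    ``>= max_missing_fraction`` (default 0.5: detected in fewer than half
    the samples).  With ``stratify_by``, the fraction is evaluated within
    each stratum of that metadata column and a metabolite is removed only
    when it fails in every stratum; per-stratum analyses should subset
    the table first, as the pipeline does.
    """
    if not 0.0 < max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must lie in (0, 1]")
    miss = table.missing_mask
    if stratify_by is None:
        frac = miss.mean(axis=1)
        drop = frac >= max_missing_fraction
    else:
        if stratify_by not in table.samples.columns:
            raise KeyError(f"no metadata column {stratify_by!r}")
        fails = []
        for _, meta in table.samples.groupby(stratify_by):
            frac = miss[list(meta.index)].mean(axis=1)
            fails.append(frac >= max_missing_fraction)
        drop = pd.concat(fails, axis=1).all(axis=1)
    kept = table.values.index[~drop]
    if len(kept) == 0:
        warnings.warn("missingness filter removed every metabolite")
    return table.subset_metabolites(list(kept))


def upper_quartile_normalize(table: IntensityTable) -> IntensityTable:
    """Subtract each sample's 75th percentile of detected log intensities.

    On the log scale this is the equivalent of dividing linear
    intensities by the upper quartile; afterwards every sample's upper
    quartile of detected values is 0, which makes the step idempotent.
    """
    if table.scale == "linear":
        raise ValueError("upper-quartile normalization expects a log-scale table")
    counts = table.values.notna().sum(axis=0)
    starved = list(counts.index[counts < 4])
    if starved:
        raise ValueError(
            f"sample(s) with fewer than 4 detected metabolites: {starved}")
    uq = table.values.quantile(0.75, axis=0)
    return replace(table, values=table.values.sub(uq, axis=1),
                   samples=table.samples.copy())


def detect_outlier_samples(table: IntensityTable, sd_threshold: float = 3.0,
                           missing: str = "drop") -> set:
    """Samples whose PC1 or PC2 score is more than ``sd_threshold`` SDs out.

    PCA is run on samples as observations using metabolites with no
    missing value (``missing="drop"``) or with missing entries replaced
    by the metabolite mean (``missing="impute"``).  Detection only; the
    caller decides whether to exclude.
    """
    if table.n_samples < 4:
        raise ValueError("outlier detection needs at least 4 samples")
    if missing not in ("drop", "impute"):
        raise ValueError("missing must be 'drop' or 'impute'")
    if sd_threshold <= 0:
        raise ValueError("sd_threshold must be positive")
    X = table.values.to_numpy().T  # samples × metabolites
    if missing == "drop":
        complete = ~np.isnan(X).any(axis=0)
        X = X[:, complete]
        if X.shape[1] < 2:
            raise ValueError(
                "fewer than 2 complete metabolites; use missing='impute'")
    else:
        col_mean = np.nanmean(X, axis=0)
        nan_at = np.isnan(X)
        X = np.where(nan_at, np.broadcast_to(col_mean, X.shape), X)
    if np.isinf(sd_threshold):
        return set()
    n_comp = min(2, table.n_samples - 1, X.shape[1])
    scores = PCA(n_components=n_comp).fit_transform(X - X.mean(axis=0))
    out = set()
    for k in range(scores.shape[1]):
        s = scores[:, k]
        sd = s.std(ddof=1)
        if sd == 0:
            continue
        z = np.abs(s - s.mean()) / sd
        out.update(np.asarray(table.sample_ids)[z > sd_threshold])
    return out


def _median_heuristic_gamma(x: np.ndarray) -> float:
    """RBF gamma from the median pairwise distance of run-order values."""
    d = np.abs(x[:, None] - x[None, :])
    med = np.median(d[np.triu_indices_from(d, k=1)])
    if med <= 0:
        med = 1.0
    return 1.0 / (2.0 * med ** 2)


def flag_run_order_confounded(table: IntensityTable, r2_threshold: float = 0.3,
                              min_samples: int = 5, svr_c: float = 1.0,
                              svr_epsilon: float = 0.1) -> set:
    """Metabolites whose intensity tracks instrument run order.

    Fits a Gaussian-kernel support-vector regression of intensity on run
    order per metabolite (bandwidth from the median pairwise run-order
    distance, intensities standardised before the fit) and flags
    metabolites whose fitted trend explains at least ``r2_threshold`` of
    the variance.  Constant metabolites have R² defined as 0.
    """
    if "run_order" not in table.samples.columns:
        raise ValueError("sample metadata has no run_order column")
    run_order = pd.to_numeric(table.samples["run_order"], errors="coerce")
    if run_order.isna().any():
        raise ValueError("run_order missing for some samples")
    order = run_order.to_numpy(dtype=float)
    flagged = set()
    for metabolite, row in table.values.iterrows():
        y = row.to_numpy(dtype=float)
        keep = ~np.isnan(y)
        if keep.sum() < min_samples:
            logger.debug("run-order flagging skipped %s (n=%d)",
                         metabolite, keep.sum())
            continue
        yy, xx = y[keep], order[keep]
        sd = yy.std()
        if sd == 0:
            continue  # constant: R² := 0
        z = (yy - yy.mean()) / sd
        model = SVR(kernel="rbf", gamma=_median_heuristic_gamma(xx),
                    C=svr_c, epsilon=svr_epsilon)
        fit = model.fit(xx[:, None], z).predict(xx[:, None])
        r2 = 1.0 - np.sum((z - fit) ** 2) / len(z)  # SS_tot = n for z-scores
        if r2 >= r2_threshold:
            flagged.add(metabolite)
    return flagged
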