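"""Pathway-level direction statistics.

Three aggregations over per-metabolite differential results:

* ``pathway_cumulative_p`` — per pathway, Fisher's combination of the
  p-values of member metabolites whose fold change has a requested sign
  (an over-representation hypergeometric scorer is available as an
  alternative), giving the cumulative evidence that a pathway moved in
  one direction;
* ``pb_vs_rest`` — rank-sum comparison of the fold-change distribution
  of purine-biosynthesis metabolites against all other annotated
  metabolites;
* ``direction_binomial`` — exact binomial test that the observed split
  of decreases among detected pathway members departs from a fair coin.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .tables import PathwayMap

PATHWAY_COLUMNS = ["pathway_id", "pathway_name", "n_detected",
                   "n_direction", "combined_p", "direction", "enriched"]


@dataclass
class DirectionTally:
    n_total: int
    n_down: int
    sidedness: str
    p_value: float


def fisher_combined_p(p_values) -> float:
    """Fisher's method: χ² tail of −2·Σ ln p at 2k degrees of freedom."""
    p = np.asarray(list(p_values), dtype=float)
    if len(p) == 0:
        raise ValueError("no p-values to combine")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    statistic = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(statistic, df=2 * len(p)))


def pathway_cumulative_p(diffs: pd.DataFrame, pmap: PathwayMap, direction: str,
                         min_metabolites: int = 2, cutoff: float = 0.01,
                         method: str = "fisher") -> pd.DataFrame:
    """Direction-stratified cumulative pathway score.

    For each pathway, member metabolites present in ``diffs`` whose
    ``log_fc`` has the requested sign are combined: ``method="fisher"``
    combines their per-metabolite p-values, ``method="hypergeom"`` tests
    over-representation of direction-consistent members against the
    detected background.  Pathways with fewer than ``min_metabolites``
    direction-consistent members are omitted.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if method not in ("fisher", "hypergeom"):
        raise ValueError("method must be 'fisher' or 'hypergeom'")
    if min_metabolites < 1:
        raise ValueError("min_metabolites must be >= 1")
    d = diffs.set_index("metabolite_id")
    sign = 1.0 if direction == "up" else -1.0
    consistent = d.index[np.sign(d["log_fc"]) == sign]
    rows = []
    background = set(d.index)
    n_bg_consistent = len(set(consistent) & background)
    for pathway in pmap.pathway_ids:
        members = pmap.metabolites_in(pathway)
        detected = members & background
        dir_members = sorted(members & set(consistent))
        if len(dir_members) < min_metabolites:
            continue
        if method == "fisher":
            combined = fisher_combined_p(d.loc[dir_members, "p_value"])
        else:
            combined = float(stats.hypergeom.sf(
                len(dir_members) - 1, len(background), n_bg_consistent,
                len(detected)))
        rows.append({
            "pathway_id": pathway,
            "pathway_name": pmap.pathway_names.get(pathway, pathway),
            "n_detected": len(detected),
            "n_direction": len(dir_members),
            "combined_p": combined,
            "direction": direction,
            "enriched": bool(combined < cutoff),
        })
    return pd.DataFrame(rows, columns=PATHWAY_COLUMNS)


def pb_vs_rest(diffs: pd.DataFrame, pmap: PathwayMap,
               min_flagged: int = 3):
    """Purine-biosynthesis versus other-pathway fold-change distributions.

    Two-sided rank-sum test of the ``log_fc`` values of purine-flagged
    metabolites against all other annotated metabolites present in
    ``diffs``; returns ``(p, median_shift)`` where ``median_shift`` is
    median(flagged) − median(others) in log units.
    """
    d = diffs.set_index("metabolite_id")
    flagged = sorted(set(d.index) & pmap.purine_flag)
    others = sorted((set(d.index) & pmap.annotated()) - pmap.purine_flag)
    if len(flagged) < min_flagged:
        raise ValueError(
            f"only {len(flagged)} purine-flagged metabolites detected; "
            f"need at least {min_flagged}")
    if len(others) == 0:
        raise ValueError("no non-flagged annotated metabolites detected")
    a = d.loc[flagged, "log_fc"].to_numpy()
    b = d.loc[others, "log_fc"].to_numpy()
    if np.ptp(np.concatenate([a, b])) == 0:
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return p, float(np.median(a) - np.median(b))


def direction_binomial(n_down: int, n_total: int,
                       sidedness: str) -> DirectionTally:
    """Exact binomial test of the decrease count against probability 1/2.

    One-sided: tail in the direction of the observed deviation,
    ``P(X >= n_down)`` when decreases dominate, ``P(X <= n_down)``
    otherwise.  Two-sided: twice the smaller tail, capped at 1.
    """
    if sidedness not in ("one_sided", "two_sided"):
        raise ValueError("sidedness must be 'one_sided' or 'two_sided'")
    if not 0 <= n_down <= n_total or n_total < 1:
        raise ValueError("need 0 <= n_down <= n_total and n_total >= 1")
    lower = sum(comb(n_total, k) for k in range(0, n_down + 1)) / 2 ** n_total
    upper = sum(comb(n_total, k) for k in range(n_down, n_total + 1)) / 2 ** n_total
    tail = min(lower, upper)
    p = tail if sidedness == "one_sided" else min(1.0, 2.0 * tail)
    return DirectionTally(n_total=n_total, n_down=n_down,
                          sidedness=sidedness, p_value=float(p))
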