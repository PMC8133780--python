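"""Synthetic intensity tables and assay traces with known ground truth.

The generator emulates the statistical structure a cross-species or
cross-genotype metabolome comparison assumes: per-metabolite log10-normal
baselines, coordinated pathway-level group shifts, detection dropout,
smooth run-order drift, and occasional globally shifted outlier samples.
Every downstream stage of the package can therefore be exercised against
a recorded :class:`SyntheticTruth`.

Nothing here models raw mass spectra, retention times or adducts; the
simulated object is the already-quantified metabolite × sample table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import IntensityTable, PathwayMap


@dataclass
class SimulationDesign:
    """Declarative description of a simulated study.

    ``planted_effects`` maps ``(pathway_id, group_label)`` to a log10
    shift added to the baseline mean of every metabolite of that pathway
    in that group; all pairwise contrasts follow from the per-group means
    recorded in the truth object.

    Defaults mirror the designs the package targets: two-group
    comparisons of about ten animals per genotype, a couple of hundred
    detected metabolites, and between-sample noise of 0.2 log10 units
    (roughly a 1.6-fold coefficient of variation, typical of quantified
    metabolite intensities).
    """

    groups: list = field(default_factory=lambda: [("wildtype", 10), ("humanized", 10)])
    tissues: list = field(default_factory=lambda: ["cerebellum"])
    n_metabolites: int = 200
    pathway_assignment: dict = field(default_factory=dict)  # metabolite -> pathway
    planted_effects: dict = field(default_factory=dict)  # (pathway, group) -> log10 shift
    dropout_rate: float = 0.0
    dropout_mode: str = "mcar"  # or "censor" (left-censored low intensities)
    drift_amplitude: float = 0.0
    drift_fraction: float = 0.1
    n_outliers: int = 0
    outlier_shift_sd: float = 5.0  # global shift in units of noise_sd
    outlier_heterogeneity: float = 0.5  # metabolite-level spread of the shift
    noise_sd: float = 0.2
    baseline_mean: float = 3.5
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.groups = [(str(g), int(n)) for g, n in self.groups]
        if any(n < 2 for _, n in self.groups):
            raise ValueError("every group needs at least 2 samples")
        if len({g for g, _ in self.groups}) != len(self.groups):
            raise ValueError("duplicate group labels")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must lie in [0, 1]")
        if self.dropout_mode not in ("mcar", "censor"):
            raise ValueError("dropout_mode must be 'mcar' or 'censor'")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        # each metabolite may belong to at most one planted pathway
        if len(self.pathway_assignment) != len(set(self.pathway_assignment)):
            raise ValueError("duplicate metabolite in pathway_assignment")

    @property
    def group_labels(self) -> list:
        return [g for g, _ in self.groups]

    def metabolite_ids(self) -> list:
        width = max(4, len(str(self.n_metabolites)))
        return [f"m{i:0{width}d}" for i in range(1, self.n_metabolites + 1)]


@dataclass
class SyntheticTruth:
    """Ground truth recorded by :func:`simulate_intensity_table`."""

    true_group_means: pd.DataFrame  # metabolite × group, log10 scale
    affected_metabolites: set
    outlier_samples: set
    drift_metabolites: set = field(default_factory=set)


def assign_pathways(metabolite_ids, pathway_sizes: dict, seed: int = 0) -> dict:
    """Assign the first metabolites to pathways of the given sizes.

    Convenience for building designs: ``{"purine_biosynthesis": 10,
    "other": 50}`` maps the first 10 ids to purine biosynthesis, the
    next 50 to "other", and leaves the remainder unannotated.
    """
    total = sum(pathway_sizes.values())
    if total > len(metabolite_ids):
        raise ValueError("more pathway slots than metabolites")
    out = {}
    cursor = 0
    for pathway, size in pathway_sizes.items():
        for m in metabolite_ids[cursor:cursor + size]:
            out[m] = pathway
        cursor += size
    return out


def pathway_map_from_design(design: SimulationDesign,
                            purine_pathway: str = "purine_biosynthesis") -> PathwayMap:
    """Build the PathwayMap implied by a design's pathway assignment."""
    membership = {m: {p} for m, p in design.pathway_assignment.items()}
    names = {p: p.replace("_", " ") for p in set(design.pathway_assignment.values())}
    flag = {m for m, p in design.pathway_assignment.items() if p == purine_pathway}
    return PathwayMap(membership=membership, pathway_names=names, purine_flag=flag)


def _drift_profile(run_order: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-frequency trend over run order, scaled to unit amplitude."""
    n = len(run_order)
    x = run_order / max(n - 1, 1)
    k = rng.integers(1, 4)  # 1–3 sinusoids
    profile = np.zeros(n)
    for _ in range(k):
        freq = rng.uniform(0.5, 2.0)
        phase = rng.uniform(0, 2 * np.pi)
        profile += rng.uniform(0.5, 1.0) * np.sin(2 * np.pi * freq * x + phase)
    peak = np.max(np.abs(profile))
    return profile / peak if peak > 0 else profile


def simulate_intensity_table(design: SimulationDesign):
    """Draw an :class:`IntensityTable` and its :class:`SyntheticTruth`.

    Baseline log10 intensities are normal per metabolite with
    metabolite-specific means from a wide hyperdistribution; planted
    pathway effects shift group means; dropout, run-order drift and
    outlier shifts are layered on top.  Identical design + seed gives
    bit-identical output.
    """
    rng = np.random.default_rng(design.seed)
    metabolites = design.metabolite_ids()
    m = design.n_metabolites

    # sample frame: groups × tissues, run order randomised across everything
    rows = []
    for tissue in design.tissues:
        for group, n in design.groups:
            for i in range(1, n + 1):
                rows.append({"sample_id": f"{tissue}_{group}_{i:02d}",
                             "group": group, "tissue": tissue})
    samples = pd.DataFrame(rows).set_index("sample_id")
    n_samples = len(samples)
    samples["run_order"] = rng.permutation(n_samples)

    # per-metabolite baselines and per-group means
    baseline = rng.normal(design.baseline_mean, design.baseline_sd, size=m)
    means = pd.DataFrame(
        np.tile(baseline[:, None], (1, len(design.groups))),
        index=metabolites, columns=design.group_labels,
    )
    affected = set()
    for (pathway, group), shift in design.planted_effects.items():
        hit = [mm for mm in metabolites
               if design.pathway_assignment.get(mm) == pathway]
        if not hit:
            raise ValueError(f"planted effect on empty pathway {pathway!r}")
        if group not in means.columns:
            raise ValueError(f"planted effect on unknown group {group!r}")
        means.loc[hit, group] += shift
        affected.update(hit)

    # noiseless expectation per cell, then between-sample noise
    group_of = samples["group"].to_numpy()
    mu = means[group_of].to_numpy()  # m × n_samples via column selection
    values = mu + rng.normal(0.0, design.noise_sd, size=(m, n_samples))

    # smooth run-order drift on a designated metabolite subset
    drift_metabolites = set()
    if design.drift_amplitude > 0 and design.drift_fraction > 0:
        k = max(1, int(round(design.drift_fraction * m)))
        idx = rng.choice(m, size=k, replace=False)
        drift_metabolites = {metabolites[i] for i in sorted(idx)}
        order = samples["run_order"].to_numpy()
        for i in idx:
            values[i] += design.drift_amplitude * _drift_profile(order, rng)

    # globally shifted outlier samples
    outliers = set()
    if design.n_outliers:
        if design.n_outliers >= n_samples:
            raise ValueError("n_outliers must be smaller than the sample count")
        which = rng.choice(n_samples, size=design.n_outliers, replace=False)
        signs = rng.choice([-1.0, 1.0], size=design.n_outliers)
        for j, s in zip(which, signs):
            # sample-wide shift with metabolite-level heterogeneity: real
            # outlier samples (degradation, dilution, contamination) never
            # move every metabolite by exactly the same amount, and a
            # perfectly uniform shift would be cancelled by per-sample
            # upper-quartile normalization
            shift = s * design.outlier_shift_sd * design.noise_sd
            values[:, j] += shift * (
                1.0 + design.outlier_heterogeneity * rng.normal(size=m))
            outliers.add(samples.index[j])

    # detection dropout
    if design.dropout_rate > 0:
        if design.dropout_mode == "mcar":
            mask = rng.random(size=values.shape) < design.dropout_rate
        else:  # left-censor: the lowest values within each metabolite vanish
            q = np.quantile(values, design.dropout_rate, axis=1, keepdims=True)
            mask = values < q
        values = np.where(mask, np.nan, values)

    table = IntensityTable(
        values=pd.DataFrame(values, index=metabolites, columns=samples.index),
        samples=samples,
        scale="log10",
    )
    truth = SyntheticTruth(
        true_group_means=means,
        affected_metabolites=affected,
        outlier_samples=outliers,
        drift_metabolites=drift_metabolites,
    )
    return table, truth


# ---------------------------------------------------------------------------
# thermal-melt fixture

#: default plateau ellipticities (mdeg at 222 nm); folded protein is the
#: more negative (more helical) signal
FOLDED_SIGNAL = -20.0
UNFOLDED_SIGNAL = -4.0


def simulate_melt_curve(midpoint: float, slope: float = 0.8,
                        noise_sd: float = 0.0, seed: int = 0,
                        t_min: float = 50.0, t_max: float = 80.0,
                        step: float = 1.0,
                        folded_signal: float = FOLDED_SIGNAL,
                        unfolded_signal: float = UNFOLDED_SIGNAL):
    """Two-state thermal unfolding curve sampled on a temperature grid.

    Fraction folded follows the two-state logistic
    ``f(T) = 1 / (1 + exp(slope · (T − midpoint)))`` so the curve crosses
    50 % folded exactly at ``midpoint``.  Gaussian noise of ``noise_sd``
    (ellipticity units) is added per point.
    """
    from .assays import MeltingCurve  # local import to avoid cycle

    if slope <= 0:
        raise ValueError("slope must be positive")
    if not t_min <= midpoint <= t_max:
        raise ValueError(
            f"midpoint {midpoint} outside scanned range [{t_min}, {t_max}]")
    temps = np.arange(t_min, t_max + step / 2, step)
    frac_folded = 1.0 / (1.0 + np.exp(slope * (temps - midpoint)))
    signal = unfolded_signal + (folded_signal - unfolded_signal) * frac_folded
    if noise_sd > 0:
        signal = signal + np.random.default_rng(seed).normal(0, noise_sd, temps.shape)
    return MeltingCurve(temperatures=temps, signal=signal)
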