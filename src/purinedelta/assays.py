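"""Quantification of ADSL biophysical measurements.

Four small computations around the enzyme characterisation work:

* specific enzymatic activity from an absorbance-versus-time trace at
  282 nm via Beer–Lambert (default extinction coefficient 10,000
  M⁻¹cm⁻¹ for the adenylosuccinate → AMP reaction), in nmol/min/µg;
* protein concentration by inversion of a BCA/BSA standard curve
  (absorbance at 562 nm);
* thermal denaturation midpoint from a CD melt at 222 nm, as the
  temperature where the fraction folded crosses 50 %;
* tetramer fraction T/(M+T) from native-gel densitometry under
  guanidine hydrochloride, with the half-dissociation concentration by
  interpolation;
* the ratio of single-substrate to mixed-substrate specific activity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: extinction coefficient of the adenylosuccinate → AMP reaction, M⁻¹cm⁻¹
ADSL_EXTINCTION_COEFF = 10_000.0


@dataclass
class AbsorbanceSeries:
    """Absorbance kinetics trace with the constants of the unit chain.

    ``path_length`` (cm) and ``reaction_volume`` (litres) have no
    defaults: microplate path lengths depend on fill volume, and the
    mol/min conversion is meaningless without the volume.
    """

    times: np.ndarray  # minutes, strictly increasing
    absorbance: np.ndarray  # AU at 282 nm
    protein_mass: float  # µg in the reaction
    path_length: float  # cm
    reaction_volume: float  # L
    extinction_coeff: float = ADSL_EXTINCTION_COEFF

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.times.shape != self.absorbance.shape:
            raise ValueError("times and absorbance lengths differ")
        if len(self.times) < 3:
            raise ValueError("need at least 3 time points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.path_length is None or self.path_length <= 0:
            raise ValueError("path_length (cm) is required and positive")
        if self.reaction_volume is None or self.reaction_volume <= 0:
            raise ValueError("reaction_volume (L) is required and positive")
        if self.extinction_coeff <= 0:
            raise ValueError("extinction_coeff must be positive")
        if self.protein_mass <= 0:
            raise ValueError("protein_mass (µg) must be positive")


@dataclass
class MeltingCurve:
    temperatures: np.ndarray  # °C, ascending
    signal: np.ndarray  # ellipticity at 222 nm
    midpoint: float | None = None

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperatures.shape != self.signal.shape:
            raise ValueError("temperature and signal lengths differ")
        if len(self.temperatures) < 5:
            raise ValueError("need at least 5 points for midpoint estimation")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly ascending")


@dataclass
class GelLane:
    tetramer_density: float
    monomer_density: float
    gdnhcl_conc: float  # molar

    def __post_init__(self) -> None:
        if self.tetramer_density < 0 or self.monomer_density < 0:
            raise ValueError("densities must be non-negative")
        if self.tetramer_density + self.monomer_density == 0:
            raise ValueError("tetramer and monomer densities are both zero")


def fit_slope(times: np.ndarray, absorbance: np.ndarray,
              initial_window: bool = False, min_points: int = 5):
    """Least-squares slope (AU/min) of absorbance versus time.

    With ``initial_window``, the prefix of at least ``min_points`` points
    maximising R² is used instead of the whole trace, which discards the
    late curvature caused by substrate depletion.
    """
    if not initial_window:
        return stats.linregress(times, absorbance).slope
    best = None
    for k in range(min_points, len(times) + 1):
        fit = stats.linregress(times[:k], absorbance[:k])
        r2 = fit.rvalue ** 2
        if best is None or r2 > best[0]:
            best = (r2, fit.slope)
    return best[1]


def specific_activity(series: AbsorbanceSeries, initial_window: bool = False,
                      flat_tol: float = 1e-9) -> float:
    """Specific enzymatic activity in nmol/min/µg protein.

    The absorbance slope is converted to a concentration rate through
    Beer–Lambert (ΔA/Δt = ε·l·ΔC/Δt), multiplied by the reaction volume
    to obtain mol/min, expressed in nmol/min and divided by the protein
    mass.  A flat trace yields 0 with a warning.
    """
    slope = fit_slope(series.times, series.absorbance,
                      initial_window=initial_window)
    if abs(slope) <= flat_tol:
        warnings.warn("flat absorbance trace; activity set to 0")
        return 0.0
    rate_molar = abs(slope) / (series.extinction_coeff * series.path_length)
    rate_mol_per_min = rate_molar * series.reaction_volume
    return rate_mol_per_min * 1e9 / series.protein_mass


@dataclass
class BCAResult:
    concentration: float  # µg/ml
    extrapolated: bool


def bca_concentration(standards, unknown_abs: float) -> BCAResult:
    """Invert a BCA standard curve for an unknown absorbance.

    ``standards`` is a sequence of ``(µg/ml, A562)`` pairs; a straight
    line is fitted by least squares and the unknown absorbance inverted
    through it.  Unknowns outside the standard absorbance range are
    still inverted but flagged (and warned) as extrapolated.
    """
    standards = [(float(c), float(a)) for c, a in standards]
    if len(standards) < 3:
        raise ValueError("need at least 3 standards")
    conc = np.array([c for c, _ in standards])
    absorb = np.array([a for _, a in standards])
    fit = stats.linregress(conc, absorb)
    if fit.slope == 0:
        raise ValueError("degenerate standard curve (zero slope)")
    value = (unknown_abs - fit.intercept) / fit.slope
    extrapolated = not (absorb.min() <= unknown_abs <= absorb.max())
    if extrapolated:
        warnings.warn("unknown absorbance outside the standard range; "
                      "extrapolated concentration")
    return BCAResult(concentration=float(value), extrapolated=extrapolated)


def fraction_folded(curve: MeltingCurve, plateau_points: int = 3) -> np.ndarray:
    """Rescale a melt signal to fraction folded using edge plateaus.

    The folded and unfolded baselines are the means of the first and
    last ``plateau_points`` points; orientation (whether the folded
    state is the high or low signal) is detected automatically, so the
    result is invariant to affine transforms and sign flips of the
    signal.
    """
    low_t = curve.signal[:plateau_points].mean()
    high_t = curve.signal[-plateau_points:].mean()
    if low_t == high_t:
        raise ValueError("flat curve: plateaus are identical")
    # folded plateau is at the low-temperature end by construction
    return (curve.signal - high_t) / (low_t - high_t)


def estimate_melting_midpoint(curve: MeltingCurve,
                              plateau_points: int = 3) -> float:
    """Temperature at which the protein is 50 % folded.

    The signal is rescaled to fraction folded and the first crossing of
    0.5 along ascending temperature is located by linear interpolation
    between the bracketing points.
    """
    frac = fraction_folded(curve, plateau_points=plateau_points)
    above = frac >= 0.5
    crossings = np.nonzero(above[:-1] != above[1:])[0]
    if len(crossings) == 0:
        raise ValueError("fraction folded never crosses 0.5")
    i = crossings[0]
    f0, f1 = frac[i], frac[i + 1]
    t0, t1 = curve.temperatures[i], curve.temperatures[i + 1]
    return float(t0 + (0.5 - f0) / (f1 - f0) * (t1 - t0))


def tetramer_fraction(lanes) -> list:
    """Per-lane tetramer fraction T/(M+T), ordered by GdnHCl concentration."""
    lanes = sorted(lanes, key=lambda lane: lane.gdnhcl_conc)
    return [(lane.gdnhcl_conc,
             lane.tetramer_density / (lane.tetramer_density + lane.monomer_density))
            for lane in lanes]


def half_dissociation_concentration(fractions) -> float:
    """GdnHCl concentration at which the tetramer fraction crosses 0.5.

    ``fractions`` is a sequence of ``(conc, fraction)`` pairs (as
    returned by :func:`tetramer_fraction`); linear interpolation between
    the bracketing concentrations.
    """
    pts = sorted((float(c), float(f)) for c, f in fractions)
    for (c0, f0), (c1, f1) in zip(pts[:-1], pts[1:]):
        if (f0 - 0.5) == 0:
            return c0
        if (f0 - 0.5) * (f1 - 0.5) < 0:
            return c0 + (0.5 - f0) / (f1 - f0) * (c1 - c0)
    if pts and pts[-1][1] == 0.5:
        return pts[-1][0]
    raise ValueError("tetramer fraction never crosses 0.5")


def activity_ratio(single: float, mixed: float) -> float:
    """Ratio of single-substrate to mixed-substrate specific activity."""
    if mixed <= 0:
        raise ValueError("mixed-substrate activity must be positive")
    return single / mixed
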