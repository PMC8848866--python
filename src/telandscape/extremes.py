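"""Hotspot/coldspot calling via polynomial-fit cumulative AUC cutoffs.

The window-density (or per-gene TE-count) values are histogrammed, a
least-squares polynomial is fitted through the (bin midpoint, count) points,
negative fitted values are clamped to zero, and the cumulative area under
the clamped curve is accumulated left to right along the density axis. The
cold threshold is the largest grid density whose cumulative AUC stays at or
below ``lower_q`` of the total; the hot threshold likewise for ``upper_q``.
Windows strictly above the hot threshold are hotspots, strictly below the
cold threshold coldspots; boundary values are "normal". Defaults: 1%/99%
for genome windows, 2.5%/97.5% for per-gene counts (the central 95%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .windows import GenomeWindow


class DegenerateDistributionError(ValueError):
    """All values identical: no density distribution to fit."""


@dataclass
class DensityCurve:
    bin_mid: np.ndarray
    counts: np.ndarray
    coeffs: np.ndarray  # numpy polynomial coefficients, ascending degree
    grid: np.ndarray
    curve: np.ndarray  # clamped fitted values on the grid
    total_auc: float
    fit_warning: bool = False


@dataclass
class ExtremeCalls:
    cold_threshold: float
    hot_threshold: float
    lower_q: float
    upper_q: float
    labels: list[str] = field(default_factory=list)  # per value

    @property
    def n_hotspots(self) -> int:
        return sum(lab == "hotspot" for lab in self.labels)

    @property
    def n_coldspots(self) -> int:
        return sum(lab == "coldspot" for lab in self.labels)


def fit_density_curve(
    values,
    degree: int = 10,
    n_bins: int = 100,
    grid_size: int = 2000,
) -> DensityCurve:
    """Fit a polynomial through the frequency distribution of ``values``."""
    v = np.asarray(values, dtype=float)
    if v.size < 2 or np.ptp(v) == 0:
        raise DegenerateDistributionError("need >= 2 distinct values")
    degree = min(degree, n_bins - 1)
    counts, edges = np.histogram(v, bins=n_bins)
    mid = (edges[:-1] + edges[1:]) / 2.0
    # fit in a scaled coordinate for numerical stability at degree ~10
    poly = np.polynomial.Polynomial.fit(mid, counts, degree)
    grid = np.linspace(v.min(), v.max(), grid_size)
    curve = np.clip(poly(grid), 0.0, None)
    total = float(np.trapezoid(curve, grid))
    if total <= 0:
        raise DegenerateDistributionError("fitted curve has zero area")
    resid = float(np.abs(poly(mid) - counts).sum())
    fit_warning = resid > 0.10 * counts.sum()
    if fit_warning:
        warnings.warn(
            "polynomial fit leaves residual structure exceeding 10% of the "
            "count mass; consider a different degree or bin count",
            stacklevel=2,
        )
    return DensityCurve(mid, counts, poly.convert().coef, grid, curve, total, fit_warning)


def auc_cutoffs(
    curve: DensityCurve, lower_q: float = 0.01, upper_q: float = 0.99
) -> tuple[float, float]:
    """Density thresholds where the cumulative AUC reaches lower_q/upper_q
    of the total, taken as the largest grid density not exceeding each mark."""
    if not 0.0 < lower_q < upper_q < 1.0:
        raise ValueError("need 0 < lower_q < upper_q < 1")
    if curve.total_auc <= 0:
        raise ValueError("zero total AUC")
    cum = np.concatenate([[0.0], cumulative_trapezoid(curve.curve, curve.grid)])
    cold = float(curve.grid[np.searchsorted(cum, lower_q * curve.total_auc, "right") - 1])
    hot = float(curve.grid[np.searchsorted(cum, upper_q * curve.total_auc, "right") - 1])
    return cold, hot


def call_extremes(
    values,
    curve: DensityCurve | None = None,
    thresholds: tuple[float, float] | None = None,
    lower_q: float = 0.01,
    upper_q: float = 0.99,
    degree: int = 10,
    n_bins: int = 100,
) -> ExtremeCalls:
    """Label each value hotspot / normal / coldspot against the AUC cutoffs.

    Comparisons are strict, so a value equal to a threshold is "normal".
    """
    v = np.asarray(values, dtype=float)
    if thresholds is None:
        if curve is None:
            curve = fit_density_curve(v, degree=degree, n_bins=n_bins)
        thresholds = auc_cutoffs(curve, lower_q, upper_q)
    cold, hot = thresholds
    if cold >= hot:
        raise ValueError("cold threshold must be below hot threshold")
    labels = [
        "hotspot" if x > hot else "coldspot" if x < cold else "normal" for x in v
    ]
    return ExtremeCalls(cold, hot, lower_q, upper_q, labels)


def call_window_extremes(
    windows: list[GenomeWindow],
    lower_q: float = 0.01,
    upper_q: float = 0.99,
    degree: int = 10,
    n_bins: int = 100,
) -> ExtremeCalls:
    """Hotspot/coldspot calls over window TE densities (kb per 100 kb)."""
    dens = [w.te_kb_per_100kb for w in windows]
    return call_extremes(dens, lower_q=lower_q, upper_q=upper_q, degree=degree, n_bins=n_bins)


def fold_enrichment(observed_density: float, expected_density: float) -> float:
    """Observed / expected density ratio, rounded to 2 decimals.

    The expected density is the genome mean window density (an even spread
    of TEs over windows).
    """
    if expected_density <= 0:
        raise ValueError("expected density must be positive")
    return round(observed_density / expected_density, 2)


def calls_to_bed(windows: list[GenomeWindow], calls: ExtremeCalls, path) -> None:
    with open(path, "w") as fh:
        for w, lab in zip(windows, calls.labels):
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{lab}\t{w.te_kb_per_100kb:.4f}\n")
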