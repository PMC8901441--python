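"""Ratiometric molecularity and oligomerization kinetics.

Foci brightness is converted to molecule numbers by comparison with an
intracellular standard of known stoichiometry imaged under identical
conditions — by default the nuclear pore protein Nup96, present in
exactly 32 copies per pore:

    M_p = I_p * M_s / I_s

where ``I_p`` is the background-corrected focus intensity, ``M_s`` the
standard's subunit count and ``I_s`` the pooled mean standard intensity.
Per-timepoint molecularity distributions (MOMP-aligned) are then
summarized into the kinetic observables: average molecularity from an
exponential fit of the survival (complementary cumulative) counts, foci
per mitochondrial area, and the fraction of foci above fixed
molecularity thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit
from skimage.filters import threshold_otsu

__all__ = [
    "StandardCalibration",
    "FociTimeSeries",
    "DecayFit",
    "calibrate_standard",
    "to_molecularity",
    "fit_cumulative_decay",
    "summarize_timeseries",
    "align_to_momp",
    "expression_level",
]


@dataclass
class StandardCalibration:
    """Pooled brightness of the counting standard.

    ``per_cell_means`` holds the Gaussian-fitted mean intensity ``i_s``
    of each imaged standard cell; ``intensity`` is their average
    ``I_s``; ``stoichiometry`` is the standard's subunit count ``M_s``
    (32 for the Nup96 nuclear pore standard).
    """

    per_cell_means: np.ndarray
    intensity: float
    stoichiometry: int
    n_cells: int

    def __post_init__(self) -> None:
        if self.intensity <= 0:
            raise ValueError("pooled standard intensity must be positive")


@dataclass
class FociTimeSeries:
    """Per-timepoint foci molecularity lists on a MOMP-aligned clock.

    ``timepoints_min`` are minutes after MOMP (Smac release);
    ``molecularities[i]`` holds the molecularity of every focus at
    timepoint ``i``; ``mito_area`` is the mitochondrial network area
    used to normalize foci density. ``truth_mean`` (synthetic series
    only) carries the generator's noise-free mean trajectory.
    """

    timepoints_min: np.ndarray
    molecularities: list[np.ndarray]
    mito_area: float
    truth_mean: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timepoints_min = np.asarray(self.timepoints_min, dtype=float)
        if self.timepoints_min.size != len(self.molecularities):
            raise ValueError("one molecularity list per timepoint required")
        if np.any(np.diff(self.timepoints_min) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        self.molecularities = [np.asarray(m, dtype=float) for m in self.molecularities]
        if any(np.any(m < 0) for m in self.molecularities):
            raise ValueError("molecularities must be non-negative")


@dataclass
class DecayFit:
    """Average molecularity from an exponential survival-count fit."""

    mean_molecularity: float
    amplitude: float
    n_foci: int
    fallback: bool = False  # True when the sample mean replaced the fit
    reason: str = ""


def calibrate_standard(
    per_cell_intensities: list[np.ndarray],
    stoichiometry: int = 32,
    min_cells: int = 5,
    min_per_cell: int = 50,
    trim: float = 0.0,
) -> StandardCalibration:
    """Pool per-cell standard intensities into a calibration.

    For each cell a single Gaussian is fitted to the complex intensity
    distribution (maximum likelihood; optionally trimmed symmetrically
    by ``trim`` fraction per tail to resist outlier clusters, default
    off) and its mean taken as ``i_s``; ``I_s`` is the arithmetic mean
    of ``i_s`` over cells. Fewer than ``min_cells`` cells (default 5)
    or ``min_per_cell`` complexes in any cell is an error — the
    standard must be sampled well enough to anchor every molecularity
    downstream.
    """
    if len(per_cell_intensities) < min_cells:
        raise ValueError(
            f"standard calibration needs >= {min_cells} cells, got {len(per_cell_intensities)}"
        )
    means = []
    for i, vals in enumerate(per_cell_intensities):
        v = np.asarray(vals, dtype=float)
        if v.size < min_per_cell:
            raise ValueError(
                f"cell {i} has {v.size} standard complexes (< {min_per_cell})"
            )
        if trim > 0:
            means.append(float(stats.trim_mean(v, trim)))
        else:
            mu, _ = stats.norm.fit(v)
            means.append(float(mu))
    means = np.asarray(means)
    return StandardCalibration(
        per_cell_means=means,
        intensity=float(means.mean()),
        stoichiometry=int(stoichiometry),
        n_cells=len(means),
    )


def to_molecularity(Ip: np.ndarray | float, calib: StandardCalibration) -> np.ndarray | float:
    """Ratiometric molecularity: ``M_p = I_p * M_s / I_s`` (exact linear map)."""
    if calib.intensity <= 0:
        raise ValueError("standard intensity must be positive")
    return np.asarray(Ip, dtype=float) * calib.stoichiometry / calib.intensity if np.ndim(Ip) else float(Ip) * calib.stoichiometry / calib.intensity


def fit_cumulative_decay(molecularities: np.ndarray, min_foci: int = 10) -> DecayFit:
    """Average molecularity via exponential fit of survival counts.

    The empirical complementary cumulative count ``C(M) = #{foci >= M}``
    is fitted with ``A * exp(-M / <M>)`` by least squares; for
    exponentially distributed molecularities the decay constant *is*
    the mean.  With fewer than ``min_foci`` foci, or when the sample is
    degenerate (all equal) or the fit fails, the sample mean is
    returned with ``fallback=True``.
    """
    m = np.asarray(molecularities, dtype=float)
    if m.size == 0:
        raise ValueError("cannot fit an empty molecularity sample")
    if m.size < min_foci:
        return DecayFit(float(m.mean()), float(m.size), m.size, True, "too few foci")
    if np.ptp(m) == 0:
        return DecayFit(float(m[0]), float(m.size), m.size, True, "degenerate sample")
    xs = np.sort(m)
    counts = m.size - np.arange(m.size, dtype=float)  # number of foci >= xs[i]
    try:
        popt, _ = curve_fit(
            lambda M, A, mbar: A * np.exp(-M / mbar),
            xs,
            counts,
            p0=(float(m.size), float(m.mean())),
            maxfev=20000,
        )
    except RuntimeError:
        return DecayFit(float(m.mean()), float(m.size), m.size, True, "fit failed")
    A, mbar = popt
    if mbar <= 0:
        return DecayFit(float(m.mean()), float(m.size), m.size, True, "non-positive decay")
    return DecayFit(float(mbar), float(A), m.size)


def summarize_timeseries(
    series: FociTimeSeries, thresholds: tuple[float, ...] = (200.0, 400.0)
) -> pd.DataFrame:
    """Kinetic observables per timepoint.

    Columns: ``time_min``, ``n_foci``, ``foci_per_area`` (count divided
    by mitochondrial area), ``mean_molecularity`` (exponential survival
    fit, NaN when no foci), ``mean_is_fallback``, and one
    ``frac_gt_<T>`` column per threshold using strict inequality
    ``M > T``.
    """
    if series.mito_area <= 0:
        raise ValueError("mitochondrial area must be positive")
    rows = []
    for t, m in zip(series.timepoints_min, series.molecularities):
        row: dict[str, float] = {
            "time_min": float(t),
            "n_foci": int(m.size),
            "foci_per_area": m.size / series.mito_area,
        }
        if m.size:
            fit = fit_cumulative_decay(m)
            row["mean_molecularity"] = fit.mean_molecularity
            row["mean_is_fallback"] = bool(fit.fallback)
        else:
            row["mean_molecularity"] = np.nan
            row["mean_is_fallback"] = True
        for T in thresholds:
            key = f"frac_gt_{int(T) if float(T).is_integer() else T}"
            row[key] = float(np.mean(m > T)) if m.size else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def align_to_momp(
    timepoints: np.ndarray, momp_time: float
) -> tuple[np.ndarray, np.ndarray]:
    """Shift acquisition times onto the MOMP-relative clock.

    Returns ``(relative_times, post_momp_mask)`` where relative time is
    ``t - momp_time`` and the mask flags frames at or after MOMP; pre-
    MOMP frames are excluded from kinetics (the oligomerization clock
    starts at Smac release). A series that ends before MOMP yields an
    all-False mask with a warning.
    """
    if momp_time is None or not np.isfinite(momp_time):
        raise ValueError("momp_time must be a finite number")
    t = np.asarray(timepoints, dtype=float)
    rel = t - momp_time
    mask = rel >= 0
    if not mask.any():
        warnings.warn("all frames precede MOMP; no kinetics can be computed", stacklevel=2)
    return rel, mask


def expression_level(
    gfp_image: np.ndarray,
    mito_marker_image: np.ndarray,
    threshold: float | None = None,
) -> float:
    """Protein expression per unit mitochondrial area.

    The mitochondrial network mask is the marker channel above
    ``threshold`` (Otsu's threshold when not given); the metric is the
    total GFP intensity of the cell divided by the mask pixel count.
    """
    gfp = np.asarray(gfp_image, dtype=float)
    marker = np.asarray(mito_marker_image, dtype=float)
    if gfp.shape != marker.shape:
        raise ValueError("GFP and marker images must have the same shape")
    if threshold is None:
        threshold = threshold_otsu(marker)
    mask = marker > threshold
    area = int(mask.sum())
    if area == 0:
        raise ValueError("mitochondrial mask is empty; check the marker channel/threshold")
    return float(gfp.sum() / area)
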