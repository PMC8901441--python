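"""Diffraction-limited spot detection, 2-D Gaussian fitting and QC filters.

The stage turns an image (or a maximum-intensity z-projection) into a
table of per-particle brightness values ``Ip``:

1. :func:`max_z_project` collapses a z-stack and records the plane of
   maximum intensity per pixel;
2. :func:`detect_spots` finds candidate centers with a Difference of
   Gaussians band-pass plus local-maximum thresholding;
3. :func:`fit_particle` fits an isotropic 2-D Gaussian inside a small
   ROI above a locally estimated background annulus and integrates it
   (``Ip = 2*pi*A*sigma^2``);
4. :func:`filter_particles` applies the quality rules: overlapping-ROI
   rejection, upper-tail sigma percentile cut (wide fits indicate
   multiple particles in one ROI), and edge-plane rejection for
   z-stacks.

Coordinates are 0-based with pixel-center convention; subpixel centers
are floats. ``sigma`` is the Gaussian standard deviation in pixels
(FWHM = 2.355 * sigma).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

from .io import ImageStack

__all__ = [
    "ParticleFit",
    "max_z_project",
    "detect_spots",
    "fit_particle",
    "filter_particles",
    "analyze_image",
    "fits_to_frame",
]

QC_FLAGS = ("overlap", "sigma_outlier", "edge_frame", "fit_fail")


@dataclass
class ParticleFit:
    """One fitted spot.

    ``brightness`` is the background-corrected integrated intensity
    ``Ip = 2*pi*A*sigma^2`` (the volume of the fitted Gaussian above the
    local background), clipped at zero. ``qc_flags`` is empty iff the
    particle is retained.
    """

    row: float
    col: float
    sigma: float = np.nan
    amplitude: float = np.nan
    background: float = np.nan
    brightness: float = np.nan
    residual: float = np.nan
    frame_of_max: int = -1
    qc_flags: set[str] = field(default_factory=set)

    @property
    def retained(self) -> bool:
        return not self.qc_flags


def max_z_project(stack: ImageStack) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-intensity projection over planes with per-pixel argmax.

    Ties resolve to the lowest plane index (``np.argmax`` convention),
    deterministically. The argmax map feeds the edge-plane filter: a
    particle brightest in the first or last plane may extend beyond the
    acquired volume and its intensity would be underestimated.
    """
    data = stack.data
    if data.shape[0] == 1:
        warnings.warn("single-plane stack: projection is the identity", stacklevel=2)
        return data[0].copy(), np.zeros(data.shape[1:], dtype=int)
    return data.max(axis=0), data.argmax(axis=0).astype(int)


def detect_spots(
    image: np.ndarray,
    dog_sigma_small: float = 1.0,
    dog_sigma_large: float = 1.6,
    threshold: float | None = None,
    threshold_sd: float = 3.5,
    min_distance: int = 3,
) -> np.ndarray:
    """Detect candidate spot centers by Difference of Gaussians.

    The image is band-passed as ``G(sigma_small) - G(sigma_large)`` and
    local maxima above threshold are returned, deduplicated within
    ``min_distance`` pixels (about one PSF width).  If ``threshold`` is
    None it defaults to ``threshold_sd`` times a robust (MAD-based)
    estimate of the DoG response noise — spots must stand out of the
    background by that many noise standard deviations.

    Returns an ``(N, 2)`` float array of (row, col) candidates; empty
    when nothing exceeds threshold.
    """
    if dog_sigma_small >= dog_sigma_large:
        raise ValueError("dog_sigma_small must be < dog_sigma_large")
    img = np.asarray(image, dtype=float)
    dog = ndimage.gaussian_filter(img, dog_sigma_small) - ndimage.gaussian_filter(
        img, dog_sigma_large
    )
    if threshold is None:
        mad = np.median(np.abs(dog - np.median(dog)))
        threshold = threshold_sd * mad / 0.6744897501960817
    peaks = peak_local_max(
        dog, min_distance=min_distance, threshold_abs=threshold, exclude_border=False
    )
    return peaks.astype(float)


def _gaussian2d(params: np.ndarray, rr: np.ndarray, cc: np.ndarray, b: float) -> np.ndarray:
    a, r0, c0, s = params
    return b + a * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * s**2))


def fit_particle(
    image: np.ndarray,
    center: tuple[float, float],
    roi_radius_px: int = 3,
    bg_radius_px: int = 4,
    frame_of_max: int = -1,
) -> ParticleFit:
    """Fit an isotropic 2-D Gaussian to one spot.

    The local background ``b`` is the mean of the annulus between
    ``roi_radius_px`` and ``bg_radius_px`` around the candidate center;
    the Gaussian (amplitude, subpixel center, sigma) is then fitted by
    least squares to the pixels within the ``roi_radius_px`` disc with
    ``b`` held fixed.  A fit that does not converge, runs into its
    bounds with ``sigma > roi_radius_px``, or whose ROI leaves the image
    is flagged ``fit_fail`` and excluded downstream.
    """
    img = np.asarray(image, dtype=float)
    r0, c0 = int(round(center[0])), int(round(center[1]))
    fit = ParticleFit(row=float(center[0]), col=float(center[1]), frame_of_max=frame_of_max)
    R = bg_radius_px
    if r0 - R < 0 or c0 - R < 0 or r0 + R >= img.shape[0] or c0 + R >= img.shape[1]:
        fit.qc_flags.add("fit_fail")
        return fit

    patch = img[r0 - R : r0 + R + 1, c0 - R : c0 + R + 1]
    rr, cc = np.mgrid[r0 - R : r0 + R + 1, c0 - R : c0 + R + 1].astype(float)
    dist2 = (rr - r0) ** 2 + (cc - c0) ** 2
    annulus = (dist2 > roi_radius_px**2) & (dist2 <= bg_radius_px**2)
    disc = dist2 <= roi_radius_px**2
    b = float(patch[annulus].mean())

    y = patch[disc]
    rd, cd = rr[disc], cc[disc]
    ra, ca = rr[annulus], cc[annulus]
    a0 = max(float(y.max() - b), 1e-6)
    p0 = np.array([a0, float(center[0]), float(center[1]), 1.2])
    lb = np.array([0.0, r0 - roi_radius_px, c0 - roi_radius_px, 0.3])
    ub = np.array([np.inf, r0 + roi_radius_px, c0 + roi_radius_px, float(bg_radius_px)])
    try:
        # the spot's own tail biases the annulus mean high; alternate the
        # Gaussian fit with re-estimating b after removing the fitted
        # tail's annulus contribution, until b stabilizes
        for _ in range(8):
            res = optimize.least_squares(
                lambda p: _gaussian2d(p, rd, cd, b) - y, p0, bounds=(lb, ub), xtol=1e-10
            )
            tail = _gaussian2d(res.x, ra, ca, 0.0)
            b_new = float((patch[annulus] - tail).mean())
            p0 = res.x
            if abs(b_new - b) < 1e-3 * max(abs(b), 1.0):
                b = b_new
                break
            b = b_new
    except Exception:
        fit.qc_flags.add("fit_fail")
        return fit

    a, rf, cf, s = res.x
    fit.amplitude = float(a)
    fit.row, fit.col = float(rf), float(cf)
    fit.sigma = float(s)
    fit.background = b
    fit.brightness = max(2.0 * np.pi * a * s**2, 0.0)
    fit.residual = float(np.sqrt(np.mean(res.fun**2)))
    if (not res.success) or s > roi_radius_px:
        fit.qc_flags.add("fit_fail")
    return fit


def filter_particles(
    fits: list[ParticleFit],
    min_center_separation_px: float = 7.0,
    sigma_percentile: float = 95.0,
    n_planes: int | None = None,
) -> tuple[list[ParticleFit], dict[str, int]]:
    """Apply the quality filters and return (retained fits, report).

    Rules, each evaluated independently on the full set of convergent
    fits (so the outcome is order-independent and re-running on the same
    input is idempotent):

    * ``overlap`` — any pair of centers closer than
      ``min_center_separation_px`` flags *both* members (conservative:
      either brightness may be contaminated).  The default of 7 px
      equals roi + background radius, so retained background annuli
      never overlap another ROI.
    * ``sigma_outlier`` — sigma above the per-image
      ``sigma_percentile``-th percentile (default 95) of the sigma
      sample; abnormally wide fits indicate several particles in one
      ROI.  One-sided: narrow fits are kept.  Skipped with a warning
      when fewer than 20 fits are available (the percentile would be
      unstable).
    * ``edge_frame`` — for z-stacks (``n_planes`` given), particles
      whose per-pixel intensity maximum lies in the first or last
      plane.

    ``fit_fail`` flags set earlier are preserved.
    """
    if not fits:
        raise ValueError("filter_particles requires at least one fit")
    if not (50.0 < sigma_percentile < 100.0):
        raise ValueError("sigma_percentile must be in (50, 100)")

    for f in fits:
        f.qc_flags.discard("overlap")
        f.qc_flags.discard("sigma_outlier")
        f.qc_flags.discard("edge_frame")
    ok = [f for f in fits if "fit_fail" not in f.qc_flags]

    if len(ok) >= 2:
        tree = cKDTree([(f.row, f.col) for f in ok])
        for i, j in tree.query_pairs(min_center_separation_px):
            ok[i].qc_flags.add("overlap")
            ok[j].qc_flags.add("overlap")

    if len(ok) >= 20:
        sigmas = np.array([f.sigma for f in ok])
        cutoff = np.percentile(sigmas, sigma_percentile)
        for f in ok:
            if f.sigma > cutoff:
                f.qc_flags.add("sigma_outlier")
    elif ok:
        warnings.warn(
            f"only {len(ok)} fits: sigma-percentile filter skipped (unstable percentile)",
            stacklevel=2,
        )

    if n_planes is not None and n_planes >= 2:
        for f in ok:
            if f.frame_of_max in (0, n_planes - 1):
                f.qc_flags.add("edge_frame")

    retained = [f for f in fits if f.retained]
    report = {flag: sum(flag in f.qc_flags for f in fits) for flag in QC_FLAGS}
    report["n_input"] = len(fits)
    report["n_retained"] = len(retained)
    return retained, report


def analyze_image(
    image: np.ndarray,
    argmax_plane: np.ndarray | None = None,
    n_planes: int | None = None,
    dog_sigma_small: float = 1.0,
    dog_sigma_large: float = 1.6,
    threshold: float | None = None,
    roi_radius_px: int = 3,
    bg_radius_px: int = 4,
    min_center_separation_px: float = 7.0,
    sigma_percentile: float = 95.0,
) -> tuple[list[ParticleFit], dict[str, int]]:
    """Detect, fit and filter all spots in one image.

    Convenience wrapper chaining :func:`detect_spots`,
    :func:`fit_particle` and :func:`filter_particles`; ``argmax_plane``
    (from :func:`max_z_project`) enables the edge-plane filter.
    Returns the retained fits and the rejection report.
    """
    centers = detect_spots(
        image,
        dog_sigma_small=dog_sigma_small,
        dog_sigma_large=dog_sigma_large,
        threshold=threshold,
    )
    fits = []
    for r, c in centers:
        fmax = -1
        if argmax_plane is not None:
            fmax = int(argmax_plane[int(round(r)), int(round(c))])
        fits.append(
            fit_particle(
                image,
                (r, c),
                roi_radius_px=roi_radius_px,
                bg_radius_px=bg_radius_px,
                frame_of_max=fmax,
            )
        )
    if not fits:
        return [], {flag: 0 for flag in QC_FLAGS} | {"n_input": 0, "n_retained": 0}
    return filter_particles(
        fits,
        min_center_separation_px=min_center_separation_px,
        sigma_percentile=sigma_percentile,
        n_planes=n_planes,
    )


def fits_to_frame(fits: list[ParticleFit]) -> pd.DataFrame:
    """Tabulate fits as a DataFrame (one row per particle).

    ``qc_flags`` is serialized as a ``|``-joined sorted string, empty
    for retained particles.
    """
    return pd.DataFrame(
        {
            "row": [f.row for f in fits],
            "col": [f.col for f in fits],
            "sigma": [f.sigma for f in fits],
            "amplitude": [f.amplitude for f in fits],
            "background": [f.background for f in fits],
            "brightness": [f.brightness for f in fits],
            "residual": [f.residual for f in fits],
            "frame_of_max": [f.frame_of_max for f in fits],
            "qc_flags": ["|".join(sorted(f.qc_flags)) for f in fits],
        }
    )
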