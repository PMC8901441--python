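"""Brightness-to-stoichiometry decomposition.

Pipeline: photobleaching traces of isolated particles calibrate the
single-fluorophore brightness (mu1, sigma1); the per-particle brightness
sample is then decomposed as a linear combination of Gaussians with
fixed means ``j*mu1`` and variances ``j*sigma1^2`` (sums of j i.i.d.
emitters), giving the observed fractions ``w_j`` of particles carrying j
*labeled* units; finally the binomial labeling model inverts ``w`` into
true n-mer fractions ``v_n`` given the labeling efficiency ``p``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.optimize import nnls

__all__ = [
    "StepCountResult",
    "MonomerCalibration",
    "MixtureResult",
    "count_bleach_steps",
    "calibrate_monomer",
    "fit_gaussian_mixture",
    "binomial_projection_matrix",
    "correct_labeling",
    "occurrence_summary",
]


# ---------------------------------------------------------------------------
# photobleaching step counting


@dataclass
class StepCountResult:
    """Outcome of change-point step detection on one bleaching trace."""

    n_steps: int
    levels: np.ndarray  # mean intensity of each plateau, in time order
    changepoints: np.ndarray  # frame indices where a new plateau starts
    rejected: bool = False  # re-brightening observed
    reason: str = ""


def _binseg(x: np.ndarray, penalty: float, min_size: int = 2) -> list[int]:
    """Binary segmentation for piecewise-constant means.

    Recursively splits at the point minimizing the summed within-segment
    squared error, accepting a split only when the error reduction
    exceeds ``penalty``. Returns sorted interior change points.
    """

    def best_split(lo: int, hi: int) -> tuple[float, int]:
        seg = x[lo:hi]
        n = seg.size
        if n < 2 * min_size:
            return 0.0, -1
        csum = np.cumsum(seg)
        total = csum[-1]
        k = np.arange(min_size, n - min_size + 1)
        left = csum[k - 1]
        # SSE reduction of splitting at k: ||seg||^2 terms cancel
        gain = left**2 / k + (total - left) ** 2 / (n - k) - total**2 / n
        i = int(np.argmax(gain))
        return float(gain[i]), lo + int(k[i])

    cps: list[int] = []
    stack = [(0, x.size)]
    while stack:
        lo, hi = stack.pop()
        gain, split = best_split(lo, hi)
        if split >= 0 and gain > penalty:
            cps.append(split)
            stack.append((lo, split))
            stack.append((split, hi))
    return sorted(cps)


def count_bleach_steps(
    trace: np.ndarray,
    median_window: int = 5,
    penalty: float | None = None,
    min_step: float | None = None,
) -> StepCountResult:
    """Count downward photobleaching steps in an intensity trace.

    The trace is smoothed with a median filter of ``median_window``
    frames, then segmented into plateaus by penalized binary
    segmentation. The number of downward level changes is the step
    count. Traces whose level sequence re-brightens (a later plateau
    higher than its predecessor by more than ``min_step``) are rejected:
    they indicate a second particle entering the ROI or blinking, and
    are unusable for monomer selection.

    ``penalty`` defaults to ``10 * sigma^2 * log(n)`` with sigma
    estimated robustly from first differences of the raw trace — a BIC-
    style choice whose prefactor was fixed once on simulated traces.
    ``min_step`` (level-difference floor for a real step) defaults to
    ``3 * sigma``.
    """
    x = np.asarray(trace, dtype=float)
    if median_window < 1:
        raise ValueError("median_window must be >= 1")
    if x.size <= 3 * median_window:
        raise ValueError("trace too short for the requested median window")

    if median_window > 1:
        k = median_window if median_window % 2 == 1 else median_window + 1
        sm = ndimage.median_filter(x, size=k, mode="nearest")
    else:
        sm = x.copy()

    diffs = np.diff(x)
    sigma = np.median(np.abs(diffs - np.median(diffs))) / 0.6744897501960817 / math.sqrt(2)
    sigma = max(sigma, 1e-12)
    if penalty is None:
        penalty = 10.0 * sigma**2 * math.log(x.size)
    if min_step is None:
        min_step = 3.0 * sigma

    cps = _binseg(sm, penalty)
    bounds = [0, *cps, x.size]
    # plateau levels from the raw trace, guarding a half-window around each
    # change point where the median filter mixes adjacent plateaus
    guard = median_window // 2
    levels = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        glo = lo + (guard if lo > 0 else 0)
        ghi = hi - (guard if hi < x.size else 0)
        seg = x[glo:ghi] if ghi > glo else x[lo:hi]
        levels.append(seg.mean())
    levels = np.asarray(levels)

    # merge consecutive plateaus closer than the step floor
    merged = [levels[0]] if levels.size else []
    keep_cp = []
    for cp, lv in zip(cps, levels[1:]):
        if abs(lv - merged[-1]) < min_step:
            merged[-1] = (merged[-1] + lv) / 2.0
        else:
            merged.append(lv)
            keep_cp.append(cp)
    levels = np.asarray(merged)
    cps = np.asarray(keep_cp, dtype=int)

    drops = np.diff(levels)
    n_down = int(np.count_nonzero(drops < 0))
    rebright = bool(np.any(drops > 0))
    return StepCountResult(
        n_steps=n_down,
        levels=levels,
        changepoints=cps,
        rejected=rebright,
        reason="re-brightening" if rebright else "",
    )


# ---------------------------------------------------------------------------
# monomer calibration


@dataclass
class MonomerCalibration:
    """Single-fluorophore brightness calibration (mu1, sigma1)."""

    mu1: float
    sigma1: float
    n_used: int

    def __post_init__(self) -> None:
        if self.mu1 <= 0:
            raise ValueError("mu1 must be positive")
        if self.sigma1 < 0:
            raise ValueError("sigma1 must be non-negative")


def calibrate_monomer(
    traces: np.ndarray | None = None,
    brightnesses: np.ndarray | None = None,
    median_window: int = 5,
    min_candidates: int = 50,
) -> MonomerCalibration:
    """Estimate the monomer brightness unit from single-step traces.

    Given bleaching ``traces`` (rows = traces), each is step-counted and
    only clean single-step traces enter the calibration; the monomer
    brightness of a trace is its initial plateau minus its final
    (post-bleach) plateau.  Alternatively ``brightnesses`` provides
    already-selected single-molecule intensities (e.g. fitted Ip of
    isolated monomers) directly.

    Fewer than ``min_candidates`` accepted values is an error: the
    calibration would be statistically unreliable and every downstream
    stoichiometry would inherit the bias.
    """
    if (traces is None) == (brightnesses is None):
        raise ValueError("provide exactly one of traces or brightnesses")
    if traces is not None:
        heights = []
        for tr in np.asarray(traces, dtype=float):
            res = count_bleach_steps(tr, median_window=median_window)
            if res.n_steps == 1 and not res.rejected and res.levels.size >= 2:
                heights.append(res.levels[0] - res.levels[-1])
        values = np.asarray(heights)
    else:
        values = np.asarray(brightnesses, dtype=float)
    if values.size < min_candidates:
        raise ValueError(
            f"only {values.size} monomer candidates (< {min_candidates}); "
            "calibration unreliable"
        )
    return MonomerCalibration(
        mu1=float(values.mean()),
        sigma1=float(values.std(ddof=1)) if values.size > 1 else 0.0,
        n_used=int(values.size),
    )


# ---------------------------------------------------------------------------
# linear-combination-of-Gaussians decomposition


@dataclass
class MixtureResult:
    """n-mer decomposition of a brightness distribution.

    ``weights_observed[j-1]`` is the fraction of particles whose
    brightness matches j labeled units; ``weights_corrected[n-1]`` (set
    by :func:`correct_labeling`) is the fraction of true n-mers after
    accounting for partial labeling.
    """

    max_n: int
    weights_observed: np.ndarray
    mu1: float
    sigma1: float
    log_likelihood: float
    n_particles: int
    weights_corrected: np.ndarray | None = None
    labeling_efficiency: float | None = None


def fit_gaussian_mixture(
    brightnesses: np.ndarray,
    calib: MonomerCalibration,
    max_n: int = 10,
    min_particles: int = 200,
    tol: float = 1e-10,
    max_iter: int = 5000,
) -> MixtureResult:
    """Decompose brightness values into fixed n-mer Gaussian components.

    Maximum-likelihood fit of ``sum_j w_j * Normal(j*mu1, j*sigma1^2)``
    for ``j = 1..max_n``, with means and variances pinned by the
    monomer calibration and only the simplex-constrained weights free.
    Fitting is by EM on the raw values (no histogram binning, hence no
    bin-width sensitivity); with fixed components each EM update is a
    closed-form responsibility average and the likelihood ascent is
    monotone.

    A degenerate calibration (``sigma1 = 0``) is floored at
    ``0.05 * mu1`` so the component densities stay proper.
    """
    x = np.asarray(brightnesses, dtype=float)
    if x.size < min_particles:
        raise ValueError(
            f"need at least {min_particles} brightness values, got {x.size}"
        )
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    sigma1 = calib.sigma1 if calib.sigma1 > 0 else 0.05 * calib.mu1

    j = np.arange(1, max_n + 1)
    means = j * calib.mu1
    sds = np.sqrt(j) * sigma1
    logpdf = stats.norm.logpdf(x[:, None], means[None, :], sds[None, :])

    w = np.full(max_n, 1.0 / max_n)
    prev = -np.inf
    for _ in range(max_iter):
        lw = logpdf + np.log(np.clip(w, 1e-300, None))[None, :]
        m = lw.max(axis=1, keepdims=True)
        pe = np.exp(lw - m)
        tot = pe.sum(axis=1, keepdims=True)
        ll = float((np.log(tot) + m).sum())
        w = (pe / tot).mean(axis=0)
        if ll - prev < tol * max(1.0, abs(ll)):
            prev = ll
            break
        prev = ll
    w = np.clip(w, 0.0, None)
    w /= w.sum()
    return MixtureResult(
        max_n=max_n,
        weights_observed=w,
        mu1=calib.mu1,
        sigma1=sigma1,
        log_likelihood=prev,
        n_particles=int(x.size),
    )


# ---------------------------------------------------------------------------
# partial-labeling correction


def binomial_projection_matrix(max_n: int, p: float) -> np.ndarray:
    """Matrix B with ``B[j-1, n-1] = C(n, j) p^j (1-p)^(n-j)``.

    Maps true n-mer fractions to the distribution of *labeled* counts
    over the visible classes ``j = 1..max_n`` (the invisible ``j = 0``
    row is omitted; a true n-mer goes dark with probability
    ``(1-p)^n``).
    """
    j = np.arange(1, max_n + 1)[:, None]
    n = np.arange(1, max_n + 1)[None, :]
    return stats.binom.pmf(j, n, p)


def correct_labeling(
    w_observed: np.ndarray,
    p: float,
    correct_invisible: bool = True,
) -> np.ndarray:
    """Invert binomial partial labeling: observed w_j -> true v_n.

    With labeling efficiency ``p``, a true n-mer shows ``j`` fluorescent
    units with probability ``C(n,j) p^j (1-p)^(n-j)``; particles with
    ``j = 0`` are invisible, so the observed fractions are the binomial
    projection of the true composition restricted to ``j >= 1`` and
    renormalized.  The projection is linear in ``v`` up to that overall
    normalization, so ``v`` is recovered by non-negative least squares
    against the projection matrix, then renormalized to the simplex.

    ``correct_invisible=True`` (default) returns the composition over
    *all* true n-mers, including those that carried no label;
    ``correct_invisible=False`` returns the composition among n-mers
    that had at least one labeled unit (each column of the projection
    matrix conditioned on visibility).

    ``p`` outside (0.75, 1] raises a warning — partial-labeling
    inversion degrades quickly at low efficiency — but proceeds.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError("labeling efficiency p must be in (0, 1]")
    if p <= 0.75:
        warnings.warn(
            f"labeling efficiency {p} is at or below 0.75; corrected fractions "
            "will be poorly conditioned",
            stacklevel=2,
        )
    w = np.asarray(w_observed, dtype=float)
    if np.any(w < 0):
        raise ValueError("observed weights must be non-negative")
    max_n = w.size
    B = binomial_projection_matrix(max_n, p)
    if not correct_invisible:
        visible = 1.0 - (1.0 - p) ** np.arange(1, max_n + 1)
        B = B / visible[None, :]
    v, _ = nnls(B, w)
    total = v.sum()
    if total <= 0:
        raise RuntimeError("labeling correction produced an all-zero solution")
    return v / total


def apply_labeling_correction(result: MixtureResult, p: float, **kwargs) -> MixtureResult:
    """Fill ``weights_corrected`` of a mixture result in place."""
    result.weights_corrected = correct_labeling(result.weights_observed, p, **kwargs)
    result.labeling_efficiency = p
    return result


# ---------------------------------------------------------------------------
# cross-experiment summary


def occurrence_summary(results: list[MixtureResult | np.ndarray], corrected: bool = False) -> pd.DataFrame:
    """Mean and SD percent occurrence per oligomer order across experiments.

    Accepts mixture results (uses observed weights, or corrected ones
    with ``corrected=True``) or bare weight arrays; shorter weight
    vectors are zero-padded to the longest, so orders absent from an
    experiment count as 0%. A single experiment reports SD = 0.
    """
    if not results:
        raise ValueError("at least one result is required")
    vectors = []
    for r in results:
        if isinstance(r, MixtureResult):
            w = r.weights_corrected if corrected else r.weights_observed
            if w is None:
                raise ValueError("corrected weights requested but not computed")
        else:
            w = np.asarray(r, dtype=float)
        vectors.append(w)
    width = max(v.size for v in vectors)
    mat = np.zeros((len(vectors), width))
    for i, v in enumerate(vectors):
        mat[i, : v.size] = v
    mean = 100.0 * mat.mean(axis=0)
    sd = 100.0 * (mat.std(axis=0, ddof=1) if mat.shape[0] > 1 else np.zeros(width))
    return pd.DataFrame(
        {"n": np.arange(1, width + 1), "mean_percent": mean, "sd_percent": sd}
    )
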