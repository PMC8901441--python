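"""Synthetic single-molecule microscopy data with known ground truth.

Every generator in this module emulates one of the experimental regimes
of the BAX/BAK stoichiometry workflow and returns, next to the simulated
data, a complete truth ledger so that downstream stages (spot detection,
brightness decomposition, ratiometric kinetics) can be validated by
parameter recovery:

* :func:`generate_particle_field` — a TIRF-like field of diffraction-
  limited spots: n-mers with binomial partial labeling, Gaussian PSF,
  Poisson shot noise and Gaussian read noise.
* :func:`generate_bleach_traces` — stepwise photobleaching intensity
  traces for monomer calibration.
* :func:`generate_standard_cells` — per-cell intensity samples of a
  counting standard of known stoichiometry (e.g. the 32-mer Nup96
  nuclear pore complex).
* :func:`generate_foci_timeseries` — MOMP-aligned foci molecularity time
  series in a fast-saturating (BAK-like) or unbounded linear (BAX-like)
  growth regime.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ImageStack
from .kinetics import FociTimeSeries

__all__ = [
    "SimConfig",
    "KineticModel",
    "BleachTraceSet",
    "generate_particle_field",
    "generate_bleach_traces",
    "generate_standard_cells",
    "generate_foci_timeseries",
]

#: Columns of the ground-truth particle table.
TRUTH_COLUMNS = ["particle", "row", "col", "n_true", "j_labeled", "brightness", "visible"]


@dataclass
class SimConfig:
    """Parameters of a simulated single-molecule imaging field.

    The defaults emulate TIRF acquisition of supported-lipid-bilayer
    samples: 100 nm pixels, a ~1.3 px Gaussian PSF and a labeling
    efficiency in the 0.75–0.85 range typical of maleimide dye coupling.

    Attributes
    ----------
    field_size_px:
        (rows, cols) of the simulated frame.
    pixel_size_nm:
        Lateral pixel size (metadata only; the PSF is given in pixels).
    psf_sigma_px:
        Standard deviation of the isotropic 2-D Gaussian PSF, pixels.
    monomer_intensity:
        Mean integrated brightness of one labeled fluorophore (mu1),
        counts per frame.
    monomer_cv:
        Coefficient of variation of the single-fluorophore brightness
        (sigma1 / mu1, unitless).
    background_level:
        Uniform background, counts per pixel.
    read_noise_sd:
        Additive Gaussian camera noise, counts; 0 disables it.
    labeling_efficiency:
        Probability ``p`` that a protomer carries a functional
        fluorophore; labeled counts are Binomial(n, p).
    nmer_weights:
        Mapping oligomer order ``n`` -> probability; must sum to 1.
    n_particles:
        Number of particles placed in the field.
    shot_noise:
        Apply Poisson noise to the noise-free image (True by default;
        disable for exact photon-conservation oracles).
    min_separation_px:
        Optional minimum center-to-center distance enforced by dart
        throwing; ``None`` places particles fully at random.
    edge_margin_px:
        Particle centers are kept this far from the frame edge so every
        PSF is rendered in full.
    seed:
        Seed of the generator's private random state.
    """

    field_size_px: tuple[int, int] = (200, 200)
    pixel_size_nm: float = 100.0
    psf_sigma_px: float = 1.3
    monomer_intensity: float = 500.0
    monomer_cv: float = 0.15
    background_level: float = 100.0
    read_noise_sd: float = 2.0
    labeling_efficiency: float = 0.8
    nmer_weights: dict[int, float] = field(default_factory=lambda: {1: 1.0})
    n_particles: int = 100
    shot_noise: bool = True
    min_separation_px: float | None = None
    edge_margin_px: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.labeling_efficiency <= 1.0):
            raise ValueError("labeling_efficiency must be in (0, 1]")
        total = sum(self.nmer_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"nmer_weights must sum to 1, got {total}")
        if any(n < 1 or n != int(n) for n in self.nmer_weights):
            raise ValueError("oligomer orders must be positive integers")
        if any(w < 0 for w in self.nmer_weights.values()):
            raise ValueError("nmer_weights must be non-negative")
        for name in ("psf_sigma_px", "monomer_intensity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("monomer_cv", "background_level", "read_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_particles < 0:
            raise ValueError("n_particles must be non-negative")


@dataclass
class KineticModel:
    """Growth law of apoptotic foci molecularity after MOMP.

    ``saturating`` mode follows M(t) = plateau * (1 - exp(-t/tau)) with
    tau = plateau / rate (so ``rate`` is the initial growth speed) and a
    constant focus birth rate — the BAK-like regime that stalls at a
    stable oligomer size.  ``linear`` mode follows M(t) = rate * t with
    a linearly increasing birth rate — the BAX-like regime of unbounded
    focus growth and accelerating nucleation.

    Per-focus molecularities are the mean trajectory times a unit-mean
    multiplicative Gamma factor with coefficient of variation
    ``noise_cv``. The default ``noise_cv = 1`` makes the per-timepoint
    molecularity distribution exponential — the broad, right-skewed
    shape cellular foci intensity distributions show, and the shape the
    survival-count analysis (exponential decay fitting) presumes.
    """

    mode: str = "saturating"
    plateau: float = 200.0
    rate: float = 20.0
    onset_lag_min: float = 0.0
    noise_cv: float = 1.0
    foci_birth_rate: float = 2e-4  # foci / (px^2 * min) at unit time scale

    def validate(self) -> None:
        if self.mode not in ("saturating", "linear"):
            raise ValueError(f"unknown kinetic mode {self.mode!r}")
        if self.mode == "saturating" and self.plateau <= 0:
            raise ValueError("plateau must be positive in saturating mode")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.noise_cv < 0 or self.foci_birth_rate < 0:
            raise ValueError("noise_cv and foci_birth_rate must be non-negative")

    def mean_molecularity(self, t_min: np.ndarray | float) -> np.ndarray:
        """Noise-free mean molecularity at time ``t_min`` after MOMP."""
        t = np.maximum(np.asarray(t_min, dtype=float) - self.onset_lag_min, 0.0)
        if self.mode == "saturating":
            tau = self.plateau / self.rate
            return self.plateau * (1.0 - np.exp(-t / tau))
        return self.rate * t


def _render_gaussian_spots(
    shape: tuple[int, int],
    rows: np.ndarray,
    cols: np.ndarray,
    brightness: np.ndarray,
    sigma: float,
) -> np.ndarray:
    """Render spots as pixel-center-sampled 2-D Gaussians.

    Amplitude is brightness / (2*pi*sigma^2), so the analytic volume of
    each spot equals its brightness; sampling at pixel centers conserves
    that volume to ~1e-9 for sigma >= 1 px (Poisson summation), which
    makes noiseless photon-conservation checks exact to float tolerance.
    """
    img = np.zeros(shape, dtype=float)
    patch = int(math.ceil(6.0 * sigma)) + 1
    for r, c, b in zip(rows, cols, brightness):
        if b <= 0:
            continue
        r0, c0 = int(round(r)), int(round(c))
        rlo, rhi = max(r0 - patch, 0), min(r0 + patch + 1, shape[0])
        clo, chi = max(c0 - patch, 0), min(c0 + patch + 1, shape[1])
        rr = np.arange(rlo, rhi, dtype=float)[:, None]
        cc = np.arange(clo, chi, dtype=float)[None, :]
        amp = b / (2.0 * math.pi * sigma**2)
        img[rlo:rhi, clo:chi] += amp * np.exp(
            -((rr - r) ** 2 + (cc - c) ** 2) / (2.0 * sigma**2)
        )
    return img


def _draw_centers(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    margin: float,
    min_sep: float | None,
    max_tries: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    lo_r, hi_r = margin, shape[0] - 1 - margin
    lo_c, hi_c = margin, shape[1] - 1 - margin
    if hi_r <= lo_r or hi_c <= lo_c:
        raise ValueError("field too small for the requested edge margin")
    if min_sep is None:
        return rng.uniform(lo_r, hi_r, n), rng.uniform(lo_c, hi_c, n)
    rows: list[float] = []
    cols: list[float] = []
    for _ in range(n):
        for attempt in range(max_tries):
            r = rng.uniform(lo_r, hi_r)
            c = rng.uniform(lo_c, hi_c)
            if all((r - rr) ** 2 + (c - cc) ** 2 >= min_sep**2 for rr, cc in zip(rows, cols)):
                rows.append(r)
                cols.append(c)
                break
        else:
            raise RuntimeError(
                "could not place particles with the requested minimum separation"
            )
    return np.asarray(rows), np.asarray(cols)


def generate_particle_field(config: SimConfig) -> tuple[ImageStack, pd.DataFrame]:
    """Simulate one TIRF-like frame of partially labeled n-mers.

    Each particle is assigned an oligomer order ``n`` from
    ``config.nmer_weights`` and a labeled count ``j ~ Binomial(n, p)``.
    Its emitted brightness is the sum of ``j`` independent Normal(mu1,
    (cv*mu1)^2) monomer draws (clipped at 0), rendered as a 2-D Gaussian
    PSF on a uniform background; Poisson shot noise and Gaussian read
    noise are applied per pixel when enabled.

    Returns
    -------
    (stack, truth):
        A single-frame :class:`~smstoich.io.ImageStack` and a ground-
        truth table with columns ``particle, row, col, n_true,
        j_labeled, brightness, visible``.  Particles with ``j = 0``
        carry no fluorophore, emit nothing and are flagged
        ``visible=False``; they stay in the ledger so that labeling-
        efficiency corrections can be validated against the
        unobservable class.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.field_size_px)
    n = config.n_particles

    if n > 0:
        area = shape[0] * shape[1]
        # mean nearest-neighbour distance of a 2-D Poisson process
        mean_nn = 0.5 / math.sqrt(n / area)
        if mean_nn < 4.0 * config.psf_sigma_px:
            warnings.warn(
                f"particle density {n / area:.3g}/px^2 implies mean nearest-neighbor "
                f"distance {mean_nn:.2f} px < 4*psf_sigma; spots will overlap heavily",
                stacklevel=2,
            )

    rows, cols = _draw_centers(
        rng, n, shape, config.edge_margin_px, config.min_separation_px
    )
    orders = np.array(sorted(config.nmer_weights), dtype=int)
    probs = np.array([config.nmer_weights[k] for k in orders], dtype=float)
    probs = probs / probs.sum()
    n_true = rng.choice(orders, size=n, p=probs) if n else np.empty(0, dtype=int)
    j_labeled = rng.binomial(n_true, config.labeling_efficiency) if n else np.empty(0, dtype=int)

    sigma1 = config.monomer_cv * config.monomer_intensity
    brightness = np.zeros(n)
    for i, j in enumerate(j_labeled):
        if j > 0:
            draws = rng.normal(config.monomer_intensity, sigma1, size=int(j))
            brightness[i] = np.clip(draws, 0.0, None).sum()

    ideal = _render_gaussian_spots(shape, rows, cols, brightness, config.psf_sigma_px)
    ideal += config.background_level
    if config.shot_noise:
        image = rng.poisson(ideal).astype(float)
    else:
        image = ideal.copy()
    if config.read_noise_sd > 0:
        image = image + rng.normal(0.0, config.read_noise_sd, size=shape)
    image = np.clip(image, 0.0, None)

    truth = pd.DataFrame(
        {
            "particle": np.arange(n, dtype=int),
            "row": rows,
            "col": cols,
            "n_true": n_true,
            "j_labeled": j_labeled,
            "brightness": brightness,
            "visible": j_labeled > 0,
        },
        columns=TRUTH_COLUMNS,
    )
    stack = ImageStack(image, pixel_size_nm=config.pixel_size_nm, channel="sim")
    return stack, truth


@dataclass
class BleachTraceSet:
    """Simulated photobleaching traces plus their truth table.

    ``traces`` has shape ``(n_traces, frames)``; ``truth`` has one row
    per trace with columns ``trace, j_fluors, steps_in_window,
    initial_level`` where ``steps_in_window`` counts fluorophores that
    bleached inside the recorded window.
    """

    traces: np.ndarray
    truth: pd.DataFrame
    monomer_intensity: float


def generate_bleach_traces(
    j_fluors: int,
    n_traces: int,
    bleach_prob_per_frame: float,
    frames: int,
    noise_sd: float,
    seed: int,
    monomer_intensity: float = 100.0,
    monomer_cv: float = 0.0,
    baseline: float = 0.0,
) -> BleachTraceSet:
    """Simulate stepwise photobleaching intensity traces.

    Each of ``j_fluors`` fluorophores gets an i.i.d. brightness draw
    Normal(mu1, (cv*mu1)^2) and a geometric bleaching frame (success
    probability ``bleach_prob_per_frame``, support starting at frame 1);
    the trace at frame t is the summed brightness of the fluorophores
    still alive, plus Gaussian noise.  Blinking is not modeled: at the
    short exposures used for step counting, irreversible bleaching
    dominates.
    """
    if j_fluors < 1:
        raise ValueError("j_fluors must be >= 1")
    if frames < 10:
        raise ValueError("at least 10 frames are required")
    if not (0.0 < bleach_prob_per_frame <= 1.0):
        raise ValueError("bleach_prob_per_frame must be in (0, 1]")
    rng = np.random.default_rng(seed)
    sigma1 = monomer_cv * monomer_intensity

    traces = np.empty((n_traces, frames))
    j_col = np.full(n_traces, j_fluors, dtype=int)
    steps = np.empty(n_traces, dtype=int)
    init = np.empty(n_traces)
    t = np.arange(frames)
    for i in range(n_traces):
        amps = np.clip(rng.normal(monomer_intensity, sigma1, j_fluors), 0.0, None)
        bleach_at = rng.geometric(bleach_prob_per_frame, j_fluors)  # frame of loss, >= 1
        alive = t[None, :] < bleach_at[:, None]
        clean = baseline + (amps[:, None] * alive).sum(axis=0)
        steps[i] = int(np.count_nonzero(bleach_at <= frames - 1))
        init[i] = clean[0]
        traces[i] = clean + (rng.normal(0.0, noise_sd, frames) if noise_sd > 0 else 0.0)

    truth = pd.DataFrame(
        {
            "trace": np.arange(n_traces, dtype=int),
            "j_fluors": j_col,
            "steps_in_window": steps,
            "initial_level": init,
        }
    )
    return BleachTraceSet(traces=traces, truth=truth, monomer_intensity=monomer_intensity)


def generate_standard_cells(
    Ms: int,
    n_cells: int,
    n_complexes_per_cell: int,
    unit_intensity: float,
    cv: float,
    seed: int,
) -> list[np.ndarray]:
    """Simulate per-cell intensity samples of a counting standard.

    Each complex intensity is drawn from Normal(Ms * unit_intensity,
    (cv * Ms * unit_intensity)^2), truncated at zero — an idealization
    of the brightness distribution of e.g. Nup96-mEGFP nuclear pore
    complexes (Ms = 32) within one cell.
    """
    if Ms < 1:
        raise ValueError("Ms must be >= 1")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    mean = Ms * unit_intensity
    sd = cv * mean
    cells = []
    for _ in range(n_cells):
        vals = rng.normal(mean, sd, n_complexes_per_cell) if sd > 0 else np.full(
            n_complexes_per_cell, mean
        )
        cells.append(np.clip(vals, 0.0, None))
    return cells


def generate_foci_timeseries(
    model: KineticModel,
    timepoints_min: np.ndarray | list[float],
    mito_area_px2: float,
    seed: int,
) -> FociTimeSeries:
    """Simulate a MOMP-aligned foci molecularity time series.

    Foci are born by a Poisson process over the observation window —
    at constant rate ``model.foci_birth_rate`` per unit mitochondrial
    area in saturating mode, at a linearly increasing rate (same time-
    averaged total) in linear mode — and every focus alive at time t
    has molecularity ``model.mean_molecularity(t)`` times a persistent
    unit-mean Gamma factor with CV ``model.noise_cv``.

    The returned series carries the noise-free mean trajectory in
    ``truth_mean`` for recovery tests.
    """
    model.validate()
    tp = np.asarray(timepoints_min, dtype=float)
    if tp.size == 0:
        raise ValueError("timepoints must be non-empty")
    if np.any(np.diff(tp) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    if tp[0] < 0:
        raise ValueError("timepoints must start at or after MOMP (t >= 0)")
    rng = np.random.default_rng(seed)

    t_max = float(tp[-1])
    expected = model.foci_birth_rate * mito_area_px2 * t_max
    n_foci = int(rng.poisson(expected)) if expected > 0 else 0
    if model.mode == "saturating":
        birth = rng.uniform(0.0, t_max, n_foci)
    else:
        # birth rate proportional to t  ->  birth times ~ sqrt(U) * t_max
        birth = t_max * np.sqrt(rng.uniform(0.0, 1.0, n_foci))

    if model.noise_cv > 0 and n_foci > 0:
        k = 1.0 / model.noise_cv**2
        factor = rng.gamma(k, 1.0 / k, n_foci)
    else:
        factor = np.ones(n_foci)

    molecularities = []
    for t in tp:
        alive = birth <= t
        m = model.mean_molecularity(t) * factor[alive]
        molecularities.append(m[m > 0])
    truth_mean = model.mean_molecularity(tp)
    return FociTimeSeries(
        timepoints_min=tp,
        molecularities=molecularities,
        mito_area=mito_area_px2,
        truth_mean=truth_mean,
    )
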