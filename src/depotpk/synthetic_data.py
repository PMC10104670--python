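"""Synthetic inputs with the statistical structure of the real assays.

Two generators, both pure functions of their spec and a mandatory seed:

* :func:`generate_release_data` — cumulative-release observations on the
  in-vitro sampling schedule (daily for four days, then days 7/14/21/28)
  with additive Gaussian measurement noise, emulating technical-triplicate
  supernatant reads.  Noisy cumulative curves are deliberately NOT
  re-monotonised: real replicate scatter produces small inversions.
* :func:`generate_micrograph` — a grayscale field of bright, anti-aliased,
  non-overlapping disks with log-normal diameters on a noisy background,
  emulating an SEM micrograph of microparticles, together with its
  ground-truth diameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .estimation import PAPER_SCHEDULE_H, ReleaseDataset
from .formulation import ValidationError
from .release_kinetics import ReleaseModel, ReleaseParams, cumulative_release

DEFAULT_SCHEDULE_H = PAPER_SCHEDULE_H


@dataclass(frozen=True)
class ReleaseNoiseModel:
    """Additive Gaussian noise on the cumulative fraction readout."""

    sd_additive: float = 0.01
    truncate_nonneg: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_additive < 0:
            raise ValidationError("sd_additive must be non-negative")


@dataclass(frozen=True)
class MicrographSpec:
    """Layout of a synthetic particle micrograph.

    Diameters are log-normal: ``median_diameter_um`` is the geometric mean
    and ``geometric_sd`` (≥ 1) the geometric standard deviation.
    ``min_separation`` is the minimum edge-to-edge gap between disks in
    pixels.
    """

    image_size: int = 512              # pixels (square)
    n_particles: int = 50
    median_diameter_um: float = 6.0
    geometric_sd: float = 1.2
    pixel_size: float = 0.05           # µm per pixel
    background_noise_sd: float = 0.02  # intensity units on [0, 1]
    min_separation: float = 3.0        # px
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 0:
            raise ValidationError("n_particles must be non-negative")
        if self.geometric_sd < 1.0:
            raise ValidationError("geometric_sd must be >= 1")
        if self.min_separation < 0:
            raise ValidationError("min_separation must be non-negative")
        if self.pixel_size <= 0 or self.median_diameter_um <= 0:
            raise ValidationError("sizes must be positive")


def median_for_d43(d43_um: float, geometric_sd: float) -> float:
    """Log-normal median whose population D[4,3] equals ``d43_um``.

    For d ~ logN(µ, σ²), E[d⁴]/E[d³] = exp(µ + 3.5 σ²), so the median is
    d43 · exp(−3.5 σ²) with σ = ln(geometric_sd).
    """
    sigma = math.log(geometric_sd)
    return d43_um * math.exp(-3.5 * sigma * sigma)


def generate_release_data(
    params: ReleaseParams | ReleaseModel,
    schedule=DEFAULT_SCHEDULE_H,
    noise: ReleaseNoiseModel = ReleaseNoiseModel(),
    n_replicates: int = 3,
) -> ReleaseDataset:
    """Noisy cumulative-release observations on a sampling schedule.

    Each replicate is the model curve evaluated at the schedule plus i.i.d.
    additive Gaussian noise, truncated at zero (a concentration read cannot
    be negative).  Deterministic given ``noise.seed``.
    """
    model = params if isinstance(params, ReleaseModel) else ReleaseModel(params)
    t = np.asarray(schedule, dtype=float)
    if t.size == 0 or np.any(np.diff(t) <= 0):
        raise ValidationError("schedule must be non-empty and strictly increasing")
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    clean = cumulative_release(model, t)
    rng = np.random.default_rng(noise.seed)
    obs = np.tile(clean, n_replicates) + rng.normal(
        0.0, noise.sd_additive, size=t.size * n_replicates
    )
    if noise.truncate_nonneg:
        obs = np.maximum(obs, 0.0)
    obs = np.minimum(obs, 1.05)  # keep within the measurable-overshoot band
    rep = np.repeat([f"rep{i}" for i in range(n_replicates)], t.size)
    return ReleaseDataset(
        times=np.tile(t, n_replicates),
        cumulative_fraction=obs,
        replicate_id=rep,
        noise_sd=noise.sd_additive,
    )


def _place_disks(
    rng: np.random.Generator, spec: MicrographSpec, radii_px: np.ndarray
) -> np.ndarray:
    """Non-overlapping centers by rejection sampling, largest disks first."""
    order = np.argsort(radii_px)[::-1]
    centers = np.full((radii_px.size, 2), np.nan)
    budget = 2000
    for idx in order:
        r = radii_px[idx]
        lo, hi = r + 1.0, spec.image_size - r - 1.0
        if hi <= lo:
            raise ValidationError(
                f"disk of radius {r:.1f} px does not fit in a "
                f"{spec.image_size} px image; use smaller particles"
            )
        placed = ~np.isnan(centers[:, 0])
        for _ in range(budget):
            c = rng.uniform(lo, hi, size=2)
            if not placed.any():
                centers[idx] = c
                break
            d = np.hypot(*(centers[placed] - c).T)
            if np.all(d >= radii_px[placed] + r + spec.min_separation):
                centers[idx] = c
                break
        else:
            raise ValidationError(
                "could not place all particles without overlap; "
                "use fewer or smaller particles or a larger image"
            )
    return centers


def _rasterize_disks(
    size: int, centers: np.ndarray, radii: np.ndarray, supersample: int = 4
) -> np.ndarray:
    """Anti-aliased binary disks via supersampled coverage averaging."""
    img = np.zeros((size, size))
    s = supersample
    for (cy, cx), r in zip(centers, radii):
        pad = int(math.ceil(r)) + 2
        y0, y1 = max(0, int(cy) - pad), min(size, int(cy) + pad + 1)
        x0, x1 = max(0, int(cx) - pad), min(size, int(cx) + pad + 1)
        # subpixel sample coordinates within the bounding box
        ys = (np.arange(y0 * s, y1 * s) + 0.5) / s
        xs = (np.arange(x0 * s, x1 * s) + 0.5) / s
        inside = (
            (ys[:, None] - cy) ** 2 + (xs[None, :] - cx) ** 2
        ) <= r * r
        cover = inside.reshape(y1 - y0, s, x1 - x0, s).mean(axis=(1, 3))
        img[y0:y1, x0:x1] = np.maximum(img[y0:y1, x0:x1], cover)
    return img


def generate_micrograph(spec: MicrographSpec) -> dict:
    """A synthetic micrograph plus its ground truth.

    Returns ``{"image", "ground_truth_diameters_um", "centers_px",
    "radii_px"}`` where the image is float64 in [0, 1] (bright particles on
    a dark noisy background).  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    sigma = math.log(spec.geometric_sd)
    diam_um = spec.median_diameter_um * np.exp(
        rng.normal(0.0, sigma, size=spec.n_particles)
    )
    radii_px = diam_um / (2.0 * spec.pixel_size)
    if spec.n_particles:
        centers = _place_disks(rng, spec, radii_px)
        img = _rasterize_disks(spec.image_size, centers, radii_px)
    else:
        centers = np.empty((0, 2))
        img = np.zeros((spec.image_size, spec.image_size))
    img = img + rng.normal(0.0, spec.background_noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return {
        "image": img,
        "ground_truth_diameters_um": diam_um,
        "centers_px": centers,
        "radii_px": radii_px,
    }
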