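"""Ground-truthed synthetic fixtures: phantom images and measurement cohorts.

No clinical images or measurement tables are distributed, so everything
downstream is exercised on synthetic data generated here:

* cross-section phantoms -- red discs, ellipses and lobed blobs on a dark
  or light background, with known minimum centre-passing width;
* scale-bar images for pixel-spacing calibration;
* paired manual/intelligent measurement cohorts whose per-site group
  medians and interquartile ranges match published reference values for
  infants with and without aortic coarctation.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import norm

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "generate_cross_section",
    "generate_scale_bar",
    "simulate_cohort",
    "SITES",
    "MANUAL_MEDIAN_IQR",
    "DIFFERENCE_MEDIAN_IQR",
]

SITES = ("AOA", "D1", "D2", "D3", "DA")

# Per-site (median, q1, q3) of the manual minimum diameter, mm.
MANUAL_MEDIAN_IQR: dict[str, dict[str, tuple[float, float, float]]] = {
    "coa": {
        "AOA": (9.3, 8.0, 10.5),
        "D1": (5.7, 5.1, 6.7),
        "D2": (5.0, 4.2, 5.9),
        "D3": (2.4, 1.9, 3.4),
        "DA": (6.5, 5.7, 7.7),
    },
    "control": {
        "AOA": (11.7, 9.8, 15.7),
        "D1": (9.7, 7.8, 14.3),
        "D2": (8.9, 7.1, 13.7),
        "D3": (8.4, 6.9, 12.9),
        "DA": (7.8, 6.4, 11.8),
    },
}

# Per-site (median, q1, q3) of the paired difference manual - intelligent, mm.
DIFFERENCE_MEDIAN_IQR: dict[str, dict[str, tuple[float, float, float]]] = {
    "coa": {
        "AOA": (0.12, -0.24, 0.72),
        "D1": (-0.65, -1.45, 0.12),
        "D2": (-0.03, -0.40, 0.42),
        "D3": (-0.14, -0.40, 0.20),
        "DA": (0.15, -0.22, 0.49),
    },
    "control": {
        "AOA": (-0.55, -1.30, -0.13),
        "D1": (-0.46, -1.24, 0.08),
        "D2": (-0.38, -0.65, 0.20),
        "D3": (-0.21, -0.58, 0.22),
        "DA": (-0.46, -0.91, 0.23),
    },
}

_Z75 = norm.ppf(0.75)  # quartile z-score linking IQR to a normal sigma


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic lumen cross-section.

    ``a`` and ``b`` are semi-axes in pixels (equal for a disc); ``rotation``
    is in degrees.  ``noise_sd`` adds per-pixel Gaussian intensity noise;
    ``edge_sigma`` > 0 softens the lumen edge (anti-aliasing is off by
    default so masks are crisp).  Blobs perturb a disc's radius with a few
    random cosine lobes of relative amplitude ``blob_irregularity``.
    """

    shape: str = "disc"
    a: float = 50.0
    b: float = 50.0
    rotation: float = 0.0
    fill_rgb: tuple[int, int, int] = (255, 0, 0)
    background_rgb: tuple[int, int, int] = (0, 0, 0)
    noise_sd: float = 0.0
    edge_sigma: float = 0.0
    width: int = 201
    height: int = 201
    seed: int = 0
    blob_irregularity: float = 0.12
    blob_lobes: int = 5

    def __post_init__(self) -> None:
        if self.shape not in ("disc", "ellipse", "blob"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if not (self.a > 0 and self.b > 0):
            raise ValueError("semi-axes must be positive")
        if self.noise_sd < 0 or self.edge_sigma < 0:
            raise ValueError("noise_sd and edge_sigma must be >= 0")
        margin = 1.0 + (self.blob_irregularity if self.shape == "blob" else 0.0)
        if 2 * max(self.a, self.b) * margin >= min(self.width, self.height) - 2:
            raise ValueError(
                f"shape with semi-axes ({self.a}, {self.b}) does not fit the "
                f"{self.width}x{self.height} canvas"
            )


def _blob_radius(theta: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    amp = rng.uniform(0.3, 1.0, spec.blob_lobes)
    amp *= spec.blob_irregularity / amp.sum()
    phase = rng.uniform(0, 2 * np.pi, spec.blob_lobes)
    k = np.arange(2, spec.blob_lobes + 2)
    pert = np.sum(amp[:, None] * np.cos(k[:, None] * theta[None, :] + phase[:, None]), axis=0)
    return spec.a * (1.0 + pert)


def generate_cross_section(spec: PhantomSpec) -> tuple[np.ndarray, float]:
    """Render a phantom and return ``(image, true_min_diameter_px)``.

    The true value is the minimum centre-passing width of the continuous
    shape: 2*min(a, b) for discs and ellipses (the minor axis is invariant
    under rotation), and the minimum of r(theta) + r(theta + pi) over a
    dense angle grid for blobs.  The image is (height, width, 3) uint8.
    """
    rng = np.random.default_rng(spec.seed)
    cx, cy = (spec.width - 1) / 2.0, (spec.height - 1) / 2.0
    ys, xs = np.mgrid[0 : spec.height, 0 : spec.width]
    dx, dy = xs - cx, ys - cy

    if spec.shape in ("disc", "ellipse"):
        phi = np.deg2rad(spec.rotation)
        u = dx * np.cos(phi) + dy * np.sin(phi)
        v = -dx * np.sin(phi) + dy * np.cos(phi)
        inside = (u / spec.a) ** 2 + (v / spec.b) ** 2 <= 1.0
        truth = 2.0 * min(spec.a, spec.b)
    else:
        theta_grid = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
        # A dedicated generator for the radius profile keeps the profile
        # independent of how many noise samples are drawn later.
        r_of = _blob_radius(theta_grid, spec, np.random.default_rng(spec.seed))
        theta = np.arctan2(dy, dx) % (2 * np.pi)
        idx = np.round(theta / (2 * np.pi) * theta_grid.size).astype(int) % theta_grid.size
        inside = np.hypot(dx, dy) <= r_of[idx]
        half = theta_grid.size // 2
        truth = float(np.min(r_of + np.roll(r_of, half)))

    alpha = inside.astype(float)
    if spec.edge_sigma > 0:
        alpha = ndimage.gaussian_filter(alpha, spec.edge_sigma)
    fill = np.array(spec.fill_rgb, dtype=float)
    bg = np.array(spec.background_rgb, dtype=float)
    img = bg[None, None, :] * (1.0 - alpha[..., None]) + fill[None, None, :] * alpha[..., None]
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8), truth


def generate_scale_bar(
    length_mm: float,
    length_px: int,
    *,
    thickness_px: int = 7,
    margin_px: int = 10,
) -> tuple[np.ndarray, dict]:
    """A horizontal white bar of exactly ``length_px`` foreground pixels.

    Returns the image and a metadata dict recording the physical length;
    the metadata is what downstream calibration consumes.
    """
    if not (length_mm > 0 and length_px > 0):
        raise ValueError("scale-bar lengths must be positive")
    length_px = int(length_px)
    h = thickness_px + 2 * margin_px
    w = length_px + 2 * margin_px
    img = np.zeros((h, w, 3), dtype=np.uint8)
    img[margin_px : margin_px + thickness_px, margin_px : margin_px + length_px] = 255
    return img, {"length_mm": float(length_mm), "length_px": length_px}


def _lognormal_params(median: float, q1: float, q3: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given median and quartiles."""
    mu = np.log(median)
    sigma = (np.log(q3) - np.log(q1)) / (2.0 * _Z75)
    return mu, sigma


def _normal_params(median: float, q1: float, q3: float) -> tuple[float, float]:
    return median, (q3 - q1) / (2.0 * _Z75)


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a paired manual/intelligent measurement cohort.

    Manual diameters are drawn log-normally per group and site (log-normal
    keeps diameters positive and maps medians cleanly); the intelligent
    value is the manual value minus an additive Gaussian paired difference.
    Defaults reproduce the reference group sizes (53 coarctation, 40
    control) and the published median/IQR targets.  Weights are uniform on
    [2, 12] kg -- all coarctation subjects are infants under one year.
    """

    n_coa: int = 53
    n_control: int = 40
    manual: Mapping[str, Mapping[str, tuple[float, float, float]]] = field(
        default_factory=lambda: MANUAL_MEDIAN_IQR
    )
    difference: Mapping[str, Mapping[str, tuple[float, float, float]]] = field(
        default_factory=lambda: DIFFERENCE_MEDIAN_IQR
    )
    weight_range_kg: tuple[float, float] = (2.0, 12.0)
    min_diameter_mm: float = 0.05  # positivity floor after the paired difference
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_coa < 0 or self.n_control < 0:
            raise ValueError("group sizes must be >= 0")
        for group in ("coa", "control"):
            for site in SITES:
                m, q1, q3 = self.manual[group][site]
                if not (0 < q1 <= m <= q3):
                    raise ValueError(f"invalid manual quartiles for {group}/{site}")
                d, d1, d3 = self.difference[group][site]
                if not (d1 <= d <= d3):
                    raise ValueError(f"invalid difference quartiles for {group}/{site}")


COHORT_COLUMNS = ["subject_id", "group", "weight_kg", "method", "site", "diameter_mm"]


def simulate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Simulate a paired-measurement cohort as a long-format table.

    One row per subject x site x method with columns
    ``subject_id, group, weight_kg, method, site, diameter_mm``; the group
    label doubles as the gold-standard diagnosis.  Sample medians converge
    to the configured medians as the group sizes grow.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    for group, n, prefix in (("coa", spec.n_coa, "coa"), ("control", spec.n_control, "ctl")):
        weights = rng.uniform(*spec.weight_range_kg, n)
        for i in range(n):
            sid = f"{prefix}_{i + 1:04d}"
            for site in SITES:
                mu, sigma = _lognormal_params(*spec.manual[group][site])
                manual = float(rng.lognormal(mu, sigma))
                loc, scale = _normal_params(*spec.difference[group][site])
                diff = float(rng.normal(loc, scale))
                intelligent = max(manual - diff, spec.min_diameter_mm)
                for method, value in (("manual", manual), ("intelligent", intelligent)):
                    rows.append(
                        {
                            "subject_id": sid,
                            "group": group,
                            "weight_kg": float(weights[i]),
                            "method": method,
                            "site": site,
                            "diameter_mm": value,
                        }
                    )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def default_cohort(seed: int = 0) -> pd.DataFrame:
    """The default 53 + 40 cohort under a given seed."""
    return simulate_cohort(replace(CohortSpec(), seed=seed))
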