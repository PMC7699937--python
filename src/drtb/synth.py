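"""Synthetic stomatal micrographs with known ground truth.

Real stomata are spread over the epidermis with near-regular spacing; the
nearest-neighbour distances of a homogeneous 2-D Poisson point process are
exactly Rayleigh-distributed with sigma = 1 / sqrt(2 pi lambda), which is
the closed-form oracle this generator is built around. An optional
hard-core (minimum-separation) thinning emulates the one-cell-spacing rule
of stomatal development; pure Poisson is the default because the Rayleigh
law is exact there.

Rendered images place one elliptical blob per point — greenish, saturated
interior with a darker rim — on a brownish cuticle-like background textured
with low-frequency noise, optionally degraded by Gaussian defocus blur and
additive sensor noise. The colour contrast (high saturation / low red in
the blobs) is what the preprocessing ratio exploits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as _draw_ellipse

logger = logging.getLogger(__name__)

__all__ = ["PointPatternParams", "RenderParams", "sample_poisson_points",
           "render_stomata_image", "planted_band_image", "get_preset",
           "preset_scan_config", "PRESETS"]


@dataclass(frozen=True)
class PointPatternParams:
    """Homogeneous Poisson point pattern.

    intensity : expected points per px^2 (lambda).
    width, height : canvas size in px.
    min_separation : hard-core radius in px; points closer than this to an
        already accepted point are discarded (0 disables thinning).
    margin : keep-out band from the canvas border, px.
    seed : RNG seed.
    """

    intensity: float
    width: int
    height: int
    min_separation: float = 0.0
    margin: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intensity <= 0:
            raise ValueError("intensity must be > 0")
        if self.min_separation < 0 or self.margin < 0:
            raise ValueError("min_separation and margin must be >= 0")
        if self.width < 1 or self.height < 1:
            raise ValueError("canvas must be at least 1 x 1")


@dataclass(frozen=True)
class RenderParams:
    """Stomata-like blob rendering.

    semi_major, semi_minor : (low, high) px ranges of the ellipse semi-axes.
    orientation : (low, high) radians range of the ellipse rotation.
    fg_color, rim_color, bg_color : RGB triples in [0,1]. The defaults give
        the blobs high saturation and low red response relative to the
        cuticle-like background, the contrast the preprocessing ratio uses.
    color_jitter : sd of a per-blob RGB offset (0 = identical blob colors).
    texture_amplitude : relative sd of the low-frequency multiplicative
        illumination field (multiplicative, so it leaves saturation alone).
    texture_scale : correlation length of the illumination field, px.
    defocus_sigma : Gaussian blur emulating out-of-focus optics, px.
    noise_sd : additive Gaussian sensor noise sd.
    seed : RNG seed (independent of the point-pattern seed).
    """

    width: int
    height: int
    semi_major: tuple = (7.0, 8.5)
    semi_minor: tuple = (4.5, 5.5)
    orientation: tuple = (0.0, np.pi)
    fg_color: tuple = (0.20, 0.55, 0.28)
    rim_color: tuple = (0.30, 0.40, 0.24)
    bg_color: tuple = (0.55, 0.50, 0.44)
    color_jitter: float = 0.0
    texture_amplitude: float = 0.01
    texture_scale: float = 50.0
    defocus_sigma: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.semi_major) <= 0 or min(self.semi_minor) <= 0:
            raise ValueError("semi-axes must be > 0")
        for c in (self.fg_color, self.rim_color, self.bg_color):
            if not all(0.0 <= v <= 1.0 for v in c):
                raise ValueError("colors must be RGB triples in [0,1]")
        if self.defocus_sigma < 0 or self.noise_sd < 0:
            raise ValueError("defocus_sigma and noise_sd must be >= 0")


def sample_poisson_points(params: PointPatternParams) -> np.ndarray:
    """Sample a homogeneous Poisson pattern, optionally hard-core thinned.

    Returns an (n, 2) array of (x, y) coordinates. The count is
    Poisson(lambda * area) before thinning; thinning keeps points in
    generation order, rejecting any closer than ``min_separation`` to an
    already accepted point.
    """
    rng = np.random.default_rng(params.seed)
    w = params.width - 2 * params.margin
    h = params.height - 2 * params.margin
    if w <= 0 or h <= 0:
        raise ValueError("margin leaves no sampling area")
    expected = params.intensity * w * h
    if expected < 3:
        warnings.warn(
            f"expected point count {expected:.2f} < 3; tessellation of the "
            "pattern will likely be degenerate", stacklevel=2)
    n = rng.poisson(expected)
    pts = np.column_stack((
        rng.uniform(params.margin, params.margin + w, size=n),
        rng.uniform(params.margin, params.margin + h, size=n),
    ))
    if params.min_separation > 0 and n > 1:
        accepted = np.zeros(n, dtype=bool)
        min_sq = params.min_separation ** 2
        for i in range(n):
            kept = pts[accepted]
            if kept.size == 0 or np.min(
                    np.sum((kept - pts[i]) ** 2, axis=1)) >= min_sq:
                accepted[i] = True
        pts = pts[accepted]
    return pts


def render_stomata_image(points: np.ndarray,
                         params: RenderParams) -> np.ndarray:
    """Render one elliptical blob per point on a textured background.

    Returns an (height, width, 3) float RGB image in [0,1], deterministic
    given (points, params). Overlapping blobs are permitted (logged at
    DEBUG level).
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    h, w = params.height, params.width
    if points.size and (points[:, 0].max() >= w or points[:, 1].max() >= h
                        or points.min() < 0):
        raise ValueError("points must lie within the canvas")
    rng = np.random.default_rng(params.seed)

    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = params.bg_color
    tex = None
    if params.texture_amplitude > 0:
        tex = gaussian_filter(rng.standard_normal((h, w)),
                              params.texture_scale)
        sd = tex.std()
        tex = tex / sd * params.texture_amplitude if sd > 0 else None

    max_r = max(params.semi_major) + 2.0
    if points.shape[0] > 1:
        from scipy.spatial.distance import pdist
        n_close = int(np.sum(pdist(points) < 2 * max_r))
        if n_close:
            logger.debug("%d blob pairs overlap or touch", n_close)

    fg = np.asarray(params.fg_color)
    rim = np.asarray(params.rim_color)
    for x, y in points:
        a = rng.uniform(*params.semi_major)
        b = rng.uniform(*params.semi_minor)
        theta = rng.uniform(*params.orientation)
        jitter = (rng.normal(0.0, params.color_jitter, size=3)
                  if params.color_jitter > 0 else np.zeros(3))
        rr, cc = _draw_ellipse(y, x, b + 2.0, a + 2.0, rotation=theta,
                               shape=(h, w))
        img[rr, cc] = np.clip(rim + 0.5 * jitter, 0, 1)
        rr, cc = _draw_ellipse(y, x, b, a, rotation=theta, shape=(h, w))
        img[rr, cc] = np.clip(fg + jitter, 0, 1)

    if tex is not None:
        img = img * (1.0 + tex[..., None])

    if params.defocus_sigma > 0:
        img = gaussian_filter(
            img, (params.defocus_sigma, params.defocus_sigma, 0))
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def planted_band_image(width: int = 1000, height: int = 1000,
                       intensity: float = 2e-4, min_separation: float = 30.0,
                       seed: int = 0,
                       band: tuple = (0.55, 0.65)) -> tuple[np.ndarray, np.ndarray]:
    """Grey fixture whose blobs are separable only inside a known threshold
    band: background intensities stay strictly below ``band[0]`` (mid-grey
    plus clipped low-frequency texture) and blob interiors strictly above
    ``band[1]``, so thresholds inside the band segment exactly the planted
    blobs. Returns (image, planted (x, y) centers)."""
    lo, hi = band
    if not 0 < lo < hi < 1:
        raise ValueError("band must satisfy 0 < lo < hi < 1")
    pp = PointPatternParams(intensity=intensity, width=width, height=height,
                            min_separation=min_separation, margin=12.0,
                            seed=seed)
    pts = sample_poisson_points(pp)
    rng = np.random.default_rng(seed + 1)
    bg_mid = lo - 0.10
    tex = gaussian_filter(rng.standard_normal((height, width)), 60.0)
    sd = tex.std()
    if sd > 0:
        tex = tex / sd * 0.03
    img = np.clip(bg_mid + tex, bg_mid - 0.045, lo - 0.005)
    for x, y in pts:
        a = rng.uniform(6.0, 9.0)
        b = rng.uniform(4.0, 6.0)
        theta = rng.uniform(0.0, np.pi)
        level = rng.uniform(hi + 0.01, min(hi + 0.09, 0.99))
        rr, cc = _draw_ellipse(y, x, b, a, rotation=theta,
                               shape=(height, width))
        img[rr, cc] = level
    return img, pts


def _preset_defs(seed: int) -> dict:
    pp = dict(intensity=4e-4, width=700, height=700, min_separation=22.0,
              margin=15.0, seed=seed)
    rp = dict(width=700, height=700, seed=seed + 1)
    return {
        "clean": (PointPatternParams(**pp),
                  RenderParams(**rp, defocus_sigma=0.8, noise_sd=0.0,
                               color_jitter=0.0)),
        "noisy": (PointPatternParams(**pp),
                  RenderParams(**rp, defocus_sigma=1.5, noise_sd=0.02,
                               color_jitter=0.008, texture_amplitude=0.03)),
        "defocus": (PointPatternParams(**pp),
                    RenderParams(**rp, defocus_sigma=6.0, noise_sd=0.004,
                                 color_jitter=0.004)),
    }


PRESETS = ("clean", "noisy", "defocus")


def get_preset(name: str, seed: int = 0) -> tuple[PointPatternParams, RenderParams]:
    """Named fixture presets: ``clean`` (sharp, low noise), ``noisy``
    (stronger sensor noise and texture), ``defocus`` (heavy out-of-focus
    blur, the known failure mode of edge-based segmentation)."""
    defs = _preset_defs(seed)
    if name not in defs:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    return defs[name]


def preset_scan_config() -> dict:
    """Threshold-scan configuration matched to the preset fixture scale,
    as a config-dict fragment (usable as a YAML config or via
    ``RunConfig.from_dict``).

    At lambda = 4e-4 points/px^2 the mean Delaunay edge is ~57 px, so the
    Rayleigh parameter is searched in 20-150 px: spacings below ~20 px are
    not resolvable as distinct stomata at this scale. Likewise regions under
    30 px (well below the ~200 px of the smallest rendered stoma) are
    treated as speckle.
    """
    return {"drtb": {"sigma_grid": "20.0:150.0:0.5", "min_area": 30}}
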