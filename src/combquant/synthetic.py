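"""Seeded synthetic comb photographs with analytic ground truth.

Real frame photo sets are large and cannot ship with the package, so
the generator builds frame-like scenes with known answers: a hexagonal
cell lattice at configurable pitch, dark near-circular lumens with
bright wax walls wherever a region is declared uncapped, speckled
texture over capped regions, a smooth illumination gradient and pixel
noise on top.  Every uncapped centre and every per-class capped area is
known analytically, which is what lets detector recall/precision and
the end-to-end area pipeline be scored exactly.

Geometry conventions: flat-top hexagonal rows — neighbouring cells in a
row sit one pitch apart, alternate rows are offset by half a pitch and
spaced pitch * sqrt(3)/2 vertically, so every nearest-neighbour
distance equals the pitch.  All randomness (centre jitter, cap texture,
pixel noise) flows from a single generator derived from the scene seed;
the same seed reproduces the raster bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .colorimetry import luminance_to_srgb_grey
from .errors import InvalidSpecError
from .geometry import as_polygon, points_in_polygon
from .quantify import CAPPED_LABELS

__all__ = ["CombSceneSpec", "GroundTruth", "generate_comb_image", "default_fixture"]

UNCAPPED = "uncapped"
_VALID_LABELS = CAPPED_LABELS | {UNCAPPED}

Region = tuple[str, tuple[tuple[float, float], ...]]


@dataclass(frozen=True)
class CombSceneSpec:
    """Full parameterisation of one synthetic comb photograph.

    Luminance levels are CIELAB L* on [0, 100]; lengths are pixels.
    ``region_layout`` lists (label, polygon) pairs with labels in
    {capped_brood, capped_honey, uncapped}; lattice cells whose site
    falls in an uncapped polygon are rendered as dark lumens, cells in
    capped polygons as wax-cap texture.  ``illumination_gradient`` is
    (direction_degrees, amplitude_L): a linear ramp of the given
    peak-to-peak amplitude along the given direction.
    """

    width_px: int = 1200
    height_px: int = 800
    pitch_px: float = 18.0
    wall_width_px: float = 2.0
    lumen_radius_px: float = 6.5
    inner_margin_px: float = 40.0
    region_layout: tuple[Region, ...] = ()
    wall_L: float = 70.0
    lumen_L: float = 20.0
    cap_mean_L: float = 55.0
    cap_texture_sd: float = 6.0
    illumination_gradient: tuple[float, float] = (30.0, 10.0)
    noise_sd: float = 2.5
    jitter_sd: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise InvalidSpecError("image dimensions must be positive")
        if not self.lumen_radius_px < self.pitch_px / 2:
            raise InvalidSpecError("lumen radius must be below half the pitch")
        for name in ("wall_L", "lumen_L", "cap_mean_L"):
            if not 0 <= getattr(self, name) <= 100:
                raise InvalidSpecError(f"{name} must lie in [0, 100]")
        if self.cap_texture_sd < 0 or self.noise_sd < 0 or self.jitter_sd < 0:
            raise InvalidSpecError("spread parameters must be >= 0")
        m = self.inner_margin_px
        if 2 * m >= min(self.width_px, self.height_px):
            raise InvalidSpecError("inner margin leaves no comb area")
        for label, poly in self.region_layout:
            if label not in _VALID_LABELS:
                raise InvalidSpecError(f"unknown region label {label!r}")
            p = as_polygon(poly)  # raises for non-simple polygons
            minx, miny, maxx, maxy = p.bounds
            if (
                minx < m
                or miny < m
                or maxx > self.width_px - m
                or maxy > self.height_px - m
            ):
                raise InvalidSpecError(
                    f"{label} polygon extends outside the comb area"
                )

    @property
    def inner_corners(self) -> tuple[tuple[float, float], ...]:
        """Inner-frame quadrilateral, clockwise from top-left."""
        m = self.inner_margin_px
        w, h = self.width_px, self.height_px
        return ((m, m), (w - m, m), (w - m, h - m), (m, h - m))

    @property
    def calibrated_cell_inflate(self) -> float:
        """Inflation factor that makes a half-pitch disc match the lumen.

        The operator's calibration target: with radius_fraction 0.5 the
        base subtraction radius is pitch/2, so scaling it by
        lumen_radius / (pitch/2) makes each subtracted disc equal the
        true lumen disc.
        """
        return self.lumen_radius_px / (0.5 * self.pitch_px)


@dataclass(frozen=True)
class GroundTruth:
    """Analytic answers for one synthetic scene.

    true_capped_area_px2 maps each capped label to its polygon area
    minus the lumen discs of the uncapped cells rendered inside it;
    uncapped_centres are the rendered lumen centres (jitter included).
    """

    uncapped_centres: np.ndarray
    true_capped_area_px2: dict[str, float]
    gross_capped_area_px2: dict[str, float]
    n_uncapped_in_capped: dict[str, int]
    inner_corners: tuple[tuple[float, float], ...]
    pitch_px: float
    lumen_radius_px: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "uncapped_centres",
            np.asarray(self.uncapped_centres, dtype=np.float64).reshape(-1, 2),
        )


def _lattice_sites(spec: CombSceneSpec) -> np.ndarray:
    """Hexagonal lattice sites (x, y) inside the comb area."""
    m = spec.inner_margin_px
    p = spec.pitch_px
    row_step = p * np.sqrt(3.0) / 2.0
    half_cell = p / 2.0
    ys = np.arange(m + half_cell, spec.height_px - m - half_cell + 1e-9, row_step)
    sites = []
    for i, y in enumerate(ys):
        x0 = m + half_cell + (half_cell if i % 2 else 0.0)
        xs = np.arange(x0, spec.width_px - m - half_cell + 1e-9, p)
        sites.append(np.column_stack([xs, np.full_like(xs, y)]))
    if not sites:
        return np.empty((0, 2))
    return np.vstack(sites)


def generate_comb_image(spec: CombSceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a synthetic comb photograph and its analytic ground truth.

    Returns
    -------
    image : ndarray, shape (H, W, 3), uint8
        Grey sRGB raster (luminance replicated into three channels; the
        detector only consumes L*, so colour realism is out of scope).
    truth : GroundTruth
        Rendered uncapped centres and per-label capped areas.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    shape = (h, w)

    sites = _lattice_sites(spec)
    jitter = rng.normal(0.0, spec.jitter_sd, size=sites.shape)

    # classify lattice sites; uncapped takes precedence over capped
    uncapped_mask = np.zeros(len(sites), dtype=bool)
    for label, poly in spec.region_layout:
        if label == UNCAPPED:
            uncapped_mask |= points_in_polygon(sites, poly)
    uncapped_centres = (sites + jitter)[uncapped_mask]

    # base comb: bright wax walls inside the frame, darker wood outside
    canvas = np.full(shape, 0.6 * spec.wall_L, dtype=np.float64)
    m = int(round(spec.inner_margin_px))
    canvas[m : h - m, m : w - m] = spec.wall_L

    # wax-cap texture over capped polygons (low-pass speckle so that cap
    # texture stays below the Canny edge threshold)
    texture = ndi.gaussian_filter(rng.normal(0.0, 1.0, size=shape), 1.5)
    sd = texture.std()
    texture = texture * (spec.cap_texture_sd / sd if sd > 0 else 0.0)
    for label, poly in spec.region_layout:
        if label == UNCAPPED:
            continue
        arr = np.asarray(poly, dtype=np.float64)
        rr, cc = draw_polygon(arr[:, 1], arr[:, 0], shape=shape)
        canvas[rr, cc] = spec.cap_mean_L + texture[rr, cc]

    # uncapped cells: bright wall ring, then the dark lumen
    ring_r = spec.lumen_radius_px + spec.wall_width_px
    for x, y in uncapped_centres:
        rr, cc = draw_disk((y, x), ring_r, shape=shape)
        canvas[rr, cc] = spec.wall_L
        rr, cc = draw_disk((y, x), spec.lumen_radius_px, shape=shape)
        canvas[rr, cc] = spec.lumen_L

    # smooth illumination gradient, then sensor noise
    direction_deg, amplitude = spec.illumination_gradient
    if amplitude:
        theta = np.deg2rad(direction_deg)
        yy, xx = np.mgrid[0:h, 0:w]
        proj = xx * np.cos(theta) + yy * np.sin(theta)
        span = proj.max() - proj.min()
        if span > 0:
            canvas += amplitude * ((proj - proj.min()) / span - 0.5)
    if spec.noise_sd:
        canvas += rng.normal(0.0, spec.noise_sd, size=shape)
    canvas = np.clip(canvas, 0.0, 100.0)

    grey = luminance_to_srgb_grey(canvas)
    image = np.repeat(grey[..., None], 3, axis=2)

    # analytic capped areas: gross polygon area minus contained lumen discs
    lumen_area = np.pi * spec.lumen_radius_px**2
    gross: dict[str, float] = {label: 0.0 for label in CAPPED_LABELS}
    n_inside: dict[str, int] = {label: 0 for label in CAPPED_LABELS}
    for label, poly in spec.region_layout:
        if label == UNCAPPED:
            continue
        gross[label] += float(as_polygon(poly).area)
        if len(uncapped_centres):
            n_inside[label] += int(points_in_polygon(uncapped_centres, poly).sum())
    true_area = {
        label: gross[label] - n_inside[label] * lumen_area for label in CAPPED_LABELS
    }

    truth = GroundTruth(
        uncapped_centres=uncapped_centres,
        true_capped_area_px2=true_area,
        gross_capped_area_px2=gross,
        n_uncapped_in_capped=n_inside,
        inner_corners=spec.inner_corners,
        pitch_px=spec.pitch_px,
        lumen_radius_px=spec.lumen_radius_px,
    )
    return image, truth


# Canonical 1200 x 800 test scene: a brood slab on the left with an
# emerged (uncapped) band inside it, a honey block top-right with an
# uncapped patch, and a free uncapped band bottom-right.
_FIXTURE_LAYOUT: tuple[Region, ...] = (
    ("capped_brood", ((80.0, 240.0), (640.0, 240.0), (640.0, 740.0), (80.0, 740.0))),
    ("capped_honey", ((700.0, 80.0), (1140.0, 80.0), (1140.0, 380.0), (700.0, 380.0))),
    (UNCAPPED, ((300.0, 300.0), (460.0, 300.0), (460.0, 680.0), (300.0, 680.0))),
    (UNCAPPED, ((820.0, 140.0), (1000.0, 140.0), (1000.0, 320.0), (820.0, 320.0))),
    (UNCAPPED, ((680.0, 440.0), (1140.0, 440.0), (1140.0, 720.0), (680.0, 720.0))),
)


def default_fixture(seed: int = 0) -> CombSceneSpec:
    """The canonical seeded test scene (fixed layout, seeded noise).

    The layout, lattice and luminance constants are fixed; only the
    stochastic elements (jitter, texture, noise) vary with the seed, so
    different seeds give independent realisations of the same scene.
    """
    return CombSceneSpec(region_layout=_FIXTURE_LAYOUT, seed=int(seed))
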