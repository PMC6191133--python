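"""Uncapped-cell detection via the Hough gradient circle transform.

Uncapped comb cells read as dark, near-circular lumens ringed by bright
wax walls, which makes them the one cell class a detector can find
reliably across cameras and lighting.  Detection runs on the CIELAB L*
channel and follows the classic gradient variant of the circular Hough
transform:

1. thin edges from a Canny detector, gated by an *edge threshold*
   expressed on the 8-bit Sobel-magnitude scale (default 200, the
   customary value);
2. each edge pixel casts votes into a centre accumulator along its
   gradient line, at every candidate radius, in both directions;
3. accumulator peaks with at least *accumulator_threshold* votes
   (initial default 20) become circle centres, subject to a minimum
   centre-to-centre distance; the operator raises or lowers this
   sensitivity in fixed increments (default 2) until the segmentation
   looks right;
4. each centre's radius is the modal edge-pixel distance.

The median nearest-neighbour spacing of the accepted centres estimates
the lattice pitch; the per-cell subtraction radius is
``cell_inflate * radius_fraction * spacing``, where the inflation
factor is the operator's correction for wall thickness and cell-size
variation between apiaries.

Detection is fully deterministic: identical raster and parameters give
an identical result set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.feature import canny

from .errors import InsufficientDetectionsError, InvalidImageError

__all__ = [
    "DetectionParams",
    "CellDetectionSet",
    "detect_uncapped_cells",
    "step_sensitivity",
    "median_neighbour_spacing",
    "effective_cell_radius",
]

# L* lives on [0, 100]; gradient thresholds follow the 8-bit convention.
_L_TO_8BIT = 255.0 / 100.0


@dataclass(frozen=True)
class DetectionParams:
    """Tunable symbols of the uncapped-cell detector.

    Parameters
    ----------
    edge_threshold:
        Canny high threshold on the 8-bit Sobel gradient-magnitude
        scale.  Default 200.
    accumulator_threshold:
        Minimum number of edge votes for a circle centre; the
        operator-adjustable sensitivity.  Default 20 (initial value).
    threshold_step:
        Increment applied to the accumulator threshold per sensitivity
        adjustment.  Default 2.
    cell_inflate:
        Multiplicative inflation factor on the subtraction radius
        (wall thickness / cell-size correction).  Default 1.0.
    radius_fraction:
        Factor converting the median nearest-neighbour spacing to a
        base radius.  On a hexagonal lattice the spacing equals the
        cell pitch (one full diameter), so 0.5 gives non-overlapping
        per-cell discs; 1.0 uses the spacing itself as the radius.
        Default 0.5.
    expected_pitch_px:
        Prior on the lattice pitch used to derive any unset radius or
        distance bound; when None it defaults to image width / 80 at
        detection time.
    min_radius_px, max_radius_px:
        Candidate-circle radius bounds; default 0.25 x and 0.75 x the
        expected pitch.
    min_centre_distance_px:
        Minimum distance between accepted centres; default 0.6 x the
        expected pitch.
    canny_sigma:
        Gaussian smoothing applied before edge detection, px.
    """

    edge_threshold: float = 200.0
    accumulator_threshold: int = 20
    threshold_step: int = 2
    cell_inflate: float = 1.0
    radius_fraction: float = 0.5
    expected_pitch_px: float | None = None
    min_radius_px: float | None = None
    max_radius_px: float | None = None
    min_centre_distance_px: float | None = None
    canny_sigma: float = 1.4

    def __post_init__(self) -> None:
        if not self.edge_threshold > 0:
            raise ValueError("edge_threshold must be > 0")
        if self.accumulator_threshold < 1:
            raise ValueError("accumulator_threshold must be >= 1")
        if self.threshold_step < 1:
            raise ValueError("threshold_step must be >= 1")
        if not self.cell_inflate > 0:
            raise ValueError("cell_inflate must be > 0")
        if not 0 < self.radius_fraction <= 1:
            raise ValueError("radius_fraction must be in (0, 1]")
        if self.min_radius_px is not None and self.max_radius_px is not None:
            if not 0 <= self.min_radius_px < self.max_radius_px:
                raise ValueError("need 0 <= min_radius_px < max_radius_px")

    def resolve(self, image_width: int) -> "DetectionParams":
        """Fill unset pitch-derived bounds from the expected pitch prior."""
        pitch = self.expected_pitch_px or image_width / 80.0
        return replace(
            self,
            expected_pitch_px=pitch,
            min_radius_px=(
                self.min_radius_px if self.min_radius_px is not None else 0.25 * pitch
            ),
            max_radius_px=(
                self.max_radius_px if self.max_radius_px is not None else 0.75 * pitch
            ),
            min_centre_distance_px=(
                self.min_centre_distance_px
                if self.min_centre_distance_px is not None
                else 0.6 * pitch
            ),
        )


@dataclass(frozen=True)
class CellDetectionSet:
    """Detected uncapped-cell circles for one photo.

    centres : (N, 2) float array of (x, y) pixel coordinates (0-based,
        origin top-left, positions refer to pixel centres)
    detected_radii : (N,) per-circle radii from the radius histogram
    accumulator_threshold_used : sensitivity at which detection ran
    median_spacing_px : median nearest-neighbour centre distance, or
        None when fewer than two circles were found
    effective_radius_px : cell_inflate * radius_fraction * spacing, or
        None when the spacing is unavailable
    """

    centres: np.ndarray
    detected_radii: np.ndarray
    accumulator_threshold_used: int
    median_spacing_px: float | None = None
    effective_radius_px: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "centres", np.asarray(self.centres, dtype=np.float64).reshape(-1, 2)
        )
        object.__setattr__(
            self, "detected_radii", np.asarray(self.detected_radii, dtype=np.float64)
        )

    def __len__(self) -> int:
        return self.centres.shape[0]

    @property
    def spacing_available(self) -> bool:
        return self.median_spacing_px is not None


def median_neighbour_spacing(centres: np.ndarray) -> float:
    """Median of each centre's distance to its nearest other centre.

    Rotation- and translation-invariant, and equivariant under uniform
    scaling; on a perfect hexagonal lattice it equals the pitch.
    Raises :class:`InsufficientDetectionsError` for fewer than two
    centres.
    """
    pts = np.asarray(centres, dtype=np.float64).reshape(-1, 2)
    if pts.shape[0] < 2:
        raise InsufficientDetectionsError(
            f"need >= 2 centres to estimate spacing, got {pts.shape[0]}"
        )
    dists, _ = cKDTree(pts).query(pts, k=2)
    return float(np.median(dists[:, 1]))


def effective_cell_radius(median_spacing_px: float, params: DetectionParams) -> float:
    """Per-cell subtraction radius from the estimated lattice spacing."""
    if not median_spacing_px > 0:
        raise ValueError(f"median spacing must be > 0, got {median_spacing_px}")
    return params.cell_inflate * params.radius_fraction * float(median_spacing_px)


def step_sensitivity(
    params: DetectionParams,
    direction: Literal["increase_detections", "decrease_detections"],
) -> DetectionParams:
    """One operator adjustment of the accumulator sensitivity.

    A lower accumulator threshold admits weaker peaks and therefore
    *more* detections.  The threshold is clamped at 1 (with a warning)
    since a non-positive vote count is meaningless.
    """
    if direction == "increase_detections":
        new = params.accumulator_threshold - params.threshold_step
    elif direction == "decrease_detections":
        new = params.accumulator_threshold + params.threshold_step
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if new < 1:
        warnings.warn(
            "accumulator threshold clamped at its floor of 1", stacklevel=2
        )
        new = 1
    return replace(params, accumulator_threshold=new)


def _edge_map(lum8: np.ndarray, params: DetectionParams):
    """Thin Canny edges plus smoothed Sobel gradients of the 8-bit image."""
    edges = canny(
        lum8,
        sigma=params.canny_sigma,
        low_threshold=params.edge_threshold / 2.0,
        high_threshold=params.edge_threshold,
    )
    smoothed = ndi.gaussian_filter(lum8, params.canny_sigma, mode="nearest")
    gy = ndi.sobel(smoothed, axis=0, mode="nearest")
    gx = ndi.sobel(smoothed, axis=1, mode="nearest")
    return edges, gx, gy


def _vote_centres(
    edge_yx: np.ndarray,
    gx: np.ndarray,
    gy: np.ndarray,
    shape: tuple[int, int],
    r_min: float,
    r_max: float,
) -> np.ndarray:
    """Accumulate centre votes along each edge pixel's gradient line."""
    h, w = shape
    ey, ex = edge_yx[:, 0], edge_yx[:, 1]
    g = np.hypot(gx[ey, ex], gy[ey, ex])
    g[g == 0] = 1.0
    ux = gx[ey, ex] / g
    uy = gy[ey, ex] / g

    acc = np.zeros(shape, dtype=np.int32)
    radii = np.arange(max(1.0, r_min), r_max + 1e-9, 1.0)
    for sign in (1.0, -1.0):
        # centres are offset from the edge along the gradient direction
        cx = ex[None, :] + sign * radii[:, None] * ux[None, :]
        cy = ey[None, :] + sign * radii[:, None] * uy[None, :]
        ix = np.round(cx).astype(np.int64).ravel()
        iy = np.round(cy).astype(np.int64).ravel()
        ok = (ix >= 0) & (ix < w) & (iy >= 0) & (iy < h)
        np.add.at(acc, (iy[ok], ix[ok]), 1)
    return acc


def _select_peaks(
    acc: np.ndarray, threshold: int, min_dist: float
) -> np.ndarray:
    """Greedy strongest-first peak picking with a minimum separation.

    Accepted peaks are refined to sub-pixel positions by the
    vote-weighted centroid of their 3 x 3 accumulator neighbourhood,
    which removes most of the integer-bin quantisation error.
    """
    local_max = acc == ndi.maximum_filter(acc, size=3, mode="constant")
    cand = np.argwhere(local_max & (acc >= threshold))
    if cand.size == 0:
        return np.empty((0, 2), dtype=np.float64)
    votes = acc[cand[:, 0], cand[:, 1]]
    # strongest first; ties broken by raster order for determinism
    order = np.lexsort((cand[:, 1], cand[:, 0], -votes))
    cand = cand[order]

    accepted: list[np.ndarray] = []
    min_d2 = min_dist * min_dist
    h, w = acc.shape
    for yx in cand:
        ok = True
        for a in accepted:
            dy = a[0] - yx[0]
            dx = a[1] - yx[1]
            if dy * dy + dx * dx < min_d2:
                ok = False
                break
        if not ok:
            continue
        y0, x0 = int(yx[0]), int(yx[1])
        ys = slice(max(0, y0 - 1), min(h, y0 + 2))
        xs = slice(max(0, x0 - 1), min(w, x0 + 2))
        win = acc[ys, xs].astype(np.float64)
        total = win.sum()
        if total > 0:
            gy, gx = np.mgrid[ys, xs]
            accepted.append(
                np.array([(win * gy).sum() / total, (win * gx).sum() / total])
            )
        else:
            accepted.append(yx.astype(np.float64))
    pts = np.asarray(accepted, dtype=np.float64)
    return pts[:, ::-1]  # (y, x) -> (x, y)


def _estimate_radii(
    centres_xy: np.ndarray, edge_yx: np.ndarray, r_min: float, r_max: float
) -> np.ndarray:
    """Modal edge-pixel distance per centre (the supported radius)."""
    if len(centres_xy) == 0:
        return np.empty(0, dtype=np.float64)
    edge_xy = edge_yx[:, ::-1].astype(np.float64)
    tree = cKDTree(edge_xy)
    bins = np.arange(max(0.5, r_min - 0.5), r_max + 1.5, 1.0)
    radii = np.empty(len(centres_xy), dtype=np.float64)
    for i, c in enumerate(centres_xy):
        idx = tree.query_ball_point(c, r_max + 1.0)
        if not idx:
            radii[i] = 0.5 * (r_min + r_max)
            continue
        d = np.linalg.norm(edge_xy[idx] - c, axis=1)
        hist, _ = np.histogram(d, bins=bins)
        radii[i] = 0.5 * (bins[np.argmax(hist)] + bins[np.argmax(hist) + 1])
    return radii


def detect_uncapped_cells(
    luminance: np.ndarray, params: DetectionParams | None = None
) -> CellDetectionSet:
    """Detect uncapped-cell circles on a CIELAB L* raster.

    Parameters
    ----------
    luminance : ndarray, shape (H, W)
        Perceptual lightness channel, values on [0, 100].
    params : DetectionParams, optional
        Detector configuration; defaults are the standard values.

    Returns
    -------
    CellDetectionSet
        Circle centres/radii plus the derived lattice spacing and
        effective subtraction radius (None when fewer than two circles
        were found).

    Raises
    ------
    InvalidImageError
        For an empty or non-2-D raster.
    """
    lum = np.asarray(luminance, dtype=np.float64)
    if lum.ndim != 2 or lum.size == 0:
        raise InvalidImageError(f"expected a non-empty 2-D raster, got {lum.shape}")
    if params is None:
        params = DetectionParams()
    p = params.resolve(lum.shape[1])

    lum8 = lum * _L_TO_8BIT
    edges, gx, gy = _edge_map(lum8, p)
    edge_yx = np.argwhere(edges)

    if len(edge_yx) == 0:
        return CellDetectionSet(
            centres=np.empty((0, 2)),
            detected_radii=np.empty(0),
            accumulator_threshold_used=p.accumulator_threshold,
        )

    acc = _vote_centres(edge_yx, gx, gy, lum.shape, p.min_radius_px, p.max_radius_px)
    centres = _select_peaks(acc, p.accumulator_threshold, p.min_centre_distance_px)
    radii = _estimate_radii(centres, edge_yx, p.min_radius_px, p.max_radius_px)

    spacing = None
    eff_radius = None
    if len(centres) >= 2:
        spacing = median_neighbour_spacing(centres)
        eff_radius = effective_cell_radius(spacing, p)

    return CellDetectionSet(
        centres=centres,
        detected_radii=radii,
        accumulator_threshold_used=p.accumulator_threshold,
        median_spacing_px=spacing,
        effective_radius_px=eff_radius,
    )
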