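"""Synthetic AFM imaging of nanodot arrays and image-to-bits decoding.

The writer places a Gaussian protrusion (default 50 nm FWHM, 10 nm
height) at every 1-cell of a bit matrix on a regular lattice; the
physical channel adds a tilted background plane and iid height noise.
The reader inverts this: least-squares plane flattening, lattice
detection from row/column projections, and per-site thresholding at a
fraction of the robust dot amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.signal import find_peaks

from .concise_codec import BitMatrix

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

__all__ = [
    "HeightImage",
    "DotModel",
    "GridSpec",
    "GridDetectionError",
    "synthesize_image",
    "plane_flatten",
    "detect_grid",
    "read_matrix",
]


class GridDetectionError(RuntimeError):
    """No periodic dot lattice could be found in the image."""


@dataclass
class HeightImage:
    """2-D height map in nm with its lateral pixel size."""

    heights: np.ndarray
    pixel_size_nm: float = 5.0

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be 2-D")
        if not np.isfinite(self.heights).all():
            raise ValueError("heights must be finite")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")


@dataclass
class DotModel:
    """Geometry and noise of the written nanodots.

    fwhm_nm / height_nm default to the demonstrated dot geometry
    (50 nm FWHM, 10 nm height); tilt is the background plane slope in
    nm per pixel along (row, col).
    """

    fwhm_nm: float = 50.0
    height_nm: float = 10.0
    pitch_nm: float = 100.0
    noise_sd_nm: float = 1.0
    tilt: Tuple[float, float] = (0.0, 0.0)
    pixel_size_nm: float = 5.0

    def __post_init__(self) -> None:
        if self.height_nm <= 0:
            raise ValueError("height_nm must be positive")
        if not 0 < self.fwhm_nm < self.pitch_nm:
            raise ValueError("need 0 < fwhm_nm < pitch_nm")

    @property
    def sigma_nm(self) -> float:
        return self.fwhm_nm * FWHM_TO_SIGMA

    @property
    def pitch_px(self) -> float:
        return self.pitch_nm / self.pixel_size_nm


@dataclass(frozen=True)
class GridSpec:
    """Detected dot lattice: origin pixel, pitch in px, grid shape."""

    origin_px: Tuple[float, float]
    pitch_px: float
    rows: int
    cols: int


def synthesize_image(
    m: BitMatrix,
    dot: DotModel = DotModel(),
    margin_px: Optional[int] = None,
    seed: Optional[int] = None,
) -> HeightImage:
    """Render a bit matrix as a noisy, tilted AFM height image."""
    rows, cols = m.bits.shape
    pitch = dot.pitch_px
    if margin_px is None:
        margin_px = int(round(pitch))
    ny = int(round(2 * margin_px + (rows - 1) * pitch)) + 1
    nx = int(round(2 * margin_px + (cols - 1) * pitch)) + 1
    if max(ny, nx) > 20000:
        raise ValueError("matrix too large for image bounds")
    img = np.zeros((ny, nx), dtype=float)

    sigma_px = dot.sigma_nm / dot.pixel_size_nm
    half = max(1, int(np.ceil(4 * sigma_px)))
    win = np.arange(-half, half + 1, dtype=float)
    for r, c in zip(*np.nonzero(m.bits)):
        cy = margin_px + r * pitch
        cx = margin_px + c * pitch
        iy, ix = int(round(cy)), int(round(cx))
        dy = (iy + win - cy) ** 2
        dx = (ix + win - cx) ** 2
        bump = dot.height_nm * np.exp(-(dy[:, None] + dx[None, :]) / (2 * sigma_px**2))
        y0, y1 = max(0, iy - half), min(ny, iy + half + 1)
        x0, x1 = max(0, ix - half), min(nx, ix + half + 1)
        img[y0:y1, x0:x1] += bump[
            y0 - (iy - half) : bump.shape[0] - ((iy + half + 1) - y1),
            x0 - (ix - half) : bump.shape[1] - ((ix + half + 1) - x1),
        ]

    sy, sx = dot.tilt
    yy, xx = np.mgrid[0:ny, 0:nx]
    img += sy * yy + sx * xx
    if dot.noise_sd_nm > 0:
        rng = np.random.default_rng(seed)
        img += rng.normal(0.0, dot.noise_sd_nm, size=img.shape)
    return HeightImage(img, dot.pixel_size_nm)


def plane_flatten(img: HeightImage) -> HeightImage:
    """Remove the least-squares background plane.

    Two passes: a global fit, then a refit restricted to the lower half
    of the residuals so that the dots themselves do not bias the
    background estimate.
    """
    h = img.heights
    ny, nx = h.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    A = np.column_stack([yy.ravel(), xx.ravel(), np.ones(h.size)])

    coef, *_ = np.linalg.lstsq(A, h.ravel(), rcond=None)
    resid = h.ravel() - A @ coef
    mask = resid <= np.median(resid)
    coef2, *_ = np.linalg.lstsq(A[mask], h.ravel()[mask], rcond=None)
    flat = (h.ravel() - A @ coef2).reshape(h.shape)
    return HeightImage(flat, img.pixel_size_nm)


def _axis_peaks(profile: np.ndarray) -> np.ndarray:
    base = np.median(profile)
    prom = 0.3 * (profile.max() - base)
    if prom <= 0:
        return np.array([], dtype=int)
    peaks, _ = find_peaks(profile, prominence=prom, distance=3)
    return peaks


def detect_grid(img: HeightImage) -> GridSpec:
    """Locate the dot lattice from row/column projection peaks.

    The projections of a flattened image peak at occupied lattice rows
    and columns; peak spacing gives the pitch, the outermost peaks give
    the grid extent.  Raises GridDetectionError when the peak pattern is
    absent or irregular (e.g. pure noise).
    """
    h = np.clip(img.heights, 0.0, None)
    peaks_y = _axis_peaks(h.sum(axis=1))
    peaks_x = _axis_peaks(h.sum(axis=0))
    if len(peaks_y) == 0 or len(peaks_x) == 0:
        raise GridDetectionError("no dot response found in projections")

    # Peaks may be missing where a whole row/column carries no dots, so
    # spacings must only be near-integer multiples of a common pitch.
    pitches = []
    for pk in (peaks_y, peaks_x):
        if len(pk) < 2:
            continue
        d = np.diff(pk).astype(float)
        base = float(d.min())
        for _ in range(3):  # refine so large multiples do not drift
            mult = np.maximum(1, np.round(d / base))
            base = float(np.sum(d) / np.sum(mult))
        mult = np.maximum(1, np.round(d / base))
        if np.any(np.abs(d - mult * base) > 0.25 * base):
            raise GridDetectionError("irregular peak spacing; no periodic lattice")
        pitches.append(base)
    if not pitches:
        raise GridDetectionError("fewer than 4 dots; lattice underdetermined")
    if len(pitches) == 2 and abs(pitches[0] - pitches[1]) > 0.25 * min(pitches):
        raise GridDetectionError("row/column pitches disagree; no square lattice")
    pitch = float(np.mean(pitches))

    def _count(pk):
        if len(pk) == 1:
            return 1
        return int(round((pk[-1] - pk[0]) / pitch)) + 1

    return GridSpec(
        origin_px=(float(peaks_y[0]), float(peaks_x[0])),
        pitch_px=pitch,
        rows=_count(peaks_y),
        cols=_count(peaks_x),
    )


def read_matrix(
    img: HeightImage,
    grid: Optional[GridSpec] = None,
    threshold_frac: float = 0.5,
    pitch_nm: Optional[float] = None,
) -> BitMatrix:
    """Binarize a flattened image on the detected lattice.

    A site reads 1 iff the maximum height inside a (pitch/2)-radius
    window around the lattice point exceeds ``threshold_frac`` times the
    robust dot amplitude (median of clearly protruded site maxima).
    """
    if grid is None:
        grid = detect_grid(img)
    h = img.heights
    ny, nx = h.shape
    half = max(1, int(grid.pitch_px / 2))
    site_max = np.full((grid.rows, grid.cols), -np.inf)
    for r in range(grid.rows):
        for c in range(grid.cols):
            cy = int(round(grid.origin_px[0] + r * grid.pitch_px))
            cx = int(round(grid.origin_px[1] + c * grid.pitch_px))
            y0, y1 = max(0, cy - half), min(ny, cy + half + 1)
            x0, x1 = max(0, cx - half), min(nx, cx + half + 1)
            site_max[r, c] = h[y0:y1, x0:x1].max()

    # robust noise scale of the flattened background
    med = np.median(h)
    mad = np.median(np.abs(h - med))
    noise = 1.4826 * mad
    floor = max(5.0 * noise, 0.25 * site_max.max(), 1e-12)
    protruded = site_max[site_max > floor]
    if protruded.size == 0:
        bits = np.zeros_like(site_max, dtype=np.uint8)
    else:
        amplitude = float(np.median(protruded))
        bits = (site_max > threshold_frac * amplitude).astype(np.uint8)
    return BitMatrix(bits, pitch_nm=pitch_nm)
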