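"""Leaf-bed location and leaf-pixel segmentation in calibrated cubes.

Each imaged plant has a target leaf bound to a "leaf-bed": a rigid black
backing with a blue fiducial marker.  Extraction proceeds in stages:

1. marker detection — every pixel is compared with a blue target
   signature by spectral angle (arccos of cosine similarity, hence
   illumination-scale invariant); pixels with angle < 0.2 rad are marker.
2. ROI location — the marker's centroid and principal axis give the
   position and orientation of the leaf-bed; the leaf region of interest
   is placed at configured offsets along that axis.
3. leaf segmentation — pixel signatures are transformed to hyper-hue
   (the brightness-independent direction left after removing the
   achromatic, equal-value component) and classified by a one-class SVM
   trained on known leaf pixels.
4. per-leaf averaging — the masked pixel signatures are averaged into
   one mean spectrum per leaf.

A VNIR camera signature and a SWIR camera signature of the same leaf are
merged by concatenation (duplicated boundary bands dropped from the SWIR
side) followed by splice-jump removal across the sensor junction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.svm import OneClassSVM

from .preprocess import JumpCorrectionParams, remove_jumps
from .spectra_core import Spectrum, SpectralCube

DEFAULT_MARKER_THRESHOLD = 0.2  # radians
DEFAULT_NU = 0.1
MIN_TRAINING_PIXELS = 20

#: tolerance below which a pixel counts as achromatic (constant signature)
ACHROMATIC_TOL = 1e-12


class DetectionError(RuntimeError):
    """Marker/ROI detection failed (empty or degenerate marker mask)."""


class AchromaticError(ValueError):
    """Hyper-hue is undefined for a constant (achromatic) signature."""


class EmptyMaskError(RuntimeError):
    """No pixels available for averaging; flag the sample acquisition_error."""


@dataclass
class PixelMask:
    """Boolean (row, col) raster labelling one pixel class of a cube."""

    mask: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("pixel mask must be 2-D (row, col)")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class LeafBedROI:
    """Leaf-bed region of interest: centre, orientation and extent (pixels)."""

    centre: tuple[float, float]      # (row, col)
    orientation: float               # radians from the image x (column) axis
    extent: tuple[float, float]      # (height, width) across / along the axis

    def __post_init__(self) -> None:
        if self.extent[0] <= 0 or self.extent[1] <= 0:
            raise ValueError("ROI extent must be positive")

    def rasterise(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of the (rotated) ROI rectangle, clipped to ``shape``."""
        rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
        dy = rows - self.centre[0]
        dx = cols - self.centre[1]
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        along = dx * c + dy * s
        across = -dx * s + dy * c
        h, w = self.extent
        return (np.abs(along) <= w / 2.0) & (np.abs(across) <= h / 2.0)


@dataclass
class ROIGeometry:
    """Placement of the leaf-bed relative to the marker, in pixels.

    Calibrated once per imaging rig; defaults match the synthetic cube
    layout (leaf bed alongside the marker on its principal axis).
    """

    offset_along: float = 28.5
    offset_across: float = 0.5
    height: float = 24.0
    width: float = 38.0


def spectral_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle (radians, in [0, pi]) between two signatures; scale invariant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("spectral_angle: vectors differ in length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("spectral_angle undefined for a zero vector")
    return float(np.arccos(np.clip(a @ b / (na * nb), -1.0, 1.0)))


def detect_marker(cube: SpectralCube, target: np.ndarray,
                  threshold: float = DEFAULT_MARKER_THRESHOLD) -> PixelMask:
    """Classify pixels whose spectral angle to ``target`` is < threshold."""
    target = np.asarray(target, dtype=float)
    if target.size != cube.n_bands:
        raise ValueError(
            f"target signature has {target.size} bands, cube has {cube.n_bands}"
        )
    tn = np.linalg.norm(target)
    if tn == 0.0:
        raise ValueError("marker target signature is a zero vector")
    flat = cube.data.reshape(-1, cube.n_bands)
    norms = np.linalg.norm(flat, axis=1)
    cos = np.zeros(flat.shape[0])
    ok = norms > 0
    cos[ok] = (flat[ok] @ target) / (norms[ok] * tn)
    angles = np.arccos(np.clip(cos, -1.0, 1.0))
    angles[~ok] = np.pi
    mask = (angles < threshold).reshape(cube.shape[:2])
    return PixelMask(mask, "marker")


def locate_roi(marker: PixelMask, geometry: ROIGeometry | None = None) -> LeafBedROI:
    """Leaf-bed ROI from the marker centroid and principal axis.

    Orientation is the principal axis of the marker pixel coordinates,
    measured from the image x (column) axis, reduced mod pi.
    """
    geometry = geometry or ROIGeometry()
    coords = np.argwhere(marker.mask)  # (row, col)
    if coords.shape[0] == 0:
        raise DetectionError("marker detection produced an empty mask")
    if coords.shape[0] == 1:
        raise DetectionError("single-pixel marker: orientation is degenerate")
    centroid = coords.mean(axis=0)
    xy = np.column_stack([coords[:, 1], coords[:, 0]]).astype(float)  # (x, y)
    cov = np.cov(xy, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0:
        raise DetectionError("degenerate marker geometry: zero spatial variance")
    principal = evecs[:, -1]
    theta = float(np.arctan2(principal[1], principal[0])) % np.pi
    ux, uy = np.cos(theta), np.sin(theta)
    # perpendicular: rotate axis by +90 degrees
    px, py = -uy, ux
    centre_col = centroid[1] + geometry.offset_along * ux + geometry.offset_across * px
    centre_row = centroid[0] + geometry.offset_along * uy + geometry.offset_across * py
    return LeafBedROI((float(centre_row), float(centre_col)), theta,
                      (geometry.height, geometry.width))


def hyper_hue(pixel: np.ndarray) -> np.ndarray:
    """Brightness-independent hue direction of a signature.

    Removes the achromatic (equal-value) component and normalises:
    h = (v - mean(v)) / ||v - mean(v)||.  Invariant to adding a constant
    and to positive scaling of brightness together with that constant
    removal; unit norm; orthogonal to the all-ones direction.
    """
    v = np.asarray(pixel, dtype=float)
    centred = v - v.mean()
    norm = np.linalg.norm(centred)
    if norm < ACHROMATIC_TOL:
        raise AchromaticError("hyper-hue undefined for a constant signature")
    return centred / norm


def hyper_hue_image(cube: SpectralCube) -> tuple[np.ndarray, np.ndarray]:
    """Hyper-hue of every pixel: returns (rows, cols, bands) and an
    achromatic-pixel mask (those rows are left as zero vectors)."""
    flat = cube.data.reshape(-1, cube.n_bands).astype(float)
    centred = flat - flat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    achromatic = norms < ACHROMATIC_TOL
    safe = np.where(achromatic, 1.0, norms)
    hue = centred / safe[:, np.newaxis]
    hue[achromatic] = 0.0
    return (hue.reshape(cube.shape), achromatic.reshape(cube.shape[:2]))


def _median_heuristic_gamma(x: np.ndarray, rng_cap: int = 400) -> float:
    """RBF bandwidth gamma = 1 / (2 * median squared pairwise distance)."""
    if x.shape[0] > rng_cap:
        # deterministic thinning; the heuristic is insensitive to it
        step = x.shape[0] // rng_cap + 1
        x = x[::step]
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    med = float(np.median(d2[np.triu_indices_from(d2, k=1)]))
    if med <= 0:
        med = 1.0
    return 1.0 / (2.0 * med)


def segment_leaf(cube: SpectralCube, roi: LeafBedROI,
                 training_pixels: np.ndarray,
                 nu: float = DEFAULT_NU,
                 min_training: int = MIN_TRAINING_PIXELS,
                 clean_mask: bool = True) -> PixelMask:
    """One-class SVM leaf segmentation on hyper-hue signatures inside the ROI.

    ``training_pixels`` are hyper-hue vectors of known leaf pixels
    (n_train, n_bands).  RBF kernel; bandwidth from the median heuristic;
    achromatic pixels map to background.  The nu-SVM rejects roughly a
    ``nu`` fraction of genuine leaf pixels as isolated speckle, so by
    default the raw mask is tidied by a morphological closing and hole
    fill (``clean_mask=False`` returns the raw classifier output).
    """
    training_pixels = np.asarray(training_pixels, dtype=float)
    if not 0.0 < nu < 1.0:
        raise ValueError("nu must be in (0, 1)")
    if training_pixels.ndim != 2 or training_pixels.shape[0] < min_training:
        raise ValueError(
            f"need at least {min_training} training pixels, "
            f"got {0 if training_pixels.ndim != 2 else training_pixels.shape[0]}"
        )
    if training_pixels.shape[1] != cube.n_bands:
        raise ValueError("training pixel band count differs from cube")
    gamma = _median_heuristic_gamma(training_pixels)
    svm = OneClassSVM(kernel="rbf", nu=nu, gamma=gamma)
    svm.fit(training_pixels)

    roi_mask = roi.rasterise(cube.shape[:2])
    hue, achromatic = hyper_hue_image(cube)
    candidates = roi_mask & ~achromatic
    mask = np.zeros(cube.shape[:2], dtype=bool)
    idx = np.argwhere(candidates)
    if idx.size:
        scores = svm.predict(hue[candidates])
        mask[candidates] = scores == 1
    if clean_mask and mask.any():
        structure = np.ones((3, 3), dtype=bool)
        mask = ndimage.binary_closing(mask, structure=structure)
        mask = ndimage.binary_fill_holes(mask)
        mask &= roi_mask
    return PixelMask(mask, "leaf")


def score_training_inlier_fraction(training_pixels: np.ndarray,
                                   nu: float = DEFAULT_NU) -> float:
    """Fraction of training hyper-hue pixels classified inlier (≈ 1 - nu)."""
    training_pixels = np.asarray(training_pixels, dtype=float)
    gamma = _median_heuristic_gamma(training_pixels)
    svm = OneClassSVM(kernel="rbf", nu=nu, gamma=gamma)
    svm.fit(training_pixels)
    return float((svm.predict(training_pixels) == 1).mean())


def mean_signature(cube: SpectralCube, mask: PixelMask, sample_id: str) -> Spectrum:
    """Per-band arithmetic mean spectrum over the masked pixels."""
    if mask.mask.shape != cube.shape[:2]:
        raise ValueError("mask shape does not match cube spatial dimensions")
    if mask.n_pixels == 0:
        raise EmptyMaskError(
            f"sample {sample_id!r}: empty pixel mask (flag acquisition_error)"
        )
    values = cube.data[mask.mask].mean(axis=0)
    return Spectrum(sample_id, cube.wavelengths.copy(), values,
                    cube.fwhm.copy(), cube.sensor_id)


def merge_vnir_swir(vnir: Spectrum, swir: Spectrum,
                    params: JumpCorrectionParams | None = None) -> Spectrum:
    """Concatenate VNIR and SWIR signatures and remove the sensor junction jump.

    SWIR bands at or below the last VNIR wavelength are dropped (the VNIR
    value wins in the overlap); the merged spectrum carries two detector
    segments and per-segment FWHM metadata.
    """
    if swir.wavelengths[-1] <= vnir.wavelengths[-1] + 1e-6:
        raise ValueError("SWIR grid lies entirely within the VNIR range")
    if swir.wavelengths[0] < vnir.wavelengths[0]:
        raise ValueError("interleaved grids: SWIR starts below VNIR")
    keep = swir.wavelengths > vnir.wavelengths[-1] + 1e-6
    n_v = vnir.n_bands
    n_s = int(keep.sum())
    merged = Spectrum(
        vnir.sample_id,
        np.concatenate([vnir.wavelengths, swir.wavelengths[keep]]),
        np.concatenate([vnir.values, swir.values[keep]]),
        np.concatenate([vnir.fwhm, swir.fwhm[keep]]),
        f"{vnir.sensor_id}+{swir.sensor_id}" if vnir.sensor_id or swir.sensor_id else "",
        [(0, n_v), (n_v, n_v + n_s)],
    )
    return remove_jumps(merged, params)
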