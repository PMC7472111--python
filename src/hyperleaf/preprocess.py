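"""Reflectance calibration and spectral pre-processing.

Order of operations for a spectrometer signature: detector splice-jump
removal, Savitzky–Golay smoothing, then trimming of the noisy band edges
(default 400–2400 nm).  Camera cubes are first calibrated against dark
and white reference frames:

    r = (i_plant - i_dark) / (i_white - i_dark)

per pixel per band; pixels where the white/dark difference is below a
small tolerance are flagged invalid rather than divided.

Splice jumps arise because a full-range spectrometer stitches together
several physical detectors whose segments are offset from one another.
For each junction, a straight line is fitted (least squares) through the
trailing ``m`` points of the left segment and extrapolated to the first
wavelength of the right segment; the whole right segment is then shifted
so that its first value lands on the extrapolated line.  Junctions are
processed left to right so corrections cascade.  The shift is additive
by default (preserving within-segment differences); a multiplicative
variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .spectra_core import SpectralCube, Spectrum

#: division guard for white-minus-dark, in raw intensity units
CALIBRATION_DENOM_TOL = 1e-9

DEFAULT_SG_WINDOW = 11
DEFAULT_SG_POLYORDER = 2
DEFAULT_TRIM_LO = 400.0
DEFAULT_TRIM_HI = 2400.0


@dataclass
class JumpCorrectionParams:
    """Splice-jump correction settings.

    m : number of trailing points of the left segment used for the
        least-squares line fit (default 6).
    mode : 'additive' shifts the right segment by a constant;
        'multiplicative' scales it so its first value matches the
        extrapolated line.
    """

    m: int = 6
    mode: str = "additive"

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("jump correction needs m >= 2 trailing points")
        if self.mode not in ("additive", "multiplicative"):
            raise ValueError(f"unknown jump-correction mode {self.mode!r}")


def calibrate_cube(plant: SpectralCube, dark: SpectralCube,
                   white: SpectralCube,
                   denom_tol: float = CALIBRATION_DENOM_TOL,
                   ) -> tuple[SpectralCube, np.ndarray]:
    """Dark/white reference calibration of a raw intensity cube.

    Returns the calibrated reflectance cube and a boolean (row, col) mask
    of pixels where |white - dark| fell below ``denom_tol`` in at least
    one band (reflectance there is set to 0 and should not be trusted).
    """
    for other, name in ((dark, "dark"), (white, "white")):
        if other.shape != plant.shape:
            raise ValueError(f"{name} frame shape {other.shape} != plant {plant.shape}")
        if np.any(np.abs(other.wavelengths - plant.wavelengths) > 1e-6):
            raise ValueError(f"{name} frame wavelength axis differs from plant cube")
    denom = white.data.astype(float) - dark.data.astype(float)
    bad = np.abs(denom) < denom_tol
    safe_denom = np.where(bad, 1.0, denom)
    refl = (plant.data.astype(float) - dark.data.astype(float)) / safe_denom
    refl = np.where(bad, 0.0, refl)
    invalid = bad.any(axis=2)
    cube = SpectralCube(refl, plant.wavelengths.copy(), plant.fwhm.copy(),
                        calibrated=True, sensor_id=plant.sensor_id)
    return cube, invalid


def remove_jumps(s: Spectrum, params: JumpCorrectionParams | None = None) -> Spectrum:
    """Remove splice discontinuities between detector segments.

    Idempotent: once segments are aligned, a second pass computes zero
    offsets.  Within-segment first differences are preserved exactly in
    additive mode.
    """
    params = params or JumpCorrectionParams()
    segs = s.detector_segments
    if len(segs) < 2:
        return s.with_values(s.values.copy())
    values = s.values.copy()
    lam = s.wavelengths
    for j in range(len(segs) - 1):
        a, b = segs[j]
        if b - a < params.m:
            raise ValueError(
                f"detector segment {j} has {b - a} bands, fewer than m={params.m}"
            )
        c, d = segs[j + 1]
        # least-squares line through the trailing m points of the left segment
        coeffs = np.polyfit(lam[b - params.m:b], values[b - params.m:b], 1)
        predicted = float(np.polyval(coeffs, lam[c]))
        if params.mode == "additive":
            values[c:d] += predicted - values[c]
        else:
            first = values[c]
            if abs(first) < 1e-12:
                raise ValueError(
                    f"multiplicative jump correction undefined: segment {j + 1} "
                    "starts at zero"
                )
            values[c:d] *= predicted / first
    return s.with_values(values)


def smooth(s: Spectrum, window: int = DEFAULT_SG_WINDOW,
           polyorder: int = DEFAULT_SG_POLYORDER) -> Spectrum:
    """Savitzky–Golay smoothing of the reflectance values (grid unchanged)."""
    if window % 2 == 0:
        raise ValueError("Savitzky–Golay window must be odd")
    if window <= polyorder:
        raise ValueError("Savitzky–Golay window must exceed the polynomial order")
    if window >= s.n_bands:
        raise ValueError(
            f"window {window} >= series length {s.n_bands}"
        )
    return s.with_values(savgol_filter(s.values, window, polyorder))


def trim(s: Spectrum, lo: float = DEFAULT_TRIM_LO,
         hi: float = DEFAULT_TRIM_HI) -> Spectrum:
    """Keep only bands with lo <= wavelength <= hi; re-index detector segments."""
    if lo >= hi:
        raise ValueError("trim requires lo < hi")
    keep = (s.wavelengths >= lo - 1e-6) & (s.wavelengths <= hi + 1e-6)
    if not keep.any():
        raise ValueError(f"trim to [{lo}, {hi}] nm removes every band")
    idx = np.flatnonzero(keep)
    first, last = idx[0], idx[-1] + 1
    new_segments = []
    offset = first
    for a, b in s.detector_segments:
        na, nb = max(a, first) - offset, min(b, last) - offset
        if nb > na:
            new_segments.append((int(na), int(nb)))
    return Spectrum(
        s.sample_id,
        s.wavelengths[first:last].copy(),
        s.values[first:last].copy(),
        s.fwhm[first:last].copy(),
        s.sensor_id,
        new_segments,
    )


def preprocess_signature(s: Spectrum,
                         params: JumpCorrectionParams | None = None,
                         sg_window: int = DEFAULT_SG_WINDOW,
                         sg_polyorder: int = DEFAULT_SG_POLYORDER,
                         trim_lo: float = DEFAULT_TRIM_LO,
                         trim_hi: float = DEFAULT_TRIM_HI) -> Spectrum:
    """Full signature pre-processing: jump removal, smoothing, trimming."""
    out = remove_jumps(s, params)
    out = smooth(out, sg_window, sg_polyorder)
    return trim(out, trim_lo, trim_hi)
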