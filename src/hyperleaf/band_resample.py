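"""Spectral band resampling with Gaussian spectral response functions.

A destination band is modelled as a Gaussian response centred on its
band centre with sigma = FWHM / (2 * sqrt(2 * ln 2)).  Each source band
contributes to a destination band in proportion to that response
evaluated at the source band centre, but only where the two bands'
FWHM intervals overlap, i.e. the contribution is cut to zero when

    |lambda_dst - lambda_src| > (FWHM_dst + FWHM_src) / 2.

Weight rows are normalised to sum to one after the cut-off, so the
resampled value of every destination band is a convex combination of
source values: constants are conserved exactly and output values never
leave the range of the contributing source values.

Sampling the response at source centres (rather than integrating
response products) is the standard approximation when the source grid is
dense relative to the destination bandwidth, which holds for the 1 nm
spectrometer grid and the 5.5/12 nm camera grids resampled to 10–100 nm
destinations.
"""

from __future__ import annotations

import numpy as np

from .spectra_core import BandSpec, Spectrum

#: FWHM = SIGMA_PER_FWHM * sigma for a Gaussian
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class NoCoverageError(ValueError):
    """A destination band receives no contribution from any source band."""


def gaussian_weights(src: BandSpec, dst: BandSpec) -> np.ndarray:
    """Weight matrix W (n_dst x n_src) with rows normalised to sum to 1."""
    lam_s = src.centres[np.newaxis, :]
    lam_d = dst.centres[:, np.newaxis]
    sigma_d = (dst.fwhm * FWHM_TO_SIGMA)[:, np.newaxis]
    w = np.exp(-0.5 * ((lam_s - lam_d) / sigma_d) ** 2)
    cutoff = (dst.fwhm[:, np.newaxis] + src.fwhm[np.newaxis, :]) / 2.0
    w = np.where(np.abs(lam_s - lam_d) > cutoff, 0.0, w)
    row_sums = w.sum(axis=1)
    dead = np.flatnonzero(row_sums <= 0)
    if dead.size:
        band = dead[0]
        raise NoCoverageError(
            f"destination band {band} at {dst.centres[band]:g} nm "
            f"(FWHM {dst.fwhm[band]:g} nm) receives no source contribution"
        )
    return w / row_sums[:, np.newaxis]


def resample(s: Spectrum, dst: BandSpec) -> Spectrum:
    """Resample a spectrum onto a destination band layout."""
    w = gaussian_weights(s.band_spec(), dst)
    return Spectrum(
        s.sample_id,
        dst.centres.copy(),
        w @ s.values,
        dst.fwhm.copy(),
        s.sensor_id,
    )


def resample_matrix(values: np.ndarray, src: BandSpec, dst: BandSpec) -> np.ndarray:
    """Resample many spectra at once: ``values`` is (n_samples, n_src)."""
    w = gaussian_weights(src, dst)
    return values @ w.T


def even_grid(lo: float, hi: float, fwhm: float, label: str | None = None) -> BandSpec:
    """Evenly distributed bands of uniform FWHM tiling [lo, hi].

    Centres sit at lo + fwhm/2, lo + 3*fwhm/2, ... up to hi - fwhm/2, so
    adjacent FWHM intervals tile the range without gaps.
    """
    if hi - lo < fwhm:
        raise ValueError(f"range [{lo}, {hi}] nm narrower than FWHM {fwhm} nm")
    n = int(np.floor((hi - lo) / fwhm + 1e-9))
    centres = lo + fwhm / 2.0 + fwhm * np.arange(n)
    return BandSpec(centres, np.full(n, float(fwhm)),
                    label or f"even-{fwhm:g}nm")


def key_band_spec(keys: np.ndarray, mode: str, nb_fwhm: float | np.ndarray = 1.0,
                  bb_rule: str = "min", label: str | None = None) -> BandSpec:
    """Band layout centred on key-wavelengths.

    mode 'NB' (narrow band): every band keeps the native sensor FWHM
    (``nb_fwhm``, scalar or per-key).  mode 'BB' (broad band): each
    band's half-width reaches halfway to its nearest neighbouring key,
    i.e. FWHM = min(left gap, right gap); the end keys use their single
    neighbour.  ``bb_rule='mean'`` uses the mean of the two half-gaps
    instead of the minimum.
    """
    keys = np.sort(np.asarray(keys, dtype=float))
    if np.any(np.diff(keys) <= 0):
        raise ValueError("duplicate key wavelengths")
    mode = mode.upper()
    if mode == "NB":
        fwhm = np.broadcast_to(np.asarray(nb_fwhm, dtype=float), keys.shape).copy()
    elif mode == "BB":
        if keys.size < 2:
            raise ValueError("broad-band layout needs at least 2 key wavelengths")
        gaps = np.diff(keys)
        left = np.concatenate(([np.inf], gaps))
        right = np.concatenate((gaps, [np.inf]))
        if bb_rule == "min":
            fwhm = np.minimum(left, right)
        elif bb_rule == "mean":
            both = np.stack([left, right])
            finite = np.isfinite(both)
            fwhm = np.where(finite.all(axis=0), both.mean(axis=0),
                            np.nanmin(np.where(finite, both, np.nan), axis=0))
        else:
            raise ValueError(f"unknown bb_rule {bb_rule!r}")
    else:
        raise ValueError(f"unknown key-band mode {mode!r} (use 'NB' or 'BB')")
    return BandSpec(keys, fwhm, label or f"key-{mode}")
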