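"""Vegetation-index baselines: exhaustive narrow-band NDVI and NREAI.

NDVI(λi, λj) = (r_i - r_j) / (r_i + r_j).  To find the best-performing
pair, an NDVI matrix over all wavelength combinations in a range is
regressed (univariate least squares) against N% using the same 5-fold
cross-validation folds as the PLSR models, and the pair maximising the
average validation R² is reported.  The R² matrix is symmetric under
pair swap (the predictor only flips sign) and the NDVI matrix itself is
antisymmetric with a zero diagonal.

NREAI = (SD_r - SD_b) / (SD_r + SD_b), where SD_b and SD_r integrate the
first-derivative spectrum (central differences on the native grid,
trapezoidal integration) over the blue edge 490–530 nm and the red edge
670–737 nm.  Undefined values (zero denominators) are returned as NaN
and excluded from regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nitrogen_regression import (MetricsReport, _mean_metrics, assign_folds,
                                  metrics)
from .spectra_core import Dataset, Spectrum

BLUE_EDGE = (490.0, 530.0)
RED_EDGE = (670.0, 737.0)
NDVI_SEARCH_RANGE = (400.0, 2400.0)


def ndvi(r_i, r_j):
    """Normalised difference (r_i - r_j)/(r_i + r_j); NaN where undefined."""
    r_i = np.asarray(r_i, dtype=float)
    r_j = np.asarray(r_j, dtype=float)
    denom = r_i + r_j
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom == 0.0, np.nan, (r_i - r_j) / np.where(denom == 0.0,
                                                                    1.0, denom))
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class NDVIMatrix:
    """All-pairs NDVI values of one spectrum (antisymmetric, zero diagonal)."""

    wavelengths: np.ndarray
    values: np.ndarray  # values[i, j] = ndvi(r[i], r[j])


def ndvi_matrix(s: Spectrum, lo: float = NDVI_SEARCH_RANGE[0],
                hi: float = NDVI_SEARCH_RANGE[1]) -> NDVIMatrix:
    sel = (s.wavelengths >= lo - 1e-6) & (s.wavelengths <= hi + 1e-6)
    lam = s.wavelengths[sel]
    r = s.values[sel]
    return NDVIMatrix(lam, ndvi(r[:, None], r[None, :]))


@dataclass
class NDVISearchResult:
    """Cross-validated R² of every NDVI pair plus the best pair found."""

    wavelengths: np.ndarray
    r2: np.ndarray                 # symmetric matrix, NaN on the diagonal
    best_pair: tuple[float, float]
    best_r2: float


def ndvi_r2_matrix(data: Dataset, lo: float = NDVI_SEARCH_RANGE[0],
                   hi: float = NDVI_SEARCH_RANGE[1],
                   seed: int = 0, k_folds: int = 5,
                   fold_assignments: np.ndarray | None = None,
                   step: int = 1,
                   chunk: int = 64) -> NDVISearchResult:
    """Exhaustive NDVI-pair search against N% with shared CV folds.

    ``step`` thins the wavelength grid (every ``step``-th band) to bound
    the quadratic pair search; ``chunk`` limits the memory footprint of
    the vectorised sweep.  Pairs with undefined NDVI for any sample, and
    the constant diagonal, carry NaN in the R² matrix.
    """
    X, y, _ = data.design_matrix()
    sel = np.flatnonzero((data.wavelengths >= lo - 1e-6)
                         & (data.wavelengths <= hi + 1e-6))[::step]
    lam = data.wavelengths[sel]
    Xs = X[:, sel]
    n, b = Xs.shape
    folds = (np.asarray(fold_assignments, dtype=int) if fold_assignments is not None
             else assign_folds(n, k_folds, seed))
    val_masks = [folds == f for f in range(k_folds)]
    r2 = np.full((b, b), np.nan)

    for start in range(0, b, chunk):
        stop = min(start + chunk, b)
        ri = Xs[:, start:stop, None]           # (n, c, 1)
        rj = Xs[:, None, :]                    # (n, 1, b)
        denom = ri + rj
        with np.errstate(divide="ignore", invalid="ignore"):
            v = (ri - rj) / denom              # (n, c, b)
        v[np.broadcast_to(denom == 0.0, v.shape)] = np.nan
        valid = np.isfinite(v).all(axis=0)     # (c, b)
        fold_r2 = np.zeros((k_folds,) + valid.shape)
        for f, val in enumerate(val_masks):
            tr = ~val
            vt = v[tr]
            mx = vt.mean(axis=0)
            my = y[tr].mean()
            varx = ((vt - mx) ** 2).mean(axis=0)
            cov = ((vt - mx) * (y[tr, None, None] - my)).mean(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                slope = np.where(varx > 0, cov / np.where(varx > 0, varx, 1.0), np.nan)
            inter = my - slope * mx
            pred = slope[None] * v[val] + inter[None]
            yv = y[val]
            sse = ((pred - yv[:, None, None]) ** 2).sum(axis=0)
            sst = float(((yv - yv.mean()) ** 2).sum())
            fold_r2[f] = 1.0 - sse / sst
        mean_r2 = fold_r2.mean(axis=0)
        mean_r2[~valid] = np.nan
        # the diagonal block is a constant predictor: undefined
        for i in range(start, stop):
            mean_r2[i - start, i] = np.nan
        r2[start:stop] = mean_r2

    if np.all(np.isnan(r2)):
        raise ValueError("no valid NDVI pair in the requested range")
    flat_best = np.nanargmax(r2)
    i, j = np.unravel_index(flat_best, r2.shape)
    # report the pair with the longer wavelength first (convention only)
    pair = (float(lam[i]), float(lam[j]))
    if pair[0] < pair[1]:
        pair = (pair[1], pair[0])
    return NDVISearchResult(lam, r2, pair, float(r2[i, j]))


def nreai(s: Spectrum) -> float:
    """Normalised red-edge area index of one spectrum (NaN if undefined)."""
    lam = s.wavelengths
    if lam[0] > BLUE_EDGE[0] + 1e-6 or lam[-1] < RED_EDGE[1] - 1e-6:
        raise ValueError(
            "spectrum does not cover the blue (490-530 nm) and red "
            "(670-737 nm) edges"
        )
    deriv = np.gradient(s.values, lam)

    def edge_area(win: tuple[float, float]) -> float:
        sel = (lam >= win[0] - 1e-6) & (lam <= win[1] + 1e-6)
        if sel.sum() < 2:
            raise ValueError(f"fewer than 2 bands inside edge window {win}")
        return float(np.trapezoid(deriv[sel], lam[sel]))

    sd_b = edge_area(BLUE_EDGE)
    sd_r = edge_area(RED_EDGE)
    denom = sd_r + sd_b
    if denom == 0.0:
        return float("nan")
    return (sd_r - sd_b) / denom


@dataclass
class VIRegressionResult:
    """Cross-validated univariate regression of N% on a vegetation index."""

    fold_metrics: list[MetricsReport]
    mean_metrics: MetricsReport
    n_valid: int


def vi_regression(data: Dataset, vi: np.ndarray, seed: int = 0,
                  k_folds: int = 5,
                  fold_assignments: np.ndarray | None = None
                  ) -> VIRegressionResult:
    """Least-squares regression of N% on an index series with shared CV folds.

    ``vi`` is aligned with ``data.design_matrix()`` sample order; NaN
    entries (undefined index values) are excluded.
    """
    _, y, _ = data.design_matrix()
    vi = np.asarray(vi, dtype=float)
    if vi.size != y.size:
        raise ValueError("index series length != sample count")
    folds = (np.asarray(fold_assignments, dtype=int) if fold_assignments is not None
             else assign_folds(y.size, k_folds, seed))
    ok = np.isfinite(vi)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 samples with a defined index value")
    vi, y, folds = vi[ok], y[ok], folds[ok]
    reports = []
    for f in range(k_folds):
        val = folds == f
        tr = ~val
        if val.sum() < 2 or tr.sum() < 2:
            continue
        varx = vi[tr].var()
        if varx == 0:
            continue
        slope = np.cov(vi[tr], y[tr], bias=True)[0, 1] / varx
        inter = y[tr].mean() - slope * vi[tr].mean()
        reports.append(metrics(y[val], slope * vi[val] + inter))
    if not reports:
        raise ValueError("no usable cross-validation fold for VI regression")
    return VIRegressionResult(reports, _mean_metrics(reports), int(ok.sum()))


def nreai_series(data: Dataset) -> np.ndarray:
    """NREAI of every sample, aligned with ``data.design_matrix()`` order."""
    _, _, ids = data.design_matrix()
    return np.array([nreai(data.spectra[sid]) for sid in ids])
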