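"""PLSR nitrogen modelling, cross-validated metrics and key-wavelength selection.

The response is leaf nitrogen as % of dry mass (N%); the predictors are
reflectance values over the spectral bands.  The model is PLS1 (single
response) computed by NIPALS with deflation; predictors are mean-centred
per training set, without unit-variance scaling (reflectance bands share
units).

Model selection and validation follow a nested scheme: samples are
shuffled into 5 outer folds by a seeded permutation; within each outer
training partition an inner 5-fold cross-validation picks the number of
latent variables (1–20) minimising pooled validation RMSE; the model is
refit on the whole training partition and scored on the held-out fold.
The headline figure is the average of the five validation R² values.

Key-wavelengths are the strict interior local extrema of the coefficient
curve obtained by averaging the five folds' coefficient vectors, ranked
by absolute coefficient.  A plateau of equal values counts as a single
extremum at its centre band.

Metrics (all in N% units except R²):

    R²        = 1 - SSE / SST           (may be negative out of sample)
    RMSE      = sqrt(mean (y - yhat)²)
    Bias      = mean (yhat - y)
    MeanABS   = mean |yhat - y|
    MedianABS = median |yhat - y|
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spectra_core import (Dataset, GridMismatchError, SampleRecord, Spectrum,
                           WAVELENGTH_TOL)

MIN_DRIED_WEIGHT_MG = 100.0
N_PERCENT_BOUNDS = (1.0, 7.0)
DEFAULT_K_FOLDS = 5
DEFAULT_LV_RANGE = (1, 20)


class ZeroVarianceError(ValueError):
    """R² is undefined when the reference values have zero variance."""


# ---------------------------------------------------------------------------
# sample cleaning
# ---------------------------------------------------------------------------


def clean(records: list[SampleRecord]) -> list[SampleRecord]:
    """Apply the exclusion rules and return only the surviving records.

    Rules: dried leaf weight < 100 mg -> too_small (no laboratory N%
    available); N% strictly below 1 or strictly above 7 -> n_outlier;
    pre-existing acquisition_error flags are retained.
    """
    survivors = []
    for r in records:
        if r.exclusion_flag == "acquisition_error":
            continue
        if np.isfinite(r.dried_weight) and r.dried_weight < MIN_DRIED_WEIGHT_MG:
            continue  # too_small
        if r.n_percent is None:
            continue  # no reference value: treat as acquisition error
        lo, hi = N_PERCENT_BOUNDS
        if r.n_percent < lo or r.n_percent > hi:
            continue  # n_outlier
        survivors.append(replace(r, exclusion_flag="none"))
    return survivors


def flag_records(records: list[SampleRecord]) -> list[SampleRecord]:
    """Same rules as :func:`clean` but returning every record, flagged."""
    out = []
    for r in records:
        flag = r.exclusion_flag
        if flag != "acquisition_error":
            if np.isfinite(r.dried_weight) and r.dried_weight < MIN_DRIED_WEIGHT_MG:
                flag = "too_small"
            elif r.n_percent is None:
                flag = "acquisition_error"
            elif r.n_percent < N_PERCENT_BOUNDS[0] or r.n_percent > N_PERCENT_BOUNDS[1]:
                flag = "n_outlier"
            else:
                flag = "none"
        out.append(replace(r, exclusion_flag=flag))
    return out


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """Validation metrics for one set of predictions."""

    r2: float
    rmse: float
    bias: float
    mean_abs: float
    median_abs: float
    n: int


def metrics(y: np.ndarray, yhat: np.ndarray) -> MetricsReport:
    """Accuracy metrics of predictions ``yhat`` against reference ``y``.

    The R² baseline mean is the mean of the evaluated ``y`` values, so a
    constant mean predictor scores exactly 0 and poor extrapolation can
    score negative.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("metrics: y and yhat must be equal-length vectors")
    if y.size < 2:
        raise ValueError("metrics: need at least 2 samples")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise ZeroVarianceError("R² undefined: reference values have zero variance")
    err = yhat - y
    return MetricsReport(
        r2=1.0 - float(np.sum(err**2)) / sst,
        rmse=float(np.sqrt(np.mean(err**2))),
        bias=float(np.mean(err)),
        mean_abs=float(np.mean(np.abs(err))),
        median_abs=float(np.median(np.abs(err))),
        n=int(y.size),
    )


def _mean_metrics(reports: list[MetricsReport]) -> MetricsReport:
    return MetricsReport(
        r2=float(np.mean([m.r2 for m in reports])),
        rmse=float(np.mean([m.rmse for m in reports])),
        bias=float(np.mean([m.bias for m in reports])),
        mean_abs=float(np.mean([m.mean_abs for m in reports])),
        median_abs=float(np.mean([m.median_abs for m in reports])),
        n=int(np.sum([m.n for m in reports])),
    )


# ---------------------------------------------------------------------------
# PLS1 (NIPALS with deflation) and coefficient paths
# ---------------------------------------------------------------------------


def pls1_coefficient_paths(X: np.ndarray, y: np.ndarray, max_components: int
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Regression coefficient vectors for every component count 1..K.

    Returns (B, intercepts) where B is (n_bands, K) and column k-1 holds
    the coefficients of the k-component PLS1 model on the original
    (uncentred) predictor scale.  K may be smaller than requested if
    deflation exhausts the signal.  One NIPALS pass yields the whole
    path: with W the X-weights, P the X-loadings and q the y-loadings,
    B_k = W_k (P_kᵀ W_k)⁻¹ q_k, and PᵀW is upper triangular so every
    leading block reuses the same decomposition.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    yd = y - y_mean
    n, p = X.shape
    kmax = min(max_components, n - 1, p)
    Ws, Ps, Qs = [], [], []
    eps = np.finfo(float).eps
    scale = max(float(np.abs(Xd).max()), 1.0)
    for _ in range(kmax):
        w = Xd.T @ yd
        wn = np.linalg.norm(w)
        if wn <= eps * scale * max(n, p):
            break
        w /= wn
        t = Xd @ w
        tt = float(t @ t)
        if tt <= eps * scale:
            break
        pvec = Xd.T @ t / tt
        q = float(yd @ t / tt)
        Xd = Xd - np.outer(t, pvec)
        yd = yd - q * t
        Ws.append(w)
        Ps.append(pvec)
        Qs.append(q)
    if not Ws:
        # constant response: zero coefficients, intercept = mean
        return np.zeros((p, 1)), np.array([y_mean])
    W = np.column_stack(Ws)
    P = np.column_stack(Ps)
    q = np.array(Qs)
    PtW = P.T @ W
    k_found = W.shape[1]
    B = np.empty((p, k_found))
    intercepts = np.empty(k_found)
    for k in range(1, k_found + 1):
        z = np.linalg.solve(PtW[:k, :k], q[:k])
        B[:, k - 1] = W[:, :k] @ z
        intercepts[k - 1] = y_mean - x_mean @ B[:, k - 1]
    return B, intercepts


def assign_folds(n: int, k_folds: int, seed: int,
                 groups: np.ndarray | None = None) -> np.ndarray:
    """Fold assignment (0..k_folds-1 per sample) by seeded permutation.

    With ``groups``, whole groups (e.g. all time-points of one plant) are
    kept together in a fold.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if groups is None:
        perm = rng.permutation(n)
        folds = np.empty(n, dtype=int)
        folds[perm] = np.arange(n) % k_folds
        return folds
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    gperm = rng.permutation(uniq.size)
    gfold = {g: i % k_folds for g, i in zip(uniq, gperm)}
    return np.array([gfold[g] for g in groups], dtype=int)


@dataclass
class FitResult:
    """Cross-validated PLSR artefacts."""

    sample_ids: list[str]
    wavelengths: np.ndarray
    fold_assignments: np.ndarray          # fold index per sample
    fold_coefficients: np.ndarray         # (k_folds, n_bands)
    fold_intercepts: np.ndarray
    fold_lv: list[int]                    # chosen latent-variable counts
    fold_metrics: list[MetricsReport]
    predictions: pd.DataFrame             # sample_id, y, yhat, fold
    mean_metrics: MetricsReport
    full_coefficients: np.ndarray = field(default=None)  # refit on all samples
    full_intercept: float = 0.0
    full_lv: int = 1
    seed: int = 0

    @property
    def avg_coefficients(self) -> np.ndarray:
        """Pointwise mean of the per-fold coefficient vectors."""
        return self.fold_coefficients.mean(axis=0)

    @property
    def mean_r2(self) -> float:
        return self.mean_metrics.r2


def _select_lv(X: np.ndarray, y: np.ndarray, lv_range: tuple[int, int],
               k_folds: int, seed: int) -> int:
    """Inner-CV latent-variable count minimising pooled validation RMSE."""
    n = X.shape[0]
    lo, hi = lv_range
    cap = min(hi, n - 1 - (n // k_folds) - 1, X.shape[1])
    cap = max(cap, lo)
    if cap < hi:
        warnings.warn(
            f"latent-variable search capped at {cap} (training size {n}, "
            f"{X.shape[1]} bands)", stacklevel=2)
    folds = assign_folds(n, k_folds, seed)
    sse = np.zeros(cap)
    counts = np.zeros(cap)
    for f in range(k_folds):
        val = folds == f
        if not val.any() or val.all():
            continue
        B, b0 = pls1_coefficient_paths(X[~val], y[~val], cap)
        pred = X[val] @ B + b0          # (n_val, k_found)
        err2 = (pred - y[val, None]) ** 2
        k_found = B.shape[1]
        sse[:k_found] += err2.sum(axis=0)
        if k_found < cap:               # deflation exhausted: pad with last model
            sse[k_found:] += err2[:, -1].sum()
        counts[:] += val.sum()
    rmse = np.sqrt(sse / counts)
    candidates = np.arange(lo, cap + 1)
    return int(candidates[np.argmin(rmse[lo - 1:])])  # ties -> fewest components


def fit_plsr_cv(data: Dataset, k_folds: int = DEFAULT_K_FOLDS,
                lv_range: tuple[int, int] = DEFAULT_LV_RANGE,
                seed: int = 0,
                groups: np.ndarray | None = None,
                fold_assignments: np.ndarray | None = None) -> FitResult:
    """Nested cross-validated PLS1 fit of N% on reflectance.

    Outer folds come from a seeded permutation (or ``fold_assignments``
    given explicitly, e.g. to keep duplicates or plants together); the
    latent-variable count of each outer fold is chosen by an inner
    cross-validation on its training partition only.  A final model is
    refit on all samples (its latent-variable count selected by the same
    inner-CV rule on the full data) for cross-sensor application.
    """
    X, y, ids = data.design_matrix()
    n = X.shape[0]
    if n < k_folds:
        raise ValueError(f"need at least {k_folds} samples, got {n}")
    if fold_assignments is not None:
        folds = np.asarray(fold_assignments, dtype=int)
        if folds.size != n:
            raise ValueError("fold_assignments length != sample count")
    else:
        folds = assign_folds(n, k_folds, seed, groups)
    ss = np.random.SeedSequence(seed)
    inner_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(k_folds + 1)]

    coefs, intercepts, lvs, reports = [], [], [], []
    pred_rows = []
    for f in range(k_folds):
        val = folds == f
        tr = ~val
        lv = _select_lv(X[tr], y[tr], lv_range, k_folds, inner_seeds[f])
        B, b0 = pls1_coefficient_paths(X[tr], y[tr], lv)
        k_use = min(lv, B.shape[1])
        beta, beta0 = B[:, k_use - 1], float(b0[k_use - 1])
        yhat = X[val] @ beta + beta0
        coefs.append(beta)
        intercepts.append(beta0)
        lvs.append(k_use)
        reports.append(metrics(y[val], yhat))
        for i, sid in enumerate(np.asarray(ids)[val]):
            pred_rows.append((sid, float(y[val][i]), float(yhat[i]), f))

    lv_full = _select_lv(X, y, lv_range, k_folds, inner_seeds[k_folds])
    B, b0 = pls1_coefficient_paths(X, y, lv_full)
    k_use = min(lv_full, B.shape[1])

    predictions = pd.DataFrame(pred_rows, columns=["sample_id", "y", "yhat", "fold"])
    predictions = predictions.sort_values("sample_id").reset_index(drop=True)
    return FitResult(
        sample_ids=list(ids),
        wavelengths=data.wavelengths.copy(),
        fold_assignments=folds,
        fold_coefficients=np.vstack(coefs),
        fold_intercepts=np.array(intercepts),
        fold_lv=lvs,
        fold_metrics=reports,
        predictions=predictions,
        mean_metrics=_mean_metrics(reports),
        full_coefficients=B[:, k_use - 1],
        full_intercept=float(b0[k_use - 1]),
        full_lv=k_use,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# key-wavelength selection
# ---------------------------------------------------------------------------


@dataclass
class KeyWavelengthSet:
    """Key-wavelengths ranked by |averaged PLSR coefficient|.

    ``entries`` rows: (rank, wavelength nm, |coefficient|, sign).
    """

    entries: list[tuple[int, float, float, int]]

    @property
    def wavelengths(self) -> np.ndarray:
        return np.array([e[1] for e in self.entries])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries,
                            columns=["rank", "wavelength_nm", "coefficient_abs",
                                     "sign"])

    def __len__(self) -> int:
        return len(self.entries)


def _local_extrema_indices(values: np.ndarray) -> list[int]:
    """Strict interior local extrema; a run of equal values counts once,
    at its centre index."""
    # compress runs of equal values
    starts = [0]
    for i in range(1, values.size):
        if values[i] != values[starts[-1]]:
            starts.append(i)
    starts.append(values.size)
    out = []
    for j in range(1, len(starts) - 2):
        a, b = starts[j], starts[j + 1]
        v = values[a]
        left, right = values[starts[j - 1]], values[b]
        if (v > left and v > right) or (v < left and v < right):
            out.append((a + b - 1) // 2)  # centre of the run
    return out


def key_wavelengths(fit: FitResult, top_k: int) -> KeyWavelengthSet:
    """Top-k key-wavelengths from the fold-averaged coefficient curve."""
    avg = fit.avg_coefficients
    if avg.size < 2:
        raise ValueError("key-wavelength selection needs at least 2 bands")
    idx = _local_extrema_indices(avg)
    if len(idx) < top_k:
        warnings.warn(
            f"only {len(idx)} interior extrema found; requested top {top_k}",
            stacklevel=2)
    order = sorted(idx, key=lambda i: (-abs(avg[i]), fit.wavelengths[i]))
    entries = [
        (rank + 1, float(fit.wavelengths[i]), float(abs(avg[i])),
         int(np.sign(avg[i])))
        for rank, i in enumerate(order[:top_k])
    ]
    return KeyWavelengthSet(entries)


# ---------------------------------------------------------------------------
# cross-sensor application
# ---------------------------------------------------------------------------


def apply_cross_sensor(model: FitResult, spectra: list[Spectrum]) -> np.ndarray:
    """Predict N% for spectra already resampled onto the model's band grid."""
    if model.full_coefficients is None:
        raise ValueError("model has no refit-on-all coefficients")
    grid = model.wavelengths
    X = []
    for s in spectra:
        if s.n_bands != grid.size or np.any(np.abs(s.wavelengths - grid)
                                            > WAVELENGTH_TOL):
            raise GridMismatchError(
                f"spectrum {s.sample_id!r} is not on the model's band grid; "
                "resample it first"
            )
        X.append(s.values)
    return np.vstack(X) @ model.full_coefficients + model.full_intercept


def evaluate_cross_sensor(model: FitResult, spectra: list[Spectrum],
                          y: np.ndarray) -> tuple[np.ndarray, MetricsReport]:
    """Cross-sensor predictions plus their metrics against reference N%."""
    yhat = apply_cross_sensor(model, spectra)
    return yhat, metrics(np.asarray(y, dtype=float), yhat)
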