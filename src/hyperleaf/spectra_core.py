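"""Core domain types and file I/O for hyperspectral leaf data.

The package works with four kinds of objects:

* :class:`Spectrum` — one sample's reflectance signature on an ordered
  wavelength grid, with per-band FWHM and the detector-segment layout
  needed for splice-jump correction.
* :class:`SpectralCube` — a (row, col, band) raster from a hyperspectral
  camera, raw intensity or calibrated reflectance.
* :class:`SampleRecord` — the ledger entry carrying the reference
  nitrogen measurement (% of dry mass) for one leaf sample.
* :class:`BandSpec` — a target sensor definition (band centres + FWHMs)
  that drives spectral band resampling.

On-disk formats are deliberately plain: spectra travel as a wide CSV
(wavelength column + one column per sample) with a YAML sidecar for FWHM
and detector segments; cubes as ENVI header + flat binary raster
(bil/bip/bsq); ledgers as CSV.  All readers and writers round-trip.

Cube coordinate convention: ``data[row, col, band]``, 0-based, row 0 at
the top of the image.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

#: absolute tolerance (nm) for all wavelength-grid comparisons
WAVELENGTH_TOL = 1e-6

EXCLUSION_FLAGS = ("none", "too_small", "n_outlier", "acquisition_error")


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class GridMismatchError(ValueError):
    """Two spectra (or a spectrum and a model) are on different wavelength grids."""


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Spectrum:
    """One reflectance signature on an ordered wavelength grid.

    ``detector_segments`` is a list of ``(start, stop)`` index ranges
    (half-open, contiguous, in order) — one per physical detector of the
    instrument.  Splice-jump correction shifts whole segments.
    """

    sample_id: str
    wavelengths: np.ndarray
    values: np.ndarray
    fwhm: np.ndarray
    sensor_id: str = ""
    detector_segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths = _as_float_array(self.wavelengths)
        self.values = _as_float_array(self.values)
        fwhm = np.asarray(self.fwhm, dtype=float)
        if fwhm.ndim == 0:
            fwhm = np.full(self.wavelengths.shape, float(fwhm))
        self.fwhm = fwhm
        n = self.wavelengths.size
        if self.values.size != n or self.fwhm.size != n:
            raise FormatError(
                f"spectrum {self.sample_id!r}: wavelengths ({n}), values "
                f"({self.values.size}) and fwhm ({self.fwhm.size}) differ in length"
            )
        if n == 0:
            raise FormatError(f"spectrum {self.sample_id!r}: empty")
        if np.any(np.diff(self.wavelengths) <= WAVELENGTH_TOL):
            raise FormatError(
                f"spectrum {self.sample_id!r}: wavelengths not strictly increasing"
            )
        if np.any(self.fwhm <= 0):
            raise FormatError(f"spectrum {self.sample_id!r}: FWHM must be positive")
        if not self.detector_segments:
            self.detector_segments = [(0, n)]
        segs = [(int(a), int(b)) for a, b in self.detector_segments]
        if segs[0][0] != 0 or segs[-1][1] != n:
            raise FormatError(
                f"spectrum {self.sample_id!r}: detector segments do not cover bands"
            )
        for (a, b), (c, _) in zip(segs, segs[1:]):
            if b != c:
                raise FormatError(
                    f"spectrum {self.sample_id!r}: detector segments not contiguous"
                )
        for a, b in segs:
            if b <= a:
                raise FormatError(
                    f"spectrum {self.sample_id!r}: empty detector segment ({a}, {b})"
                )
        self.detector_segments = segs

    @property
    def n_bands(self) -> int:
        return int(self.wavelengths.size)

    def with_values(self, values: np.ndarray) -> "Spectrum":
        """Copy of this spectrum with ``values`` replaced (grid unchanged)."""
        return replace(self, values=_as_float_array(values))

    def band_spec(self, label: str | None = None) -> "BandSpec":
        return BandSpec(self.wavelengths.copy(), self.fwhm.copy(),
                        label or self.sensor_id)


@dataclass
class SpectralCube:
    """A (row, col, band) hyperspectral raster with its wavelength axis."""

    data: np.ndarray
    wavelengths: np.ndarray
    fwhm: np.ndarray
    calibrated: bool = False
    sensor_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = _as_float_array(self.wavelengths)
        fwhm = np.asarray(self.fwhm, dtype=float)
        if fwhm.ndim == 0:
            fwhm = np.full(self.wavelengths.shape, float(fwhm))
        self.fwhm = fwhm
        if self.data.ndim != 3:
            raise FormatError("cube data must be 3-D (row, col, band)")
        if self.data.shape[2] != self.wavelengths.size:
            raise FormatError(
                f"cube band dimension ({self.data.shape[2]}) does not match "
                f"wavelength axis ({self.wavelengths.size})"
            )
        if self.fwhm.size != self.wavelengths.size:
            raise FormatError("cube FWHM length does not match wavelength axis")
        if self.calibrated and not np.all(np.isfinite(self.data)):
            raise FormatError("calibrated cube contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return int(self.wavelengths.size)


@dataclass
class SampleRecord:
    """Ledger entry: metadata plus the reference N%% for one leaf sample."""

    sample_id: str
    variety: str = ""
    n_treatment: float = np.nan   # mg N per kg soil
    time_point: int = 1           # measurement round, 1..3
    dried_weight: float = np.nan  # mg
    n_percent: float | None = None  # %% of dry mass
    exclusion_flag: str = "none"

    def __post_init__(self) -> None:
        if self.exclusion_flag not in EXCLUSION_FLAGS:
            raise ValueError(f"unknown exclusion flag {self.exclusion_flag!r}")
        if self.n_percent is not None and not np.isfinite(self.n_percent):
            self.n_percent = None
        if self.n_percent is None and self.exclusion_flag not in (
            "too_small", "acquisition_error"
        ):
            # an under-weight leaf returns no laboratory N%; such rows are
            # legal before cleaning has assigned the too_small flag
            if not (np.isfinite(self.dried_weight) and self.dried_weight < 100.0):
                raise ValueError(
                    f"record {self.sample_id!r}: n_percent missing but record is "
                    f"not flagged too_small/acquisition_error"
                )


@dataclass
class BandSpec:
    """A sensor band layout: ordered band centres (nm) with per-band FWHM."""

    centres: np.ndarray
    fwhm: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.centres = _as_float_array(self.centres)
        fwhm = np.asarray(self.fwhm, dtype=float)
        if fwhm.ndim == 0:
            fwhm = np.full(self.centres.shape, float(fwhm))
        self.fwhm = fwhm
        if self.centres.size == 0:
            raise ValueError(f"band spec {self.label!r}: no bands")
        if self.fwhm.size != self.centres.size:
            raise ValueError(f"band spec {self.label!r}: centre/FWHM length mismatch")
        if np.any(np.diff(self.centres) <= 0):
            raise ValueError(f"band spec {self.label!r}: centres not strictly increasing")
        if np.any(self.fwhm <= 0):
            raise ValueError(f"band spec {self.label!r}: FWHM must be positive")

    @property
    def n_bands(self) -> int:
        return int(self.centres.size)


@dataclass
class Dataset:
    """Spectra keyed by sample id plus their ledger records, on one shared grid."""

    spectra: dict[str, Spectrum]
    records: list[SampleRecord]
    wavelength_range_label: str = "FULL"

    def __post_init__(self) -> None:
        record_ids = {r.sample_id for r in self.records}
        for sid in self.spectra:
            if sid not in record_ids:
                raise ValueError(f"spectrum {sid!r} has no matching ledger record")
        grids = [s.wavelengths for s in self.spectra.values()]
        for g in grids[1:]:
            if g.size != grids[0].size or np.any(
                np.abs(g - grids[0]) > WAVELENGTH_TOL
            ):
                raise GridMismatchError(
                    "spectra in a Dataset must share one wavelength grid"
                )

    @property
    def wavelengths(self) -> np.ndarray:
        return next(iter(self.spectra.values())).wavelengths

    @property
    def sample_ids(self) -> list[str]:
        """Sample ids present in both stores, in deterministic (sorted) order."""
        return sorted(self.spectra)

    def design_matrix(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Return (X, y, sample_ids) for samples that have a reference N%%."""
        ids = [
            sid for sid in self.sample_ids
            if self._record(sid).n_percent is not None
        ]
        X = np.vstack([self.spectra[sid].values for sid in ids])
        y = np.array([self._record(sid).n_percent for sid in ids], dtype=float)
        return X, y, ids

    def _record(self, sample_id: str) -> SampleRecord:
        for r in self.records:
            if r.sample_id == sample_id:
                return r
        raise KeyError(sample_id)

    def subset(self, sample_ids: Sequence[str]) -> "Dataset":
        keep = set(sample_ids)
        return Dataset(
            {sid: s for sid, s in self.spectra.items() if sid in keep},
            [r for r in self.records if r.sample_id in keep],
            self.wavelength_range_label,
        )


# ---------------------------------------------------------------------------
# spectra table I/O: wide CSV + YAML sidecar
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def write_spectra_table(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra as a wide CSV (wavelength + one column per sample).

    FWHM, sensor id and detector segments go to a YAML sidecar next to the
    CSV.  All spectra must share one wavelength grid.
    """
    path = Path(path)
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to write")
    grid = spectra[0].wavelengths
    for s in spectra[1:]:
        if s.n_bands != spectra[0].n_bands or np.any(
            np.abs(s.wavelengths - grid) > WAVELENGTH_TOL
        ):
            raise GridMismatchError("spectra must share one grid to be written together")
    columns = {"wavelength_nm": grid}
    columns.update((s.sample_id, s.values) for s in spectra)
    pd.DataFrame(columns).to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "sensor_id": spectra[0].sensor_id,
        "fwhm_nm": [float(v) for v in spectra[0].fwhm],
        "detector_segments": [[int(a), int(b)] for a, b in spectra[0].detector_segments],
    }
    _sidecar_path(path).write_text(yaml.safe_dump(sidecar, sort_keys=False))


def read_spectra_table(path: str | Path, sensor_id: str | None = None) -> list[Spectrum]:
    """Read a wide spectra CSV (+ YAML sidecar) back into Spectrum objects."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - wrap any parse failure
        raise FormatError(f"cannot parse spectra table {path}: {exc}") from exc
    if "wavelength_nm" not in df.columns:
        raise FormatError(f"{path}: missing 'wavelength_nm' column")
    grid = df["wavelength_nm"].to_numpy(dtype=float)
    if grid.size == 0:
        raise FormatError(f"{path}: empty table")
    if np.any(np.diff(grid) <= WAVELENGTH_TOL):
        raise FormatError(f"{path}: wavelengths not strictly increasing")
    sidecar_file = _sidecar_path(path)
    fwhm: np.ndarray | float = 1.0
    segments: list[tuple[int, int]] = []
    sc_sensor = ""
    if sidecar_file.exists():
        meta = yaml.safe_load(sidecar_file.read_text()) or {}
        if "fwhm_nm" in meta:
            fwhm = np.asarray(meta["fwhm_nm"], dtype=float)
            if fwhm.size != grid.size:
                raise FormatError(f"{sidecar_file}: FWHM length mismatch")
        segments = [tuple(seg) for seg in meta.get("detector_segments", [])]
        sc_sensor = meta.get("sensor_id", "")
    sensor = sensor_id if sensor_id is not None else sc_sensor
    out = []
    for col in df.columns:
        if col == "wavelength_nm":
            continue
        vals = df[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            raise FormatError(f"{path}: non-numeric/missing value in column {col!r}")
        out.append(
            Spectrum(str(col), grid.copy(), vals, fwhm, sensor,
                     [tuple(s) for s in segments])
        )
    if not out:
        raise FormatError(f"{path}: no sample columns")
    return out


# ---------------------------------------------------------------------------
# ENVI cube I/O (header + flat binary raster; bil/bip/bsq)
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
                5: np.float64, 12: np.uint16}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().upper().startswith("ENVI"):
        raise FormatError("not an ENVI header (missing 'ENVI' magic)")
    fields: dict[str, str] = {}
    # key = value, where value may be a {...} block spanning lines
    pattern = re.compile(r"^\s*([a-zA-Z][a-zA-Z0-9 _.-]*?)\s*=\s*(\{.*?\}|[^\n]*)",
                         re.DOTALL | re.MULTILINE)
    pos = 0
    body = text
    while True:
        m = pattern.search(body, pos)
        if m is None:
            break
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        fields[key] = val
        pos = m.end()
    return fields


def _parse_list(val: str) -> np.ndarray:
    inner = val.strip().lstrip("{").rstrip("}")
    return np.array([float(tok) for tok in inner.replace("\n", " ").split(",")
                     if tok.strip()], dtype=float)


def read_envi_cube(path: str | Path) -> SpectralCube:
    """Read an ENVI raster (``path`` + ``path``.hdr or sibling .hdr).

    Returns an uncalibrated cube in (row, col, band) order regardless of the
    file's interleave.  A missing wavelength list is a format error.
    """
    path = Path(path)
    hdr_path = path.with_suffix(path.suffix + ".hdr")
    if not hdr_path.exists():
        hdr_path = path.with_suffix(".hdr")
    if not hdr_path.exists():
        raise FormatError(f"no ENVI header found for {path}")
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields.get("interleave", "bsq").lower()
    except KeyError as exc:
        raise FormatError(f"{hdr_path}: missing required field {exc}") from exc
    if "wavelength" not in fields:
        raise FormatError(f"{hdr_path}: missing wavelength metadata")
    wavelengths = _parse_list(fields["wavelength"])
    if wavelengths.size != bands:
        raise FormatError(f"{hdr_path}: wavelength list length != bands")
    fwhm = (_parse_list(fields["fwhm"]) if "fwhm" in fields
            else np.ones(bands))
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"{hdr_path}: unsupported data type {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    if int(fields.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    raw = np.fromfile(path, dtype=dtype)
    if raw.size != samples * lines * bands:
        raise FormatError(
            f"{path}: data size {raw.size} != samples*lines*bands "
            f"({samples * lines * bands})"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    else:
        raise FormatError(f"{hdr_path}: unknown interleave {interleave!r}")
    sensor = fields.get("sensor type", "").strip("{} ")
    return SpectralCube(np.ascontiguousarray(data.astype(float)),
                        wavelengths, fwhm, calibrated=False, sensor_id=sensor)


def write_envi_cube(cube: SpectralCube, path: str | Path,
                    interleave: str = "bil",
                    dtype: np.dtype | type = np.float64) -> None:
    """Write a cube as ENVI raster + ``.hdr`` sibling header."""
    path = Path(path)
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"unknown interleave {interleave!r}")
    dtype = np.dtype(dtype)
    if dtype not in _ENVI_CODES:
        raise ValueError(f"unsupported dtype {dtype}")
    rows, cols, bands = cube.shape
    data = cube.data.astype(dtype)
    if interleave == "bsq":
        flat = data.transpose(2, 0, 1)
    elif interleave == "bil":
        flat = data.transpose(0, 2, 1)
    else:
        flat = data
    flat.tofile(path)
    wl = ", ".join(f"{v:.6f}" for v in cube.wavelengths)
    fw = ", ".join(f"{v:.6f}" for v in cube.fwhm)
    hdr = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"sensor type = {cube.sensor_id}\n"
        f"wavelength = {{{wl}}}\n"
        f"fwhm = {{{fw}}}\n"
    )
    path.with_suffix(path.suffix + ".hdr").write_text(hdr)


# ---------------------------------------------------------------------------
# sample ledger I/O
# ---------------------------------------------------------------------------

_LEDGER_COLUMNS = ("sample_id", "variety", "n_treatment", "time_point",
                   "dried_weight", "n_percent")


def write_ledger(records: Sequence[SampleRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "sample_id": r.sample_id,
            "variety": r.variety,
            "n_treatment": r.n_treatment,
            "time_point": r.time_point,
            "dried_weight": r.dried_weight,
            "n_percent": "" if r.n_percent is None else r.n_percent,
            "exclusion_flag": r.exclusion_flag,
        })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_ledger(path: str | Path) -> list[SampleRecord]:
    """Read a sample ledger CSV into records (exclusion flags default 'none')."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _LEDGER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    records = []
    for i, row in df.iterrows():
        def num(col: str, required: bool = True) -> float | None:
            raw = row[col].strip()
            if raw == "":
                if required:
                    raise FormatError(f"{path}: row {i}: empty {col!r}")
                return None
            try:
                return float(raw)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: row {i}: malformed numeric in {col!r}: {raw!r}"
                ) from exc

        flag = row.get("exclusion_flag", "none") or "none"
        n_pct = num("n_percent", required=False)
        try:
            records.append(SampleRecord(
                sample_id=row["sample_id"],
                variety=row["variety"],
                n_treatment=num("n_treatment"),
                time_point=int(num("time_point")),
                dried_weight=num("dried_weight"),
                n_percent=n_pct,
                exclusion_flag=flag,
            ))
        except ValueError as exc:
            raise FormatError(f"{path}: row {i}: {exc}") from exc
    return records
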