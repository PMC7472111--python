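"""Synthetic wheat-leaf data with known ground truth.

Real leaf reflectance is a smooth continuum (visible pigment trough,
NIR plateau, SWIR water dips) carved by absorption features.  The
generator emulates that statistical structure — it is not a radiative
transfer model:

* a fixed smooth continuum encoded as control points and interpolated
  with a shape-preserving (PCHIP) spline on a 1 nm master grid;
* nitrogen-sensitive Gaussian absorption dips whose depths grow linearly
  with the sample's N%, centred by default on protein/chlorophyll bands
  (676, 1517, 2106, 2180, 2313 nm);
* nitrogen-independent confounder dips (water bands at 1450/1940 nm)
  with random depths;
* per-sample multiplicative amplitude jitter and additive Gaussian
  noise, drawn independently per sensor;
* resampling onto each sensor's band grid through the same Gaussian
  spectral-response machinery the analysis uses;
* detector splice offsets at configured junction wavelengths
  (spectrometer: 1000 and 1800 nm; merged camera pair: 1000 nm).

N% per sample is drawn from a treatment-shifted normal (means rising
with the soil-nitrogen treatment) clipped to the 1–7% window.  All
randomness flows from a single mandatory seed through named substreams,
so any artefact is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .band_resample import gaussian_weights
from .spectra_core import BandSpec, Dataset, SampleRecord, SpectralCube, Spectrum

# master simulation grid (nm)
MASTER_LO, MASTER_HI = 350.0, 2500.0

#: sensor band layouts: ASD-style 1 nm spectrometer, VNIR camera (5.5 nm),
#: SWIR camera (12 nm)
SENSOR_PRESETS: dict[str, BandSpec] = {
    "asd": BandSpec(np.arange(350.0, 2500.0 + 0.5, 1.0), 1.0, "asd"),
    "fx10": BandSpec(np.arange(400.0, 1000.0 + 1e-9, 5.5), 5.5, "fx10"),
    "swir": BandSpec(np.arange(1000.0, 2500.0 + 1e-9, 12.0), 12.0, "swir"),
}

#: continuum control points resembling a green-leaf reflectance curve
CONTINUUM_POINTS = (
    (350.0, 0.050), (400.0, 0.055), (450.0, 0.070), (500.0, 0.095),
    (550.0, 0.160), (600.0, 0.110), (650.0, 0.085), (680.0, 0.075),
    (705.0, 0.160), (725.0, 0.330), (750.0, 0.450), (800.0, 0.470),
    (900.0, 0.480), (1000.0, 0.470), (1100.0, 0.450), (1200.0, 0.425),
    (1300.0, 0.420), (1400.0, 0.300), (1450.0, 0.260), (1550.0, 0.310),
    (1650.0, 0.330), (1750.0, 0.300), (1850.0, 0.200), (1920.0, 0.115),
    (1980.0, 0.130), (2100.0, 0.180), (2200.0, 0.170), (2300.0, 0.125),
    (2400.0, 0.085), (2500.0, 0.060),
)


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort.

    Absorption features are (centre nm, FWHM nm, depth per unit N%);
    confounders are (centre nm, FWHM nm, max depth) with depths drawn
    uniformly per sample, independent of N%.
    """

    seed: int
    n_samples: int = 300
    varieties: int = 5
    treatments: tuple[float, ...] = (25.0, 50.0, 100.0, 200.0)
    treatment_n_means: tuple[float, ...] = (2.0, 3.0, 4.0, 5.5)
    n_sd: float = 0.6
    n_percent_range: tuple[float, float] = (1.0, 7.0)
    absorption_features: tuple[tuple[float, float, float], ...] = (
        (676.0, 14.0, 0.012),
        (1517.0, 24.0, 0.009),
        (2106.0, 26.0, 0.010),
        (2180.0, 24.0, 0.013),
        (2313.0, 24.0, 0.009),
    )
    confounders: tuple[tuple[float, float, float], ...] = (
        (1450.0, 36.0, 0.05),
        (1940.0, 46.0, 0.07),
    )
    amplitude_jitter_sd: float = 0.05
    noise_sigma: float = 0.005
    splice_junctions: tuple[float, ...] = (1000.0, 1800.0)
    splice_offset_sd: float = 0.02
    camera_gain: float = 1.0    # planted cross-sensor gain distortion
    camera_offset: float = 0.0  # planted cross-sensor additive distortion

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if len(self.treatments) != len(self.treatment_n_means):
            raise ValueError("treatments and treatment_n_means differ in length")
        for c, w, d in self.absorption_features:
            if not MASTER_LO <= c <= MASTER_HI:
                raise ValueError(f"feature centre {c} nm outside master grid")
            if d < 0 or w <= 0:
                raise ValueError("feature depths must be >= 0 and widths > 0")

    @property
    def feature_centres(self) -> np.ndarray:
        return np.array([c for c, _, _ in self.absorption_features])


def master_grid() -> np.ndarray:
    return np.arange(MASTER_LO, MASTER_HI + 0.5, 1.0)


def continuum(wavelengths: np.ndarray | None = None) -> np.ndarray:
    """Smooth green-leaf continuum on the given (default master) grid."""
    lam = master_grid() if wavelengths is None else np.asarray(wavelengths)
    pts = np.array(CONTINUUM_POINTS)
    return PchipInterpolator(pts[:, 0], pts[:, 1])(lam)


def _gauss(lam: np.ndarray, centre: float, fwhm: float) -> np.ndarray:
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((lam - centre) / sigma) ** 2)


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named, order-independent child stream of the master seed."""
    digest = np.frombuffer(name.encode() + b"\x00" * (-len(name) % 4),
                           dtype=np.uint32)
    return np.random.default_rng(np.random.SeedSequence(
        entropy=seed, spawn_key=tuple(int(d) for d in digest)))


@dataclass
class CohortBundle:
    """A generated cohort: per-sensor datasets plus the planted truth."""

    records: list[SampleRecord]
    datasets: dict[str, Dataset]
    master_wavelengths: np.ndarray
    master_clean: np.ndarray       # (n_samples, n_master): pre-jitter, pre-noise
    n_percent: np.ndarray
    feature_centres: np.ndarray
    confounder_depths: np.ndarray
    config: GeneratorConfig = field(repr=False, default=None)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]


def _draw_records(cfg: GeneratorConfig) -> tuple[list[SampleRecord], np.ndarray]:
    rng = _substream(cfg.seed, "meta")
    records = []
    n_percent = np.empty(cfg.n_samples)
    lo, hi = cfg.n_percent_range
    for i in range(cfg.n_samples):
        t_idx = int(rng.integers(len(cfg.treatments)))
        n_pct = float(np.clip(rng.normal(cfg.treatment_n_means[t_idx], cfg.n_sd),
                              lo, hi))
        n_percent[i] = n_pct
        records.append(SampleRecord(
            sample_id=f"S{i:04d}",
            variety=f"V{int(rng.integers(cfg.varieties)) + 1}",
            n_treatment=cfg.treatments[t_idx],
            time_point=i % 3 + 1,
            dried_weight=float(np.clip(rng.normal(260.0, 55.0), 120.0, None)),
            n_percent=n_pct,
        ))
    return records, n_percent


def _master_reflectance(cfg: GeneratorConfig, n_percent: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Clean (pre-jitter, pre-noise) reflectance matrix and confounder depths."""
    lam = master_grid()
    base = continuum(lam)
    rng = _substream(cfg.seed, "confounders")
    n = n_percent.size
    refl = np.tile(base, (n, 1))
    for c, w, d_per_n in cfg.absorption_features:
        refl -= np.outer(n_percent * d_per_n, _gauss(lam, c, w))
    conf_depths = np.empty((n, len(cfg.confounders)))
    for j, (c, w, dmax) in enumerate(cfg.confounders):
        depths = rng.uniform(0.0, dmax, size=n)
        conf_depths[:, j] = depths
        refl -= np.outer(depths, _gauss(lam, c, w))
    return np.clip(refl, 1e-4, None), conf_depths


def _sensor_noise(cfg: GeneratorConfig, clean: np.ndarray, sensor: str
                  ) -> np.ndarray:
    rng = _substream(cfg.seed, f"noise-{sensor}")
    n = clean.shape[0]
    jitter = 1.0 + cfg.amplitude_jitter_sd * rng.standard_normal(n)
    noisy = clean * jitter[:, None]
    if cfg.noise_sigma > 0:
        noisy = noisy + rng.normal(0.0, cfg.noise_sigma, size=clean.shape)
    return noisy


def _segments_from_junctions(centres: np.ndarray,
                             junctions: tuple[float, ...]) -> list[tuple[int, int]]:
    cuts = [0]
    for j in junctions:
        idx = int(np.searchsorted(centres, j, side="right"))
        if 0 < idx < centres.size:
            cuts.append(idx)
    cuts.append(centres.size)
    cuts = sorted(set(cuts))
    return [(a, b) for a, b in zip(cuts, cuts[1:])]


def generate_cohort(cfg: GeneratorConfig,
                    sensors: tuple[str, ...] = ("asd",)) -> CohortBundle:
    """Generate a cohort of leaf signatures for one or more sensors.

    All sensors observe the same underlying samples (same N%, same clean
    master spectra); jitter and noise are drawn independently per sensor.
    Supported sensors: ``asd`` (full-range spectrometer with splice
    offsets at the configured junctions), ``platform`` (VNIR 5.5 nm +
    SWIR 12 nm camera pair merged with a junction offset at 1000 nm) and
    ``fx10`` (VNIR-only benchtop camera).
    """
    records, n_percent = _draw_records(cfg)
    clean, conf_depths = _master_reflectance(cfg, n_percent)
    src = BandSpec(master_grid(), 1.0, "master")
    datasets: dict[str, Dataset] = {}

    for sensor in sensors:
        noisy = _sensor_noise(cfg, clean, sensor)
        if sensor == "asd":
            preset = SENSOR_PRESETS["asd"]
            vals = noisy @ gaussian_weights(src, preset).T
            segs = _segments_from_junctions(preset.centres, cfg.splice_junctions)
            rng = _substream(cfg.seed, "splice-asd")
            offsets = rng.normal(0.0, cfg.splice_offset_sd,
                                 size=(cfg.n_samples, len(segs) - 1))
            for k, (a, b) in enumerate(segs[1:]):
                vals[:, a:b] += offsets[:, :k + 1].sum(axis=1)[:, None]
            spectra = {
                r.sample_id: Spectrum(r.sample_id, preset.centres.copy(),
                                      vals[i], preset.fwhm.copy(), "asd",
                                      list(segs))
                for i, r in enumerate(records)
            }
        elif sensor == "platform":
            vn, sw = SENSOR_PRESETS["fx10"], SENSOR_PRESETS["swir"]
            vals_v = noisy @ gaussian_weights(src, vn).T
            vals_s = noisy @ gaussian_weights(src, sw).T
            vals_v = vals_v * cfg.camera_gain + cfg.camera_offset
            vals_s = vals_s * cfg.camera_gain + cfg.camera_offset
            keep = sw.centres > vn.centres[-1] + 1e-6
            rng = _substream(cfg.seed, "splice-platform")
            offsets = rng.normal(0.0, cfg.splice_offset_sd, size=cfg.n_samples)
            centres = np.concatenate([vn.centres, sw.centres[keep]])
            fwhm = np.concatenate([vn.fwhm, sw.fwhm[keep]])
            n_v = vn.n_bands
            segs = [(0, n_v), (n_v, centres.size)]
            spectra = {}
            for i, r in enumerate(records):
                v = np.concatenate([vals_v[i], vals_s[i][keep] + offsets[i]])
                spectra[r.sample_id] = Spectrum(
                    r.sample_id, centres.copy(), v, fwhm.copy(),
                    "fx10+swir", list(segs))
        elif sensor == "fx10":
            preset = SENSOR_PRESETS["fx10"]
            vals = noisy @ gaussian_weights(src, preset).T
            vals = vals * cfg.camera_gain + cfg.camera_offset
            spectra = {
                r.sample_id: Spectrum(r.sample_id, preset.centres.copy(),
                                      vals[i], preset.fwhm.copy(), "fx10")
                for i, r in enumerate(records)
            }
        else:
            raise ValueError(f"unknown sensor preset {sensor!r}")
        datasets[sensor] = Dataset(spectra, records)

    return CohortBundle(records, datasets, master_grid(), clean, n_percent,
                        cfg.feature_centres, conf_depths, cfg)


# ---------------------------------------------------------------------------
# hyperspectral cube generation
# ---------------------------------------------------------------------------


@dataclass
class CubeLayout:
    """Spatial layout of a synthetic leaf-bed image (pixel coordinates)."""

    shape: tuple[int, int] = (48, 64)
    marker_rect: tuple[int, int, int, int] = (20, 28, 4, 20)  # r0, r1, c0, c1
    leaf_centre: tuple[float, float] = (24.0, 40.0)
    leaf_radii: tuple[float, float] = (9.0, 15.0)             # (rows, cols)
    background_reflectance: float = 0.04
    pixel_variation_sd: float = 0.03
    sensor: str = "fx10"


@dataclass
class CubeBundle:
    """A synthetic raw cube with its calibration frames and planted truth."""

    raw: SpectralCube
    dark: SpectralCube
    white: SpectralCube
    marker_mask: np.ndarray
    leaf_mask: np.ndarray
    planted_reflectance: np.ndarray   # (rows, cols, bands), pre-noise truth
    leaf_mean_truth: np.ndarray       # planted mean leaf signature
    marker_target: np.ndarray         # noise-free blue marker signature
    noise_sigma: float
    sample_id: str


def marker_signature(wavelengths: np.ndarray) -> np.ndarray:
    """Blue fiducial marker: strong reflectance peak around 460 nm."""
    return 0.06 + 0.5 * _gauss(np.asarray(wavelengths, dtype=float), 460.0, 90.0)


def generate_cube(cfg: GeneratorConfig,
                  layout: CubeLayout | None = None,
                  sample_id: str = "CUBE0") -> CubeBundle:
    """Synthetic leaf-bed image: black background, blue marker, leaf pixels.

    Raw intensities are produced by inverting the dark/white calibration
    against generated reference frames, so calibrating the raw cube
    recovers the planted reflectance to numerical precision (before the
    planted per-pixel noise is considered).
    """
    layout = layout or CubeLayout()
    preset = SENSOR_PRESETS[layout.sensor]
    lam, fwhm = preset.centres, preset.fwhm
    rows, cols = layout.shape
    bands = lam.size

    r0, r1, c0, c1 = layout.marker_rect
    marker_mask = np.zeros((rows, cols), dtype=bool)
    marker_mask[r0:r1, c0:c1] = True
    rr, cc = np.mgrid[0:rows, 0:cols]
    ry, rx = layout.leaf_radii
    cy, cx = layout.leaf_centre
    leaf_mask = ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0
    if (marker_mask & leaf_mask).any():
        raise ValueError("cube layout: marker and leaf regions overlap")

    rng = _substream(cfg.seed, f"cube-{sample_id}")
    # one leaf sample drawn from the cohort reflectance model
    lo, hi = cfg.n_percent_range
    t_idx = int(rng.integers(len(cfg.treatments)))
    n_pct = float(np.clip(rng.normal(cfg.treatment_n_means[t_idx], cfg.n_sd), lo, hi))
    base = continuum(master_grid())
    master = base.copy()
    for c, w, d in cfg.absorption_features:
        master -= n_pct * d * _gauss(master_grid(), c, w)
    for j, (c, w, dmax) in enumerate(cfg.confounders):
        master -= rng.uniform(0.0, dmax) * _gauss(master_grid(), c, w)
    src = BandSpec(master_grid(), 1.0, "master")
    leaf_base = gaussian_weights(src, preset) @ np.clip(master, 1e-4, None)
    target = marker_signature(lam)

    refl = np.empty((rows, cols, bands))
    refl[:] = layout.background_reflectance
    refl[marker_mask] = target
    n_leaf = int(leaf_mask.sum())
    pixvar = 1.0 + layout.pixel_variation_sd * rng.standard_normal((n_leaf, 1))
    leaf_pixels = leaf_base[None, :] * pixvar
    refl[leaf_mask] = leaf_pixels
    planted = refl.copy()
    if cfg.noise_sigma > 0:
        refl = refl + rng.normal(0.0, cfg.noise_sigma, size=refl.shape)
    refl = np.clip(refl, 1e-6, None)

    dark_vals = 96.0 + 0.01 * (lam - lam[0])
    white_vals = 2800.0 + 400.0 * np.sin(2.0 * np.pi * (lam - lam[0]) / 900.0)
    dark = np.broadcast_to(dark_vals, (rows, cols, bands)).copy()
    white = np.broadcast_to(white_vals, (rows, cols, bands)).copy()
    raw = dark + refl * (white - dark)

    mk = dict(wavelengths=lam.copy(), fwhm=fwhm.copy(), sensor_id=layout.sensor)
    return CubeBundle(
        raw=SpectralCube(raw, calibrated=False, **mk),
        dark=SpectralCube(dark, calibrated=False, **mk),
        white=SpectralCube(white, calibrated=False, **mk),
        marker_mask=marker_mask,
        leaf_mask=leaf_mask,
        planted_reflectance=planted,
        leaf_mean_truth=leaf_pixels.mean(axis=0),
        marker_target=target,
        noise_sigma=cfg.noise_sigma,
        sample_id=sample_id,
    )


# ---------------------------------------------------------------------------
# pathological ledgers for the cleaning rules
# ---------------------------------------------------------------------------


def generate_ledger_for_cleaning(n_total: int, n_too_small: int,
                                 n_outlier: int, n_error: int,
                                 seed: int) -> list[SampleRecord]:
    """Ledger with exactly the requested pathological records (disjoint).

    too-small leaves get dried weights below 100 mg and no N%;
    outliers get N% outside [1, 7]; acquisition errors carry their flag.
    """
    if min(n_too_small, n_outlier, n_error) < 0:
        raise ValueError("category counts must be non-negative")
    if n_too_small + n_outlier + n_error > n_total:
        raise ValueError(
            f"infeasible ledger: {n_too_small}+{n_outlier}+{n_error} "
            f"pathological records > {n_total} total"
        )
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(17,)))
    kinds = (["too_small"] * n_too_small + ["n_outlier"] * n_outlier
             + ["acquisition_error"] * n_error
             + ["valid"] * (n_total - n_too_small - n_outlier - n_error))
    rng.shuffle(kinds)
    records = []
    for i, kind in enumerate(kinds):
        sid = f"L{i:04d}"
        variety = f"V{int(rng.integers(5)) + 1}"
        treatment = float(rng.choice([25.0, 50.0, 100.0, 200.0]))
        tp = i % 3 + 1
        if kind == "too_small":
            rec = SampleRecord(sid, variety, treatment, tp,
                               dried_weight=float(rng.uniform(40.0, 99.0)),
                               n_percent=None)
        elif kind == "n_outlier":
            n_pct = (float(rng.uniform(0.2, 0.95)) if rng.random() < 0.5
                     else float(rng.uniform(7.05, 9.0)))
            rec = SampleRecord(sid, variety, treatment, tp,
                               dried_weight=float(rng.uniform(120.0, 400.0)),
                               n_percent=n_pct)
        elif kind == "acquisition_error":
            rec = SampleRecord(sid, variety, treatment, tp,
                               dried_weight=float(rng.uniform(120.0, 400.0)),
                               n_percent=None,
                               exclusion_flag="acquisition_error")
        else:
            rec = SampleRecord(sid, variety, treatment, tp,
                               dried_weight=float(rng.uniform(120.0, 400.0)),
                               n_percent=float(rng.uniform(1.5, 6.5)))
        records.append(rec)
    return records
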