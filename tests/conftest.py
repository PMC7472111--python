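import numpy as np
import pytest

import hyperleaf as hl


def preprocess_asd(bundle: hl.CohortBundle) -> hl.Dataset:
    """Standard spectrometer preprocessing for a generated cohort."""
    keep = [r.sample_id for r in hl.clean(bundle.records)]
    spectra = {
        sid: hl.preprocess_signature(bundle.datasets["asd"].spectra[sid])
        for sid in keep
    }
    return hl.Dataset(spectra, bundle.records)


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic study cohort (n=300, noise 0.005), seed 1."""
    cfg = hl.GeneratorConfig(seed=1)
    return hl.generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_fit(default_cohort):
    """Cross-validated PLSR fit of the default cohort (spectrometer, FULL)."""
    data = preprocess_asd(default_cohort)
    return hl.fit_plsr_cv(data, seed=1)


@pytest.fixture(scope="session")
def segmentation_run():
    """A synthetic leaf-bed cube pushed through the extraction stages."""
    cfg = hl.GeneratorConfig(seed=5)
    bundle = hl.generate_cube(cfg)
    cube, invalid = hl.calibrate_cube(bundle.raw, bundle.dark, bundle.white)
    marker = hl.detect_marker(cube, bundle.marker_target, 0.2)
    roi = hl.locate_roi(marker)
    hue, _ = hl.hyper_hue_image(cube)
    rng = np.random.default_rng(5)
    leaf_idx = np.argwhere(bundle.leaf_mask)
    sel = leaf_idx[rng.choice(len(leaf_idx), 200, replace=False)]
    training = hue[sel[:, 0], sel[:, 1]]
    leaf = hl.segment_leaf(cube, roi, training, nu=0.1)
    return {
        "bundle": bundle, "cube": cube, "invalid": invalid,
        "marker": marker, "roi": roi, "training": training, "leaf": leaf,
    }
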