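import numpy as np
import pytest

import autoaif as aa

try:
    from hypothesis import settings

    settings.register_profile("ci", deadline=None, derandomize=True)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def schedule():
    """The 62-frame / 65-min dynamic acquisition grid."""
    return aa.build_frame_schedule(aa.PAPER_FRAME_SPEC)


@pytest.fixture(scope="session")
def default_phantom():
    """One seeded realization of the default head phantom."""
    return aa.build_phantom(aa.PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free phantom at the default resolution (partial volume only)."""
    return aa.build_phantom(aa.PhantomSpec(seed=0, noise_scale=0.0))


@pytest.fixture(scope="session")
def pristine_phantom():
    """Phantom without blur or noise (ground-truth structure only)."""
    return aa.build_phantom(aa.PhantomSpec(seed=0, noise_scale=0.0, psf_fwhm_mm=0.0))


@pytest.fixture(scope="session")
def extracted_default(default_phantom):
    """Full pipeline run (mask, TAC matrix, IDIF extraction) on the default phantom."""
    image, truth = default_phantom
    mask = aa.brain_mask(image)
    tacs = aa.extract_tac_matrix(image, mask)
    ext = aa.IDIFExtractor().fit(tacs, schedule=image.schedule)
    return image, truth, tacs, ext


@pytest.fixture(scope="session")
def region_lookup(default_phantom):
    """Map voxel coordinate tuples to ground-truth region names."""
    image, truth = default_phantom

    def build():
        lut = {}
        for name in ("artery", "vein", "da", "gm", "wm", "perivascular"):
            for c in getattr(truth, f"{name}_mask").coords:
                lut[tuple(int(v) for v in c)] = name
        return lut

    return build()


@pytest.fixture(scope="session")
def truth_aif_frames(default_phantom):
    image, truth = default_phantom
    return truth.true_aif
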