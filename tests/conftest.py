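import numpy as np
import pytest

from breastseg.core import BinaryMask
from breastseg.phantom import PhantomConfig, generate_phantom
from breastseg.pipeline import PipelineConfig, segment_study


@pytest.fixture(scope="session")
def default_phantom():
    """Default phantom (seed 7): two symmetric breasts, 10% FG, 8 mm tumor,
    <2 mm inter-sequence shift."""
    return generate_phantom(PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def pipeline_result(default_phantom):
    study, _ = default_phantom
    return segment_study(study, PipelineConfig())


@pytest.fixture(scope="session")
def cropped_truth(default_phantom, pipeline_result):
    """Ground-truth masks cropped to the pipeline's relevant-slice range."""
    _, truth = default_phantom
    lo, hi = pipeline_result.slice_range

    def crop(mask):
        return BinaryMask(mask.voxels[lo : hi + 1], mask.spacing, mask.name)

    return {
        "breast": crop(truth.breast),
        "fat": crop(truth.fat),
        "fg": crop(truth.fg),
        "tumor": crop(truth.tumor),
        "skin": crop(truth.skin),
        "pectoral": crop(truth.pectoral),
        "body": crop(truth.body),
        "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
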