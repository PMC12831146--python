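import sys
import warnings
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ccpsv import SyntheticSceneParams, generate_cc_scene

# statsmodels MixedLM emits convergence chatter on boundary fits that the
# package records on the result object instead.
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def small_scene():
    """A 256-px noise-free attenuated scene shared by read-only tests."""
    return generate_cc_scene(
        SyntheticSceneParams(
            raster_px=256, seed=7, attenuation_amplitude=0.3, noise_sd=0.0, n_psv=2
        )
    )
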