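import numpy as np
import pytest
from hypothesis import settings

from amyquant import segment_slide
from amyquant.simulate import clean_section_spec, render_slide

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_section():
    """The canonical 4000x4000 px section (200 plaques, 50 artifacts),
    rendered once and segmented once for the whole session."""
    spec = clean_section_spec(seed=1)
    slide, truth = render_slide(spec)
    result = segment_slide(slide)
    return spec, slide, truth, result


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
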