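import numpy as np
import pytest

from overscanqa.phantom import Anatomy, PhantomSpec, generate_phantom
from overscanqa.segmentation import LandmarkMask


#: compact anatomy used where full-length volumes would be wasteful:
#: short lungs and kidneys, everything else as in the default layout
COMPACT = Anatomy(
    cartilage_span=(0.0, 12.0),
    pyriform_span=(-20.0, -6.0),
    lung_span=(12.0, 80.0),
    kidney_span=(86.0, 146.0),
    airway_bottom=40.0,
)


@pytest.fixture
def compact_anatomy():
    return COMPACT


@pytest.fixture
def make_phantom():
    """Factory for compact phantoms: make(superior, inferior, **overrides)."""

    def _make(superior=4.0, inferior=0.0, **kw):
        kw.setdefault("anatomy", COMPACT)
        kw.setdefault("shape", (96, 96))
        kw.setdefault("noise_sigma", 0.0)
        kw.setdefault("seed", 0)
        spec = PhantomSpec(
            superior_margin=superior, inferior_margin=inferior, **kw
        )
        return generate_phantom(spec)

    return _make


def oracle_masks(truth):
    """Ground-truth landmark masks wrapped for the decision stage."""
    return {
        "cartilage_mask": LandmarkMask(
            truth.masks["thyroid_cartilage"], "thyroid_cartilage", "oracle"
        ),
        "kidney_mask": LandmarkMask(truth.masks["kidney"], "kidney", "oracle"),
    }
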