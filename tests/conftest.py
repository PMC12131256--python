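import numpy as np
import pytest

from probemech.ingest import BendingTrace, CrossSection, Geometry, SampleRecord
from probemech.synth import SyntheticConfig, generate_cohort


@pytest.fixture
def geometry():
    return Geometry(span_L=0.1, offset_a=0.025)


@pytest.fixture
def linear_trace(geometry):
    """Exact line F = 50 x over 20 points."""
    x = np.linspace(0, 0.005, 20)
    return BendingTrace("lin", x, 50.0 * x, geometry.span_L, geometry.offset_a)


def make_record(sample_id="s1", plant_id="p1", **kw):
    defaults = dict(
        species="sp1",
        mound_id="GTM001",
        plant_part="stem",
        material_type="twig",
        section=CrossSection(shape="circular", radius=0.0015),
        length=0.3,
        tool_source_species=True,
        preference="most_preferred",
        plant_used=True,
    )
    defaults.update(kw)
    return SampleRecord(sample_id=sample_id, plant_id=plant_id, **defaults)


@pytest.fixture
def small_cohort():
    cfg = SyntheticConfig(seed=11)
    records, truth = generate_cohort(cfg)
    return cfg, records, truth
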