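import numpy as np
import pytest

from spiralfield.field_fill import (
    BackgroundCondition,
    Condition,
    FieldSpec,
    StimulusField,
    make_stimulus,
)
from spiralfield.geometry import (
    SpiralSpec,
    apply_orientation_jitter,
    draw_pose,
    place_contour,
    pose_pattern,
    tail_location,
)


@pytest.fixture(scope="session")
def spec() -> SpiralSpec:
    """Default spiral spec with the calibrated angular scale resolved."""
    s = SpiralSpec()
    s.resolved_kappa()  # warm the calibration cache once per session
    return s


@pytest.fixture(scope="session")
def field_spec() -> FieldSpec:
    return FieldSpec()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def clean_field_factory(spec, field_spec):
    """Distracter-free posed spiral fields (the preliminary-experiment
    stimulus configuration)."""

    def make(spacing_deg: float, jitter_deg: float, seed: int) -> StimulusField:
        rng = np.random.default_rng(seed)
        chain = place_contour(spec, spacing_deg, rng=rng)
        chain = apply_orientation_jitter(chain, jitter_deg, rng)
        pose = draw_pose(chain.elements, field_spec.extent, rng)
        posed = pose_pattern(chain.elements, pose, field_spec.extent)
        return StimulusField(
            field_spec=field_spec, elements=tuple(posed),
            condition=Condition(spacing_deg=spacing_deg, jitter_deg=jitter_deg),
            tail=tail_location(chain, pose), pose=pose)

    return make


@pytest.fixture(scope="session")
def small_cluttered_field():
    """One fully assembled 6-lambda stimulus (cheap to fill)."""
    rng = np.random.default_rng(7)
    return make_stimulus(Condition(spacing_deg=1.8), rng)
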