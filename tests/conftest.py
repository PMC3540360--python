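import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from beadpk.profiles import (
    Analyte,
    ConcentrationProfile,
    Phase,
    Route,
    SamplePoint,
)


def make_profile(
    times,
    concs,
    route=Route.IV,
    analyte=Analyte.PARENT,
    dose_mg=174.6,
    infusion_duration_h=1.0,
    subject="s1",
    phase=None,
):
    """Build a valid profile from parallel time/concentration arrays.

    ``concs`` entries that are None become BLOQ points.
    """
    if phase is None:
        phase = Phase.PRIMARY_IV if route is Route.IV else Phase.PRIMARY_EMBOLIZATION
    points = tuple(
        SamplePoint(float(t), None, True) if c is None else SamplePoint(float(t), float(c))
        for t, c in zip(times, concs)
    )
    return ConcentrationProfile(
        subject_id=subject,
        phase=phase,
        route=route,
        analyte=analyte,
        dose_mg=dose_mg,
        infusion_duration_h=infusion_duration_h if route is Route.IV else None,
        points=points,
    )


@pytest.fixture
def mono_exponential():
    """Noise-free mono-exponential profile factory: C(t) = c0 * exp(-k t)."""

    def factory(k, c0=1000.0, times=None):
        if times is None:
            times = np.array([0.0, 0.5, 1, 2, 3, 4, 6, 9, 12, 16, 20])
        return make_profile(times, c0 * np.exp(-k * np.asarray(times, dtype=float)))

    return factory
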