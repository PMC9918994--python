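import numpy as np
import pytest

from isofuzz.isokinetic_model import (
    MEASUREMENT_FIELDS,
    MODES,
    ParticipantMeasurements,
    build_default_model,
)


@pytest.fixture(scope="session")
def model():
    return build_default_model()


def make_participant(pid="p1", **overrides):
    """All-zero participant, with overrides as e.g. ratio_R_60=55."""
    values = {m: {f: 0.0 for f in MEASUREMENT_FIELDS} for m in MODES}
    for key, v in overrides.items():
        field, mode = key.rsplit("_", 1)
        values[int(mode)][field] = v
    return ParticipantMeasurements(participant_id=pid, values=values)


def optimal_inputs():
    """Mid-kernel ratios, domain-max torque inputs for every mode."""
    return {
        60: dict(ratio_R=55.0, ratio_L=55.0, away_R=4.5, away_L=4.5, toward_R=3.0, toward_L=3.0),
        180: dict(ratio_R=55.0, ratio_L=55.0, away_R=3.0, away_L=3.0, toward_R=3.0, toward_L=3.0),
        300: dict(ratio_R=72.5, ratio_L=72.5, away_R=2.8, away_L=2.8, toward_R=2.8, toward_L=2.8),
    }


def numeric_cog(agg, step=1e-5):
    """Independent trapezoidal-rule centroid of a piecewise-linear function."""
    xs = np.array([x for x, _ in agg.breakpoints])
    mus = np.array([mu for _, mu in agg.breakpoints])
    grid = np.arange(xs[0], xs[-1] + step, step)
    vals = np.interp(grid, xs, mus)
    area = np.trapezoid(vals, grid)
    moment = np.trapezoid(grid * vals, grid)
    return moment / area
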