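import numpy as np
import pytest

from titracam import (
    DosePoint,
    TitrationCurve,
    make_reading,
)


def replicates_with(mean: float, sd: float, n: int = 9) -> list:
    """Construct n values with exactly the requested sample mean and SD."""
    base = np.arange(n, dtype=float)
    base -= base.mean()
    norm = base.std(ddof=1)
    if sd == 0.0:
        return [mean] * n
    return list(mean + sd * base / norm)


def make_curve(volumes, rgb_rows, indicator=None, increment=None) -> TitrationCurve:
    points = [
        DosePoint(volume=float(v), reading=make_reading(*map(float, rgb)))
        for v, rgb in zip(volumes, rgb_rows)
    ]
    return TitrationCurve(points=points, indicator=indicator, increment=increment)


@pytest.fixture
def step_curve():
    """Ideal step: 200 for V <= 2.00, 100 for V >= 2.02 on a 0.02 mL grid."""
    volumes = np.round(np.arange(0, 4.001, 0.02), 4)
    rgb = [(200, 50, 50) if v <= 2.00 else (100, 50, 50) for v in volumes]
    return make_curve(volumes, rgb, increment=0.02)
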