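import numpy as np
import pytest

from roadvib.displacement import TrialResult
from roadvib.logio import Annotation, GnssFix, LoggerTrace
from roadvib.synthetic import reference_table


@pytest.fixture
def rng():
    return np.random.default_rng(20220523)


@pytest.fixture
def make_trace():
    """Factory for small random traces with all record types populated."""

    def _make(n=103, f=5, seed=0, with_gnss=True, with_aux=True):
        r = np.random.default_rng(seed)
        accel = r.normal(0.0, 0.3, size=(n, 3))
        duration = n / f
        gnss = (
            [
                GnssFix(time=t, lat=52.0 + 0.001 * t, lon=13.0 + 0.002 * t, elevation=40.0 + t)
                for t in np.linspace(0, duration, 8)
            ]
            if with_gnss
            else []
        )
        aux = {"temperature": [(0.0, 17.2), (duration / 2, 17.5)]} if with_aux else {}
        annotations = [
            Annotation(time=0.0, kind="road_surface", value="B"),
            Annotation(time=0.0, kind="speed", value=60.0),
            Annotation(time=min(3.0, duration), kind="event", value="pothole"),
        ]
        return LoggerTrace(
            f=f,
            accel=accel,
            aux=aux,
            gnss=gnss,
            annotations=annotations,
            meta={"date": "2022-05-23T08:00:00", "device": "nano33ble"},
        )

    return _make


@pytest.fixture(scope="session")
def reference_frame():
    """Packaged per-category road-trial reference parameters."""
    return reference_table()


@pytest.fixture(scope="session")
def reference_trials(reference_frame):
    """120 trials whose per-category sample mean and SD exactly equal the
    packaged reference values (10 replicates per cell, fixed spread shape)."""
    z = np.array([-1.5, -1.0, -0.5, -0.25, -0.1, 0.1, 0.25, 0.5, 1.0, 1.5])
    z = (z - z.mean()) / z.std(ddof=1)
    trials = []
    for row in reference_frame.itertuples(index=False):
        for v in row.mean_dbar + row.sd_dbar * z:
            trials.append(
                TrialResult(
                    surface=row.surface,
                    speed=float(row.speed),
                    dbar=float(v),
                    min_di=min(float(v), float(row.min_di)),
                    max_di=max(float(v), float(row.max_di)),
                    seconds=60.0,
                )
            )
    return trials
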