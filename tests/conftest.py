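import numpy as np
import pytest

from ecohorizon.proficiency import ForecastEnsemble, ProficiencyCurve, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_trajectory(values, unit="generation", label=""):
    values = np.asarray(values, dtype=float)
    return Trajectory(times=np.arange(len(values), dtype=float), values=values,
                      unit=unit, label=label)


def make_ensemble(truth, *forecasts):
    t = make_trajectory(truth)
    return ForecastEnsemble(truth=t, forecasts=tuple(make_trajectory(f) for f in forecasts))


def make_curve(distances, values, metric="synthetic", higher=True, unit="arbitrary", **kw):
    return ProficiencyCurve(
        distances=np.asarray(distances, dtype=float),
        mean_proficiency=np.asarray(values, dtype=float),
        metric_name=metric, higher_is_better=higher, unit=unit, **kw,
    )
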