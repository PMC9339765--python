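import numpy as np
import pytest

from sessilecmr import (
    DetectionDataset,
    IndividualRecord,
    PlotInfo,
    SimulationConfig,
    SurveyorInfo,
    filter_closure,
    simulate_population,
)


def make_dataset(matrix, experience=None, plot_id="P", lost=None, area=100.0):
    """Build a single-plot dataset from a 0/1 matrix (helpers for tests)."""
    m = np.asarray(matrix, dtype=np.int8)
    n, T = m.shape
    sids = [f"S{t + 1}" for t in range(T)]
    exp = experience or ["novice"] * T
    lost = lost or [False] * n
    return DetectionDataset(
        surveyors={s: SurveyorInfo(s, e, frozenset({plot_id})) for s, e in zip(sids, exp)},
        plots={plot_id: PlotInfo(plot_id, area=area)},
        individuals={
            plot_id: [
                IndividualRecord(f"h{i + 1}", plot_id, lost=lost[i]) for i in range(n)
            ]
        },
        occasions={plot_id: sids},
        matrices={plot_id: m},
    )


@pytest.fixture(scope="session")
def study_dataset():
    """The default three-plot synthetic study, closure-filtered."""
    ds = simulate_population(SimulationConfig(seed=1))
    ds, _ = filter_closure(ds)
    return ds


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
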