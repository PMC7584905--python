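import pytest

from universalize import (
    ChoiceParams,
    StrategyMixture,
    ThresholdScenario,
    condition_bounds,
    make_idealized_threshold_curve,
)

CONDITIONS = ("4_7", "10_13")
NI_GRID = (0, 2, 7, 8, 13, 19)


@pytest.fixture(scope="session")
def idealized_curves():
    """Idealized 1-to-0 threshold curves for the two design conditions."""
    return {
        c: make_idealized_threshold_curve(20, *condition_bounds(c), 1.0, 0.0)
        for c in CONDITIONS
    }


@pytest.fixture
def scenario_4_7(idealized_curves):
    return ThresholdScenario(
        n_total=20,
        n_interested=7,
        curve=idealized_curves["4_7"],
        harm_onset=4,
        collapse_point=7,
    )


@pytest.fixture(scope="session")
def universalizer_only():
    """A population of pure universalizers with the recovery-test parameters."""
    return StrategyMixture(0.0, 0.0, 1.0, ChoiceParams(tau=3.0, beta=-0.5))
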