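import pytest

from pursuitkit import AnimalSpec
from pursuitkit.synthetic import make_scenario_battery


@pytest.fixture
def cursor30():
    """A 30 kg cursor (cheetah/wolf class) with default constants."""
    return AnimalSpec(mass=30.0)


@pytest.fixture
def big_cat250():
    """A 250 kg predator (lion/tiger class)."""
    return AnimalSpec(mass=250.0)


@pytest.fixture
def prey_masses():
    """The canonical prey mass ladder: hare to hartebeest."""
    return (3.0, 10.0, 40.0, 100.0, 200.0)


@pytest.fixture
def single_turn_scenario():
    """Canonical single-90°-turn gambit: 20 vs 15 m/s, 0.3 s reaction,
    turn triggered at 10 m."""
    return make_scenario_battery()[0]
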