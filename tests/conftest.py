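import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from plastodecay import simulate as sim


@pytest.fixture(scope="session")
def mini_plastome():
    """One built mini blueprint genome plus its reference CDS set."""
    blueprint = sim.mini_blueprint(11)
    record, truth = sim.build_plastome(blueprint)
    refs = {g.name: record.feature_sequence(record.gene(g.name))
            for g in blueprint.genes if g.feature_class == "CDS"}
    return blueprint, record, truth, refs


@pytest.fixture(scope="session")
def desk_plastome():
    blueprint = sim.desk_blueprint(7)
    record, truth = sim.build_plastome(blueprint)
    return blueprint, record, truth
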