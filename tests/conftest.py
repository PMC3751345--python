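import numpy as np
import pytest

from comap.model import GenomeMap, Marker
from comap.simulate import random_map


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def simple_map():
    return GenomeMap(
        map_id="demo",
        species="cow",
        chromosome="20",
        units="bp",
        extent_min=0.0,
        extent_max=100.0,
        markers=(
            Marker("mk10", 10.0, 10.0, strand="forward", kind="gene",
                   accession="ACC10"),
            Marker("mk50", 50.0, 50.0),
            Marker("mk90", 90.0, 90.0, strand="reverse"),
        ),
    )


def make_random_map(rng, map_id, n=40, **kwargs):
    return random_map(rng, map_id, n, **kwargs)
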