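import numpy as np
import pandas as pd
import pytest

from ftldtx import synthetic


@pytest.fixture(scope="session")
def small_geom():
    return synthetic.make_geometry(20, "sphere", seed=0)


@pytest.fixture(scope="session")
def small_expr(small_geom):
    donors = synthetic.make_expression(small_geom, 30, 0.4, n_donors=2, seed=1)
    return synthetic.average_expression(donors)


@pytest.fixture(scope="session")
def medium_geom():
    return synthetic.make_geometry(100, "sphere", seed=7)
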