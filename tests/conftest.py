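import numpy as np
import pandas as pd
import pytest

import genomeflux as gf


@pytest.fixture
def tree2():
    return gf.parse_tree("(A:0.7,B:1.2);")


@pytest.fixture
def tree3():
    return gf.parse_tree("((A:0.4,B:0.6):0.3,C:0.8);")


@pytest.fixture
def table1():
    return gf.load_table1_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def make_counts(profiles: dict[str, list[int]], families=None) -> gf.CountMatrix:
    n = len(next(iter(profiles.values())))
    families = families or [f"f{i}" for i in range(n)]
    return gf.CountMatrix(pd.DataFrame(profiles, index=families))


@pytest.fixture
def make_counts_fixture():
    return make_counts
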