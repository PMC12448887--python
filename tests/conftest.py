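import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from alaamnet.data import LayerNetwork, PersonRecord


def make_network(arcs, n, directed, name="test", meta=None):
    """LayerNetwork on integer-labelled nodes '0'..'n-1'."""
    return LayerNetwork([str(i) for i in range(n)],
                        [(str(i), str(j)) for i, j in arcs],
                        directed=directed, name=name, meta=meta)


def make_person(pid, **kw):
    base = dict(person_id=pid, household_id="h" + pid, village="1",
                gender="woman", age=30, education="none", wealth_rank=5,
                community_role="none", ipvaw_accept=0, is_reporter=1)
    base.update(kw)
    return PersonRecord(**base)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_records():
    """Six people in three households, mixed genders, known outcomes."""
    rows = [
        ("000101", "0001", "1", "woman", 1, 1),
        ("000102", "0001", "1", "man", 0, 1),
        ("000103", "0001", "1", "woman", 1, 0),
        ("000201", "0002", "1", "man", 0, 1),
        ("000202", "0002", "2", "woman", 0, 1),
        ("000301", "0003", "2", "man", 1, 0),
    ]
    return [make_person(pid, household_id=hh, village=v, gender=g,
                        ipvaw_accept=acc, is_reporter=rep)
            for pid, hh, v, g, acc, rep in rows]
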