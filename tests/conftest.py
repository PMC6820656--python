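import numpy as np
import pandas as pd
import pytest

from netvuln import RegulatoryNetwork


@pytest.fixture
def toy_network():
    """m1->{a,b}, m2->{b,c}: a and c are single-line, b is shared."""
    return RegulatoryNetwork([("m1", "a"), ("m1", "b"), ("m2", "b"), ("m2", "c")])


@pytest.fixture
def star_network():
    return RegulatoryNetwork([("hub", f"g{i}") for i in range(5)])


@pytest.fixture
def small_expr():
    """6 features x 8 samples with one large planted shift."""
    rng = np.random.default_rng(42)
    samples = [f"S{i}" for i in range(4)] + [f"R{i}" for i in range(4)]
    vals = rng.normal(8.0, 0.5, size=(6, 8))
    vals[0, 4:] += 3.0  # strongly shifted feature
    expr = pd.DataFrame(vals, index=[f"f{i}" for i in range(6)], columns=samples)
    groups = pd.Series(["sensitive"] * 4 + ["resistant"] * 4, index=samples)
    return expr, groups


def random_bipartite(rng, n_mirna=5, n_mrna=8, n_edges=12):
    """Random simple bipartite edge list for oracle comparisons."""
    pairs = [(f"m{i}", f"g{j}") for i in range(n_mirna) for j in range(n_mrna)]
    idx = rng.choice(len(pairs), size=min(n_edges, len(pairs)), replace=False)
    return RegulatoryNetwork([pairs[i] for i in idx])
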