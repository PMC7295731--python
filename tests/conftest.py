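import numpy as np
import pandas as pd
import pytest

from refstab.ct_io import CtTable


def make_table(ct_by_gene, groups=None, replicate=1):
    """CtTable from {gene: [ct per sample]}; optional {sample: group}."""
    genes = list(ct_by_gene)
    n = len(ct_by_gene[genes[0]])
    samples = [f"s{i + 1}" for i in range(n)]
    rows = []
    for g in genes:
        for s, ct in zip(samples, ct_by_gene[g]):
            grp = groups[s] if groups else "all"
            rows.append((s, grp, g, replicate, ct))
    return CtTable(pd.DataFrame(rows, columns=["sample", "group", "gene", "replicate", "ct"]))


@pytest.fixture
def toy_table():
    """Three genes over three samples: A and C share a profile, B is flat."""
    return make_table({"A": [20, 21, 22], "B": [25, 25, 25], "C": [30, 31, 32]})


@pytest.fixture
def random_matrix_factory():
    """Seeded random gene x sample Ct matrices."""

    def factory(seed, k=5, n=12):
        rng = np.random.default_rng(seed)
        base = rng.uniform(15, 30, size=k)
        vals = base[:, None] + rng.normal(0, rng.uniform(0.1, 1.0, size=k)[:, None], (k, n))
        return pd.DataFrame(vals, index=[f"g{i + 1}" for i in range(k)],
                            columns=[f"s{j + 1}" for j in range(n)])

    return factory
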