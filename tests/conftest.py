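import numpy as np
import pandas as pd
import pytest

from fosnet import FosCountTable, SyntheticDesign, gen_fos_counts, load_default_metadata

CHOLINERGIC = ["MA", "NDB", "SI", "MS", "PPN", "MH", "LH"]


def two_block_design(**overrides) -> SyntheticDesign:
    """The planted-partition reference design: 2 blocks of 10 regions."""
    kwargs = dict(
        n_regions=20,
        partition=(tuple(range(10)), tuple(range(10, 20))),
        within_r=0.9,
        between_r=0.0,
        n_subjects_per_group=40,
        group_log_shift=0.3,
        seed=11,
    )
    kwargs.update(overrides)
    return SyntheticDesign(**kwargs)


def cholinergic_table(seed: int = 3, n_extra: int = 5, **overrides) -> FosCountTable:
    """Synthetic table whose first 7 regions carry the cholinergic acronyms.

    BFCS regions form one planted block, BCS a second, remaining regions a
    third, so subsystem contrasts have real structure to find.
    """
    n = 7 + n_extra
    kwargs = dict(
        n_regions=n,
        partition=(tuple(range(3)), tuple(range(3, 7)), tuple(range(7, n))),
        within_r=0.8,
        between_r=-0.2,
        n_subjects_per_group=6,
        seed=seed,
    )
    kwargs.update(overrides)
    table = gen_fos_counts(SyntheticDesign(**kwargs))
    counts = table.counts.copy()
    counts.index = CHOLINERGIC + [f"X{i:02d}" for i in range(n_extra)]
    return FosCountTable(counts=counts, group_of=dict(table.group_of))


@pytest.fixture(scope="session")
def metadata():
    return load_default_metadata()


@pytest.fixture
def toy_table() -> FosCountTable:
    """Tiny deterministic 4-region, 6-subject table."""
    counts = pd.DataFrame(
        {
            "c1": [0, 10, 99, 5],
            "c2": [1, 20, 150, 7],
            "c3": [2, 30, 200, 6],
            "t1": [5, 40, 999, 50],
            "t2": [6, 50, 800, 60],
            "t3": [7, 60, 700, 55],
        },
        index=["A", "B", "C", "D"],
    )
    groups = {s: ("control" if s.startswith("c") else "treatment") for s in counts}
    return FosCountTable(counts=counts, group_of=groups)


def random_graph(rng: np.random.Generator, n_max: int = 12):
    """A random undirected graph with random module labels, for oracles."""
    n = int(rng.integers(3, n_max + 1))
    p = float(rng.uniform(0.1, 0.7))
    nodes = [f"n{i}" for i in range(n)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    modules = {v: int(rng.integers(0, max(2, n // 3))) for v in nodes}
    return nodes, edges, modules
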