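import itertools

import numpy as np
import pandas as pd
import pytest

from cgenet.expression import ExpressionTable, GroupKey
from cgenet.network import ThresholdedNetwork
from cgenet.registry import Region, RegionRegistry, default_region_registry

SALINE = GroupKey("cfos", "adult", "saline")


@pytest.fixture(scope="session")
def registry():
    return default_region_registry()


def small_registry(n: int = 4) -> RegionRegistry:
    """Tiny synthetic registry for unit fixtures (A, B, C, ...)."""
    names = [chr(ord("A") + i) for i in range(n)]
    return RegionRegistry(
        tuple(
            Region(id=nm, full_name=f"region {nm}", area_group="striatum",
                   layout_xy=(float(i), 0.0))
            for i, nm in enumerate(names)
        )
    )


def make_table(values: np.ndarray, registry: RegionRegistry,
               group: GroupKey = SALINE,
               subject_prefix: str = "s") -> ExpressionTable:
    """Subjects x regions array -> validated long table."""
    n, p = values.shape
    rows = []
    for s in range(n):
        for j, region in enumerate(registry.ids[:p]):
            rows.append(
                {
                    "subject_id": f"{subject_prefix}{s + 1:02d}",
                    "age": group.age,
                    "treatment": group.treatment,
                    "gene": group.gene,
                    "region": region,
                    "value": values[s, j],
                }
            )
    return ExpressionTable(pd.DataFrame(rows), registry)


def make_net(w: np.ndarray, names: list[str] | None = None,
             n: int = 7, alpha: float = 0.05) -> ThresholdedNetwork:
    """Wrap a symmetric weight matrix as a ThresholdedNetwork fixture."""
    k = w.shape[0]
    names = names or [f"r{i}" for i in range(k)]
    return ThresholdedNetwork(
        group=SALINE, regions=tuple(names),
        w=pd.DataFrame(np.asarray(w, dtype=float), index=names, columns=names),
        alpha=alpha, n=n,
    )


def clique_union(sizes: list[int]) -> np.ndarray:
    """Disjoint union of unit-weight cliques, block by block."""
    total = sum(sizes)
    w = np.zeros((total, total))
    start = 0
    for size in sizes:
        for i, j in itertools.combinations(range(start, start + size), 2):
            w[i, j] = w[j, i] = 1.0
        start += size
    return w


@pytest.fixture(scope="session")
def two_triangles():
    return make_net(clique_union([3, 3]), list("abcdef"))
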