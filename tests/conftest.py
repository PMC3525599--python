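import pytest

from qclique import Graph, QuasiCliqueSpec


@pytest.fixture
def triangle() -> Graph:
    return Graph(["a", "b", "c"], [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def five_cycle() -> Graph:
    return Graph(list("abcde"), [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0)])


@pytest.fixture
def k4_minus_edge() -> Graph:
    return Graph(list("wxyz"), [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)])


def complete_graph(n: int) -> Graph:
    labels = [f"u{i}" for i in range(n)]
    return Graph(labels, [(i, j) for i in range(n) for j in range(i + 1, n)])


@pytest.fixture
def spec85() -> QuasiCliqueSpec:
    return QuasiCliqueSpec(gamma="0.85")
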