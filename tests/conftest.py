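import numpy as np
import pytest

from tcstat import make_phantom_topology, make_ribbon_phantom


@pytest.fixture(scope="session")
def phantom():
    return make_ribbon_phantom(seed=0)


@pytest.fixture(scope="session")
def phantom_topology(phantom):
    return make_phantom_topology(phantom)


def bfs_components(n_nodes, edges, subset):
    """Independent BFS oracle: connected components of ``subset`` using
    only edges with both endpoints in ``subset``.  Returns a list of
    sorted node lists."""
    subset = set(int(i) for i in subset)
    adj = {i: [] for i in subset}
    for i, j in edges:
        if i in subset and j in subset:
            adj[i].append(j)
            adj[j].append(i)
    seen = set()
    comps = []
    for start in sorted(subset):
        if start in seen:
            continue
        queue = [start]
        seen.add(start)
        comp = []
        while queue:
            u = queue.pop()
            comp.append(u)
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    queue.append(v)
        comps.append(sorted(comp))
    return comps


@pytest.fixture(scope="session")
def bfs_oracle():
    return bfs_components
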