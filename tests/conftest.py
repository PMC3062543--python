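import random

import pytest

from cascade_ne import PathwayNetwork


def random_digraph(rng: random.Random, max_nodes: int = 8,
                   weights=(10.0, 200.0)) -> PathwayNetwork:
    """Random directed graph for oracle comparisons (no self-loops/dups)."""
    n = rng.randint(2, max_nodes)
    names = [f"n{i}" for i in range(n)]
    pairs = [(a, b) for a in names for b in names if a != b]
    density = rng.uniform(0.15, 0.6)
    k = max(1, round(density * len(pairs)))
    chosen = rng.sample(pairs, k)
    return PathwayNetwork(
        [(a, b, rng.choice(weights)) for a, b in chosen], extra_nodes=names
    )


def brute_force_distances(net: PathwayNetwork) -> dict[tuple[str, str], float]:
    """Exhaustive minimum over all simple directed paths (independent oracle).

    DFS from each source enumerating every simple path, recording the
    minimum total line value reaching each node.  Exponential, so only
    for small graphs.
    """
    adj: dict[str, list[tuple[str, float]]] = {v: [] for v in net.nodes}
    for rec in net.edges():
        adj[rec.source].append((rec.target, rec.line_value))
    best: dict[tuple[str, str], float] = {}

    def dfs(source: str, node: str, cost: float, visited: set[str]) -> None:
        for nxt, w in adj[node]:
            if nxt in visited:
                continue
            total = cost + w
            key = (source, nxt)
            if total < best.get(key, float("inf")):
                best[key] = total
            dfs(source, nxt, total, visited | {nxt})

    for source in net.nodes:
        dfs(source, source, 0.0, {source})
    return best


def brute_force_ne(net: PathwayNetwork) -> float:
    """NE from the exhaustive path enumeration oracle (ordered pairs)."""
    return sum(1.0 / d for d in brute_force_distances(net).values())


@pytest.fixture
def chain3() -> PathwayNetwork:
    """a -> b -> c with line values 10."""
    return PathwayNetwork([("a", "b", 10.0), ("b", "c", 10.0)])


@pytest.fixture
def chain4() -> PathwayNetwork:
    """a -> b -> c -> d with line values 10."""
    return PathwayNetwork(
        [("a", "b", 10.0), ("b", "c", 10.0), ("c", "d", 10.0)]
    )
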