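"""Synthetic cascades, docking-score tables and assay data.

These generators stand in for a real docking library and wet-lab assays
when exercising the pipeline: a random feed-forward cascade network, a
compound x target score table with a planted potency gradient, and assay
records whose activity tracks mean binding strength through a tunable
link.  At zero noise the planted compound order is exactly recoverable
end-to-end, which anchors the pipeline's correctness tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import DEFAULT_LINE_VALUE, PathwayNetwork
from .scores import DockingScoreTable
from .assay import AssayRecord

__all__ = ["SyntheticSpec", "generate_cascade", "generate_scores", "generate_assays"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic data set.

    ``potency_gradient`` lists per-compound mean binding energies in
    kcal/mol, most potent first; the default spans -12 (a strong
    nanomolar-range binder) to -6 (a weak but genuine binder), a range
    over which every compound stays above the line-value floor so the
    planted order is strictly recoverable at zero noise.
    ``edge_density`` is the fraction of forward (acyclic) node pairs that
    carry an arrow.
    """

    n_nodes: int = 41
    edge_density: float = 0.065
    n_compounds: int = 20
    n_targets: int = 14
    potency_gradient: tuple[float, ...] | None = None
    noise_sd: float = 0.0
    seed: int = 0
    allow_feedback: bool = False

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if not 0 < self.edge_density <= 1:
            raise ValueError("edge_density must be in (0, 1]")
        if self.n_targets > self.n_nodes:
            raise ValueError("n_targets cannot exceed n_nodes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.potency_gradient is not None and (
            len(self.potency_gradient) != self.n_compounds
        ):
            raise ValueError("potency_gradient length must equal n_compounds")

    def gradient(self) -> np.ndarray:
        if self.potency_gradient is not None:
            return np.asarray(self.potency_gradient, dtype=float)
        return np.linspace(-12.0, -6.0, self.n_compounds)


def _node_name(i: int) -> str:
    return f"enzyme_{i:02d}"


def generate_cascade(spec: SyntheticSpec) -> PathwayNetwork:
    """Random weakly connected feed-forward cascade, all line values 10.

    Nodes are laid out in topological order; each non-root node receives
    an arrow from an earlier node (guaranteeing weak connectivity), and
    further forward arrows are added to reach the requested density.
    With ``allow_feedback`` a small number of back arrows emulate the
    amplification loops of real cascades.  Deterministic in the seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    edges: set[tuple[int, int]] = set()
    for j in range(1, n):
        i = int(rng.integers(0, j))
        edges.add((i, j))
    n_forward = n * (n - 1) // 2
    target_edges = max(n - 1, round(spec.edge_density * n_forward))
    candidates = [
        (i, j) for i in range(n) for j in range(i + 1, n) if (i, j) not in edges
    ]
    extra = min(target_edges - len(edges), len(candidates))
    if extra > 0:
        for k in rng.choice(len(candidates), size=extra, replace=False):
            edges.add(candidates[int(k)])
    if spec.allow_feedback:
        # close actual forward paths so the loops are real amplification
        # cycles, preferring long-range feedback
        reach: dict[int, set[int]] = {i: set() for i in range(n)}
        for i, j in sorted(edges, reverse=True):
            reach[i] |= {j} | reach[j]
        back = [(j, i) for i in range(n) for j in reach[i]]
        n_back = min(max(1, len(edges) // 10), len(back))
        if n_back:
            for k in rng.choice(len(back), size=n_back, replace=False):
                edges.add(back[int(k)])
    return PathwayNetwork(
        (_node_name(i), _node_name(j), DEFAULT_LINE_VALUE)
        for i, j in sorted(edges)
    )


def generate_scores(
    spec: SyntheticSpec, net: PathwayNetwork
) -> DockingScoreTable:
    """Score table with a planted potency gradient across all targets.

    Targets are the ``n_targets`` highest-out-degree nodes (every scored
    target can actually perturb the network).  Compound k's energy
    against each target is ``gradient[k] + Normal(0, noise_sd)``,
    clamped nonpositive.  At ``noise_sd = 0`` the NE-decrease ranking
    equals the planted order.
    """
    rng = np.random.default_rng(spec.seed + 1)
    by_out_degree = sorted(
        net.nodes, key=lambda v: (-net.graph.out_degree(v), v)
    )
    targets = by_out_degree[: spec.n_targets]
    gradient = spec.gradient()
    rows = []
    for k in range(spec.n_compounds):
        for t in targets:
            be = gradient[k] + rng.normal(0.0, spec.noise_sd) if spec.noise_sd else gradient[k]
            rows.append((f"compound_{k:03d}", t, min(be, 0.0), "other"))
    frame = pd.DataFrame(
        rows, columns=["compound", "target", "binding_energy", "stage"]
    )
    return DockingScoreTable.from_frame(frame)


def generate_assays(
    table: DockingScoreTable,
    link_strength: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[AssayRecord]:
    """Assay records whose activity tracks mean binding strength.

    Each compound's activity sum is ``link_strength * mean |BE|`` across
    its scored targets plus Gaussian noise (truncated at 0), split into
    three nonnegative component ratios by random proportions.  With
    ``link_strength = 0`` activities are pure noise, giving the null
    model for correlation tests.
    """
    if link_strength < 0:
        raise ValueError("link_strength must be >= 0")
    rng = np.random.default_rng(seed)
    mean_abs = table.frame.groupby("compound")["binding_energy"].apply(
        lambda s: float(s.abs().mean())
    )
    records = []
    for compound in sorted(mean_abs.index):
        total = link_strength * mean_abs[compound]
        if noise_sd:
            total += float(rng.normal(0.0, noise_sd))
        total = max(total, 0.0)
        w = rng.dirichlet(np.ones(3))
        records.append(
            AssayRecord(
                compound,
                float(total * w[0]),
                float(total * w[1]),
                float(total * w[2]),
            )
        )
    return records
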