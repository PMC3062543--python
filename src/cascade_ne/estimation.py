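"""Compound ranking by network-efficiency decrease.

For each compound the cascade network is reweighted from its docking
scores (see :mod:`cascade_ne.scores`), NE is recomputed, and compounds
are ranked by the decrease relative to the intact network — the larger
the decrease, the more strongly the compound is predicted to shut the
cascade down.  A two-stage hierarchical screen ranks with a fast scoring
stage first and re-ranks the surviving top fraction with a slower, more
accurate stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .efficiency import network_efficiency
from .network import PathwayNetwork
from .scores import (
    DockingScoreTable,
    ReferenceEnergy,
    TransformConfig,
    reference_energies,
    reweight_for_compound,
)

__all__ = [
    "CompoundEstimate",
    "ScreenReport",
    "DrugTargetNetwork",
    "estimate_compounds",
    "hierarchical_screen",
    "drug_target_network",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CompoundEstimate:
    """Per-compound outcome of the NE-decrease calculation."""

    compound: str
    ne_after: float
    ne_decrease: float
    rank: int


@dataclass(frozen=True)
class ScreenReport:
    """Both stages of a hierarchical screen."""

    stage1: list[CompoundEstimate]
    survivors: list[str]
    stage2: list[CompoundEstimate]
    keep_fraction: float


@dataclass(frozen=True)
class DrugTargetNetwork:
    """Bipartite compound-target graph of strong predicted interactions."""

    graph: nx.Graph
    threshold: float
    compounds: frozenset[str] = field(default_factory=frozenset)
    targets: frozenset[str] = field(default_factory=frozenset)

    def degree(self, compound: str) -> int:
        if compound not in self.compounds:
            raise KeyError(f"unknown compound {compound!r}")
        return self.graph.degree(("compound", compound))

    def edges(self) -> list[tuple[str, str]]:
        return sorted(
            (u[1], v[1]) if u[0] == "compound" else (v[1], u[1])
            for u, v in self.graph.edges()
        )


def estimates_to_frame(estimates: list[CompoundEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "compound": [e.compound for e in estimates],
            "ne_after": [e.ne_after for e in estimates],
            "ne_decrease": [e.ne_decrease for e in estimates],
            "rank": [e.rank for e in estimates],
        }
    )


def estimate_compounds(
    net: PathwayNetwork,
    table: DockingScoreTable,
    compounds: list[str] | None = None,
    refs: ReferenceEnergy | None = None,
    config: TransformConfig = TransformConfig(),
    pair_mode: str = "ordered",
) -> list[CompoundEstimate]:
    """Reweight, recompute NE and rank each compound by NE decrease.

    Reference energies default to the per-target minima within ``table``;
    pass ``refs`` to pin them externally (e.g. when comparing tables).
    Returns estimates sorted by decreasing ``ne_decrease``, ties broken
    by compound id; ``rank`` starts at 1.
    """
    baseline = network_efficiency(net, pair_mode=pair_mode).ne
    if refs is None:
        refs = reference_energies(table)
    if compounds is None:
        compounds = table.compounds
    rows: list[tuple[str, float]] = []
    for compound in compounds:
        sub = table.for_compound(compound)
        in_network = [t for t in sub["target"] if t in net and t not in refs.degenerate]
        if not in_network:
            logger.warning(
                "compound %s has no scored target in the network; decrease 0",
                compound,
            )
            rows.append((str(compound), baseline))
            continue
        reweighted = reweight_for_compound(net, table, refs, compound, config)
        rows.append(
            (str(compound), network_efficiency(reweighted, pair_mode=pair_mode).ne)
        )
    rows.sort(key=lambda r: (-(baseline - r[1]), r[0]))
    return [
        CompoundEstimate(c, ne_after, baseline - ne_after, i + 1)
        for i, (c, ne_after) in enumerate(rows)
    ]


def hierarchical_screen(
    net: PathwayNetwork,
    stage1: DockingScoreTable,
    stage2: DockingScoreTable,
    keep_fraction: float = 0.10,
    config: TransformConfig = TransformConfig(),
) -> ScreenReport:
    """Two-stage screen: rank by stage-1 scores, re-rank the top fraction.

    ``ceil(keep_fraction * n)`` compounds survive stage 1 (at least one).
    Reference energies are recomputed per stage, since each scoring
    program has its own energy scale.  Survivors missing from the
    stage-2 table raise an error naming them.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    first = estimate_compounds(net, stage1, config=config)
    n_keep = math.ceil(keep_fraction * len(first))
    survivors = [e.compound for e in first[:n_keep]]
    missing = set(survivors) - set(stage2.compounds)
    if missing:
        raise KeyError(
            f"stage-2 table missing surviving compound(s): {sorted(missing)}"
        )
    second = estimate_compounds(net, stage2.subset(survivors))
    return ScreenReport(first, survivors, second, keep_fraction)


def drug_target_network(
    table: DockingScoreTable, threshold: float
) -> DrugTargetNetwork:
    """Bipartite graph linking compounds to strongly bound targets.

    An edge is drawn for every (compound, target) whose binding-energy
    magnitude is at least ``threshold`` (kcal/mol).  There is no default
    threshold: strength is a modelling choice the caller must make.
    """
    if not threshold > 0:
        raise ValueError(f"threshold must be a positive magnitude, got {threshold}")
    g = nx.Graph()
    compounds = frozenset(table.compounds)
    targets = frozenset(table.targets)
    for c in compounds:
        g.add_node(("compound", c), kind="compound")
    for t in targets:
        g.add_node(("target", t), kind="target")
    strong = table.frame[table.frame["binding_energy"].abs() >= threshold]
    for row in strong.itertuples():
        g.add_edge(("compound", row.compound), ("target", row.target))
    return DrugTargetNetwork(g, threshold, compounds, targets)
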