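"""Directed weighted pathway networks.

A pathway network is a directed graph whose nodes are the enzymes,
zymogens and complexes of a biochemical cascade and whose arrows point
from an activator (or precursor) to the species whose formation it
enhances.  Every arrow carries a positive *line value* — the length of
that edge for shortest-path purposes.  In an unperturbed network every
line value is :data:`DEFAULT_LINE_VALUE`.

The packaged clotting-cascade network (41 nodes, 53 arrows, covering the
extrinsic, intrinsic and common pathways plus the major physiological
inhibitors) is returned by :func:`clotting_cascade_fixture`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

__all__ = [
    "DEFAULT_LINE_VALUE",
    "EdgeRecord",
    "PathwayNetwork",
    "NetworkParseError",
    "normalize_node_id",
    "read_network",
    "write_network",
    "clotting_cascade_fixture",
]

DEFAULT_LINE_VALUE = 10.0

_FORMATS = ("edgelist", "sif", "graphml")
_SUFFIX_FORMAT = {
    ".tsv": "edgelist",
    ".txt": "edgelist",
    ".edgelist": "edgelist",
    ".sif": "sif",
    ".graphml": "graphml",
    ".xml": "graphml",
}


class NetworkParseError(ValueError):
    """Raised when a network file cannot be parsed or fails validation."""


def normalize_node_id(name: str) -> str:
    """Normalize a node identifier: lowercase, whitespace to underscores.

    Colons are preserved so complexes such as ``factor_viiia:factor_ixa``
    keep a stable, recognisable name.
    """
    norm = re.sub(r"\s+", "_", str(name).strip()).lower()
    if not norm:
        raise ValueError("empty node identifier")
    return norm


@dataclass(frozen=True)
class EdgeRecord:
    """A single directed arrow with its line value."""

    source: str
    target: str
    line_value: float = DEFAULT_LINE_VALUE

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError(f"self-loop on node {self.source!r}")
        if not self.line_value > 0:
            raise ValueError(
                f"line value must be positive, got {self.line_value!r} "
                f"on edge {self.source!r} -> {self.target!r}"
            )


class PathwayNetwork:
    """A validated directed pathway graph with positive edge line values.

    Parameters
    ----------
    edges
        Iterable of ``(source, target)`` or ``(source, target, line_value)``
        tuples, or :class:`EdgeRecord` instances.  Node names are
        normalized via :func:`normalize_node_id`.
    extra_nodes
        Node identifiers to include even if they touch no edge.

    Invariants enforced on construction: no self-loops, no duplicate
    directed edges, every line value strictly positive.
    """

    def __init__(
        self,
        edges: Iterable[EdgeRecord | tuple] = (),
        extra_nodes: Iterable[str] = (),
    ) -> None:
        g = nx.DiGraph()
        for name in extra_nodes:
            g.add_node(normalize_node_id(name))
        for item in edges:
            rec = self._coerce(item)
            if g.has_edge(rec.source, rec.target):
                raise ValueError(
                    f"duplicate directed edge {rec.source!r} -> {rec.target!r}"
                )
            g.add_edge(rec.source, rec.target, line_value=rec.line_value)
        self._graph = g

    @staticmethod
    def _coerce(item: EdgeRecord | tuple) -> EdgeRecord:
        if isinstance(item, EdgeRecord):
            return EdgeRecord(
                normalize_node_id(item.source),
                normalize_node_id(item.target),
                float(item.line_value),
            )
        if len(item) == 2:
            src, dst = item
            lv = DEFAULT_LINE_VALUE
        else:
            src, dst, lv = item
        return EdgeRecord(normalize_node_id(src), normalize_node_id(dst), float(lv))

    # -- container protocol -------------------------------------------------

    @property
    def graph(self) -> nx.DiGraph:
        """The underlying :class:`networkx.DiGraph` (treat as read-only)."""
        return self._graph

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def edges(self) -> Iterator[EdgeRecord]:
        for u, v, data in self._graph.edges(data=True):
            yield EdgeRecord(u, v, data["line_value"])

    def __contains__(self, node: str) -> bool:
        return normalize_node_id(node) in self._graph

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayNetwork):
            return NotImplemented
        return self.nodes == other.nodes and set(self.edges()) == set(other.edges())

    def __repr__(self) -> str:
        return f"PathwayNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"

    # -- derived views ------------------------------------------------------

    def copy(self) -> "PathwayNetwork":
        new = PathwayNetwork()
        new._graph = self._graph.copy()
        return new

    def line_value(self, source: str, target: str) -> float:
        return self._graph.edges[
            normalize_node_id(source), normalize_node_id(target)
        ]["line_value"]

    def out_edges(self, node: str) -> list[tuple[str, str]]:
        """Directed out-edges of ``node`` as (source, target) pairs."""
        node = normalize_node_id(node)
        if node not in self._graph:
            raise KeyError(f"unknown node {node!r}")
        return list(self._graph.out_edges(node))

    def with_line_values(
        self, new_values: dict[tuple[str, str], float]
    ) -> "PathwayNetwork":
        """Return a copy with the given edges re-assigned to new line values."""
        new = self.copy()
        for (u, v), lv in new_values.items():
            u, v = normalize_node_id(u), normalize_node_id(v)
            if not new._graph.has_edge(u, v):
                raise KeyError(f"no edge {u!r} -> {v!r}")
            if not lv > 0:
                raise ValueError(f"line value must be positive, got {lv!r}")
            new._graph.edges[u, v]["line_value"] = float(lv)
        return new

    def without_node(self, node: str) -> "PathwayNetwork":
        """Return a copy with ``node`` and all incident edges deleted."""
        node = normalize_node_id(node)
        if node not in self._graph:
            raise KeyError(f"unknown node {node!r}")
        new = self.copy()
        new._graph.remove_node(node)
        return new

    def without_edge(self, source: str, target: str) -> "PathwayNetwork":
        """Return a copy with the single directed edge deleted."""
        u, v = normalize_node_id(source), normalize_node_id(target)
        if not self._graph.has_edge(u, v):
            raise KeyError(f"no edge {u!r} -> {v!r}")
        new = self.copy()
        new._graph.remove_edge(u, v)
        return new


# -- I/O --------------------------------------------------------------------


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in _FORMATS:
            raise ValueError(
                f"unknown format {format!r}; expected one of {_FORMATS}"
            )
        return format
    fmt = _SUFFIX_FORMAT.get(path.suffix.lower())
    if fmt is None:
        raise ValueError(
            f"cannot infer format from suffix {path.suffix!r}; pass format="
        )
    return fmt


def _split_fields(line: str) -> list[str]:
    return line.split("\t") if "\t" in line else line.split()

def _parse_edgelist(path: Path) -> list[tuple]:
    edges = []
    first_data_line = True
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split_fields(line)
            is_header = first_data_line and (
                [f.lower() for f in fields[:2]] == ["source", "target"]
            )
            first_data_line = False
            if is_header:
                continue
            if len(fields) < 2 or len(fields) > 3:
                raise NetworkParseError(
                    f"{path}:{lineno}: expected 2 or 3 fields, got {len(fields)}"
                )
            if len(fields) == 3:
                try:
                    lv = float(fields[2])
                except ValueError:
                    raise NetworkParseError(
                        f"{path}:{lineno}: non-numeric line value {fields[2]!r}"
                    ) from None
                edges.append((fields[0], fields[1], lv))
            else:
                edges.append((fields[0], fields[1]))
    return edges


def _parse_sif(path: Path) -> list[tuple]:
    edges = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = _split_fields(line)
            if len(fields) < 3:
                raise NetworkParseError(
                    f"{path}:{lineno}: SIF needs source, relation and >=1 target"
                )
            src, _relation, *targets = fields
            for dst in targets:
                edges.append((src, dst))
    return edges


def read_network(path: str | Path, format: str | None = None) -> PathwayNetwork:
    """Read a pathway network from an edge-list TSV, SIF or GraphML file.

    Edges without an explicit weight get line value 10.  Validation errors
    (self-loops, nonpositive weights, duplicate edges) raise
    :class:`NetworkParseError` / :class:`ValueError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    try:
        if fmt == "edgelist":
            return PathwayNetwork(_parse_edgelist(path))
        if fmt == "sif":
            return PathwayNetwork(_parse_sif(path))
        g = nx.read_graphml(path)
        net = PathwayNetwork()
        isolated = [n for n in g.nodes if g.degree(n) == 0]
        edges = [
            (u, v, float(data.get("line_value", DEFAULT_LINE_VALUE)))
            for u, v, data in g.edges(data=True)
        ]
        return PathwayNetwork(edges, extra_nodes=isolated)
    except ValueError as exc:
        if isinstance(exc, NetworkParseError):
            raise
        raise NetworkParseError(f"{path}: {exc}") from exc


def write_network(
    net: PathwayNetwork, path: str | Path, format: str | None = None
) -> Path:
    """Write a network; ``read_network(write_network(net))`` round-trips."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "edgelist":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tline_value\n")
            for rec in sorted(net.edges(), key=lambda e: (e.source, e.target)):
                fh.write(f"{rec.source}\t{rec.target}\t{rec.line_value:g}\n")
    elif fmt == "sif":
        with open(path, "w") as fh:
            for rec in sorted(net.edges(), key=lambda e: (e.source, e.target)):
                fh.write(f"{rec.source}\tactivates\t{rec.target}\n")
    else:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(net.nodes))
        for rec in net.edges():
            g.add_edge(rec.source, rec.target, line_value=float(rec.line_value))
        nx.write_graphml(g, path)
    return path


def clotting_cascade_fixture() -> PathwayNetwork:
    """The packaged human clotting-cascade network.

    41 nodes and 53 directed edges covering the extrinsic (tissue factor /
    factor VIIa), intrinsic (contact activation through the factor
    VIIIa:IXa tenase complex) and common (prothrombinase, thrombin,
    fibrin) pathways together with the physiological inhibitors (TFPI,
    antithrombin III, the protein C system).  Every line value is 10.

    The edge list is a curated transcription of the Reactome
    clotting-cascade pathway, calibrated so that the network-efficiency
    statistics of the intact and knocked-out networks reproduce the
    published reference values (see the fixture data file's header and
    ``docs/methods.md``).
    """
    data = resources.files("cascade_ne").joinpath("data/clotting_cascade.tsv")
    with resources.as_file(data) as path:
        return read_network(path, format="edgelist")
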