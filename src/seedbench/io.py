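"""Graph and results I/O plus closed-form test fixtures.

Readers accept whitespace- or comma-delimited edge lists (``#`` comments,
integer or string labels), GraphML and GML.  Whatever the source, the result
is a simple undirected graph with 0-based consecutive integer ids: directed
edges are symmetrized, self-loops dropped (count logged), and the original
labels kept under the ``"label"`` node attribute with the full id → label map
in ``g.graph["node_labels"]``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import ParameterError

__all__ = [
    "read_graph",
    "write_graph",
    "write_partition",
    "write_results",
    "FixtureSpec",
    "build_fixture",
]

log = logging.getLogger("seedbench")

_FORMATS = ("edgelist", "graphml", "gml")


@dataclass(frozen=True)
class FixtureSpec:
    """A named deterministic graph whose edge set has a closed form."""

    name: str
    params: tuple = field(default=())


_HEADER_TOKENS = {"source", "target", "from", "to", "node1", "node2", "u", "v"}


def _parse_edgelist(path: Path) -> nx.Graph:
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = [p.strip() for p in (line.split(",") if "," in line else line.split()) if p.strip()]
            if len(parts) < 2:
                raise ParameterError(f"{path}:{lineno}: expected two columns, got {raw!r}")
            rows.append((parts[0], parts[1]))
    if rows and {rows[0][0].lower(), rows[0][1].lower()} <= _HEADER_TOKENS:
        rows = rows[1:]  # optional header row
    g = nx.Graph()
    g.add_edges_from(rows)
    return g


def _normalise(g: nx.Graph, name: str) -> nx.Graph:
    if g.is_directed():
        g = g.to_undirected()
    loops = list(nx.selfloop_edges(g))
    if loops:
        log.info("dropping %d self-loop(s) from %s", len(loops), name)
        g.remove_edges_from(loops)
    labels = sorted(g.nodes(), key=lambda x: (0, int(x)) if str(x).lstrip("-").isdigit() else (1, str(x)))
    mapping = {lab: i for i, lab in enumerate(labels)}
    h = nx.Graph(name=name)
    h.add_nodes_from(range(len(labels)))
    h.add_edges_from((mapping[u], mapping[v]) for u, v in g.edges())
    nx.set_node_attributes(h, {i: str(lab) for lab, i in mapping.items()}, "label")
    h.graph["node_labels"] = {i: str(lab) for lab, i in mapping.items()}
    return h


def read_graph(path, format: str | None = None) -> nx.Graph:
    """Read a graph file into a simple undirected 0-indexed network."""
    path = Path(path)
    if format is None:
        format = {".graphml": "graphml", ".gml": "gml"}.get(path.suffix.lower(), "edgelist")
    if format not in _FORMATS:
        raise ParameterError(f"unknown format {format!r}; valid: {_FORMATS}")
    if format == "graphml":
        g = nx.read_graphml(path)
    elif format == "gml":
        g = nx.read_gml(path, label="id")
    else:
        g = _parse_edgelist(path)
    return _normalise(g, name=path.stem)


def write_graph(g: nx.Graph, path) -> None:
    """Write a whitespace-delimited integer edge list (sorted, reproducible)."""
    path = Path(path)
    with open(path, "w") as fh:
        for u, v in sorted((min(e), max(e)) for e in g.edges()):
            fh.write(f"{u} {v}\n")


def write_partition(partition, path) -> None:
    """Write a community partition as CSV with columns node,community."""
    rows = sorted(partition.assignment.items())
    pd.DataFrame(rows, columns=["node", "community"]).to_csv(path, index=False)


def write_results(tables: dict, out_dir, manifest: dict | None = None) -> list[Path]:
    """Write named DataFrames as CSVs plus a manifest.json; returns paths.

    Column order is preserved and rows are written as-is, so identical inputs
    produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        dest = out_dir / f"{name}.csv"
        index = name == "degeneracy"  # square matrix keeps its strategy index
        table.to_csv(dest, index=index)
        written.append(dest)
    if manifest is not None:
        from . import __version__

        dest = out_dir / "manifest.json"
        payload = {"package": "seedbench", "version": __version__, **manifest}
        dest.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
        written.append(dest)
    return written


def build_fixture(spec: FixtureSpec | str, *params: int) -> nx.Graph:
    """Build a deterministic fixture graph with a closed-form edge set.

    Builders: star(k leaves), path(n nodes), cycle(n), two_cliques_bridge(k),
    dyad(), grid(rows, cols).
    """
    if isinstance(spec, str):
        spec = FixtureSpec(spec, tuple(params))
    name, args = spec.name, spec.params
    if name == "star":
        (k,) = args
        if k < 1:
            raise ParameterError("star needs at least one leaf")
        g = nx.star_graph(k)
    elif name == "path":
        (n,) = args
        if n < 2:
            raise ParameterError("path needs at least two nodes")
        g = nx.path_graph(n)
    elif name == "cycle":
        (n,) = args
        if n < 3:
            raise ParameterError("cycle needs at least three nodes")
        g = nx.cycle_graph(n)
    elif name == "two_cliques_bridge":
        (k,) = args
        if k < 2:
            raise ParameterError("cliques need at least two nodes")
        g = nx.disjoint_union(nx.complete_graph(k), nx.complete_graph(k))
        g.add_edge(0, k)
    elif name == "dyad":
        g = nx.path_graph(2)
    elif name == "grid":
        rows, cols = args
        if rows < 1 or cols < 1:
            raise ParameterError("grid needs positive dimensions")
        g = nx.convert_node_labels_to_integers(nx.grid_2d_graph(rows, cols))
    else:
        raise ParameterError(f"unknown fixture {name!r}")
    g.graph["name"] = f"{name}{args}"
    return g
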