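"""Reticular-network container and serialization.

The follicular stromal network is represented as an undirected spatial graph:
nodes are CXCL13-expressing stromal cells (FDCs or CD21-negative reticular
cells) with 3D positions in micrometres, edges are physical connections
between neighbouring cells.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

FDC = "FDC"
CD21NEG_RC = "CD21neg_RC"
SUBTYPES = (FDC, CD21NEG_RC)


@dataclass
class StromalNode:
    """A single stromal cell: position (µm), subtype and CXCL13 secretion rate."""

    id: int
    position: np.ndarray  # shape (3,), µm
    subtype: str = FDC
    secretion_rate: float = 1.0  # concentration · s⁻¹

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("position must be finite")
        if self.subtype not in SUBTYPES:
            raise ValueError(f"subtype must be one of {SUBTYPES}, got {self.subtype!r}")
        if self.secretion_rate < 0:
            raise ValueError("secretion_rate must be >= 0")


@dataclass
class ReticularNetwork:
    """Spatial undirected graph of stromal cells.

    ``bounds`` is an axis-aligned box ``((xlo, ylo, zlo), (xhi, yhi, zhi))``
    in µm enclosing every node position.
    """

    nodes: list[StromalNode]
    edges: set[tuple[int, int]] = field(default_factory=set)
    bounds: tuple[tuple[float, float, float], tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        ids = {n.id for n in self.nodes}
        if len(ids) != len(self.nodes):
            raise ValueError("duplicate node ids")
        canon = set()
        for e in self.edges:
            i, j = e
            if i == j:
                raise ValueError(f"self-loop at node {i}")
            if i not in ids or j not in ids:
                raise ValueError(f"edge {e} references missing node")
            canon.add((min(i, j), max(i, j)))  # canonical order dedupes
        self.edges = canon
        if self.bounds is None and self.nodes:
            pos = self.positions()
            lo = pos.min(axis=0)
            hi = pos.max(axis=0)
            self.bounds = (tuple(lo), tuple(hi))
        elif self.bounds is not None and self.nodes:
            lo, hi = np.asarray(self.bounds[0]), np.asarray(self.bounds[1])
            pos = self.positions()
            if (pos < lo - 1e-9).any() or (pos > hi + 1e-9).any():
                raise ValueError("node positions outside bounds")

    # -- container protocol -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def positions(self) -> np.ndarray:
        return np.array([n.position for n in self.nodes], dtype=float).reshape(-1, 3)

    def subtypes(self) -> np.ndarray:
        return np.array([n.subtype for n in self.nodes])

    def secretion_rates(self) -> np.ndarray:
        return np.array([n.secretion_rate for n in self.nodes], dtype=float)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(
                n.id,
                x=float(n.position[0]),
                y=float(n.position[1]),
                z=float(n.position[2]),
                subtype=n.subtype,
                secretion_rate=float(n.secretion_rate),
            )
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, bounds=None) -> "ReticularNetwork":
        nodes = []
        for i, data in g.nodes(data=True):
            pos = np.array(
                [data.get("x", 0.0), data.get("y", 0.0), data.get("z", 0.0)], float
            )
            nodes.append(
                StromalNode(
                    id=int(i),
                    position=pos,
                    subtype=data.get("subtype", FDC),
                    secretion_rate=float(data.get("secretion_rate", 1.0)),
                )
            )
        edges = {(int(u), int(v)) for u, v in g.edges()}
        return cls(nodes=nodes, edges=edges, bounds=bounds)

    @classmethod
    def from_arrays(
        cls,
        positions: np.ndarray,
        edges: Iterable[Sequence[int]],
        subtypes: Sequence[str] | None = None,
        secretion_rates: Sequence[float] | None = None,
        bounds=None,
    ) -> "ReticularNetwork":
        positions = np.asarray(positions, float).reshape(-1, 3)
        n = len(positions)
        subtypes = list(subtypes) if subtypes is not None else [FDC] * n
        rates = (
            list(secretion_rates) if secretion_rates is not None else [1.0] * n
        )
        nodes = [
            StromalNode(id=i, position=positions[i], subtype=subtypes[i],
                        secretion_rate=rates[i])
            for i in range(n)
        ]
        return cls(nodes=nodes, edges={(int(i), int(j)) for i, j in edges},
                   bounds=bounds)

    # -- serialization -------------------------------------------------------
    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))

    @classmethod
    def read_graphml(cls, path: str | Path) -> "ReticularNetwork":
        return cls.from_networkx(nx.read_graphml(str(path), node_type=int))

    def to_json_dict(self) -> dict:
        return {
            "nodes": [
                {
                    "id": n.id,
                    "position": [float(v) for v in n.position],
                    "subtype": n.subtype,
                    "secretion_rate": float(n.secretion_rate),
                }
                for n in self.nodes
            ],
            "edges": sorted([list(e) for e in self.edges]),
            "bounds": [list(b) for b in self.bounds] if self.bounds else None,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict()))

    @classmethod
    def read_json(cls, path: str | Path) -> "ReticularNetwork":
        d = json.loads(Path(path).read_text())
        nodes = [
            StromalNode(
                id=int(n["id"]),
                position=np.asarray(n["position"], float),
                subtype=n.get("subtype", FDC),
                secretion_rate=float(n.get("secretion_rate", 1.0)),
            )
            for n in d["nodes"]
        ]
        edges = {(int(i), int(j)) for i, j in d["edges"]}
        bounds = tuple(tuple(b) for b in d["bounds"]) if d.get("bounds") else None
        return cls(nodes=nodes, edges=edges, bounds=bounds)
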