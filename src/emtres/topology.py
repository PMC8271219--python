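"""Signed directed regulatory-network topologies and the plain-text "topo" format.

A topology is an ordered set of named nodes plus signed directed edges
(activation or inhibition). The on-disk dialect is the conventional
whitespace-separated edge list used by circuit-perturbation tools::

    Source  Target  Type
    ZEB1    miR200  2

with ``Type`` 1 = activation, 2 = inhibition; the header line is optional.
Node order is the order of first appearance in the file, which fixes the
state-vector layout everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

ACTIVATION = "activation"
INHIBITION = "inhibition"

_SIGN_CODE = {ACTIVATION: 1, INHIBITION: 2}
_CODE_SIGN = {"1": ACTIVATION, "2": INHIBITION}


class TopologyError(ValueError):
    """Malformed topology file or invariant violation."""


@dataclass(frozen=True)
class RegulatoryEdge:
    """One signed regulatory interaction ``source -> target``."""

    source: str
    target: str
    sign: Literal["activation", "inhibition"]

    def __post_init__(self) -> None:
        if self.sign not in (ACTIVATION, INHIBITION):
            raise TopologyError(
                f"edge {self.source}->{self.target}: sign must be "
                f"'{ACTIVATION}' or '{INHIBITION}', got {self.sign!r}"
            )


@dataclass(frozen=True)
class NetworkTopology:
    """Validated signed directed network.

    Invariants: node names unique; every edge endpoint is a declared node;
    self-loops are allowed; parallel edges of the same (source, target) pair
    are not.
    """

    nodes: tuple[str, ...]
    edges: tuple[RegulatoryEdge, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise TopologyError("duplicate node names")
        declared = set(self.nodes)
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            if e.source not in declared or e.target not in declared:
                raise TopologyError(
                    f"edge {e.source}->{e.target} references an undeclared node"
                )
            key = (e.source, e.target)
            if key in seen:
                raise TopologyError(f"duplicate edge {e.source}->{e.target}")
            seen.add(key)

    # -- accessors -----------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_index(self, name: str) -> int:
        try:
            return self.nodes.index(name)
        except ValueError:
            raise KeyError(f"unknown node {name!r}; nodes are {self.nodes}") from None

    def incoming(self, node: str) -> tuple[RegulatoryEdge, ...]:
        return tuple(e for e in self.edges if e.target == node)

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(source index, target index, sign code) arrays, one entry per edge."""
        src = np.array([self.node_index(e.source) for e in self.edges], dtype=np.int64)
        tgt = np.array([self.node_index(e.target) for e in self.edges], dtype=np.int64)
        sign = np.array([_SIGN_CODE[e.sign] for e in self.edges], dtype=np.int64)
        return src, tgt, sign

    def degree_signature(self) -> tuple:
        """Per-node (in, out) degrees and global sign counts; the invariants
        preserved by topology randomization."""
        indeg = {n: 0 for n in self.nodes}
        outdeg = {n: 0 for n in self.nodes}
        n_act = n_inh = 0
        for e in self.edges:
            outdeg[e.source] += 1
            indeg[e.target] += 1
            if e.sign == ACTIVATION:
                n_act += 1
            else:
                n_inh += 1
        return (
            tuple(indeg[n] for n in self.nodes),
            tuple(outdeg[n] for n in self.nodes),
            n_act,
            n_inh,
        )


def _parse_lines(lines: Iterable[str], origin: str) -> NetworkTopology:
    nodes: list[str] = []
    edges: list[RegulatoryEdge] = []
    seen: set[tuple[str, str]] = set()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if lineno == 1 and [p.lower() for p in parts[:3]] == ["source", "target", "type"]:
            continue
        if len(parts) != 3:
            raise TopologyError(
                f"{origin}:{lineno}: expected 'SOURCE TARGET TYPE', got {line!r}"
            )
        src, tgt, code = parts
        if code not in _CODE_SIGN:
            raise TopologyError(
                f"{origin}:{lineno}: unknown sign code {code!r} (1=activation, 2=inhibition)"
            )
        if (src, tgt) in seen:
            raise TopologyError(f"{origin}:{lineno}: duplicate edge {src}->{tgt}")
        seen.add((src, tgt))
        for name in (src, tgt):
            if name not in nodes:
                nodes.append(name)
        edges.append(RegulatoryEdge(src, tgt, _CODE_SIGN[code]))
    return NetworkTopology(tuple(nodes), tuple(edges))


def read_topology(path: str | Path) -> NetworkTopology:
    """Parse a topo edge-list file into a validated :class:`NetworkTopology`."""
    path = Path(path)
    with path.open() as fh:
        return _parse_lines(fh, origin=str(path))


def write_topology(topology: NetworkTopology, path: str | Path) -> None:
    """Write a topology in the topo dialect (round-trips bit-exact)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("Source Target Type\n")
        for e in topology.edges:
            fh.write(f"{e.source} {e.target} {_SIGN_CODE[e.sign]}\n")


def load_default_topology() -> NetworkTopology:
    """The bundled 5-node EMT / estrogen-receptor crosstalk network.

    Nodes: ERa66 (full-length ER-alpha), ERa36 (truncated variant), SLUG,
    ZEB1 and miR200. Edges encode ERa66 self-activation and repression of
    ERa36 and SLUG, mutual ZEB1/miR200 inhibition with ZEB1 self-activation,
    SLUG and ZEB1 repression of ERa66, ERa36 activation of ZEB1, and SLUG
    repression of miR200.
    """
    ref = resources.files("emtres.data").joinpath("emt_er.topo")
    return _parse_lines(ref.read_text().splitlines(), origin="emt_er.topo")
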