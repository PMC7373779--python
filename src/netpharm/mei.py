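"""Biomarker-enzyme interaction network: construction and topology.

Degree centrality is the raw edge count of a node (the only topology
statistic used downstream); a degree-normalized variant is available behind
a flag but is never the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .model import Biomarker, BipartiteNetwork, Enzyme

__all__ = [
    "DegreeRow",
    "DegreeTable",
    "build_mei_network",
    "node_degrees",
    "select_hubs",
    "enzyme_function_tally",
]


@dataclass(frozen=True, slots=True)
class DegreeRow:
    node_id: str
    role: str
    degree: float


class DegreeTable:
    """Rows of (node, role, degree), ordered degree-descending then id-ascending."""

    def __init__(self, rows: Iterable[DegreeRow]) -> None:
        self.rows = sorted(rows, key=lambda r: (-r.degree, r.node_id))

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def degrees(self) -> dict[str, float]:
        return {r.node_id: r.degree for r in self.rows}

    @classmethod
    def from_degrees(cls, degrees: Mapping[str, float] | Sequence[tuple[str, float]],
                     role: str) -> "DegreeTable":
        items = degrees.items() if isinstance(degrees, Mapping) else degrees
        return cls(DegreeRow(str(n), role, d) for n, d in items)


def build_mei_network(
    relations: Iterable[tuple[str, str]],
    biomarkers: Mapping[str, Biomarker],
    enzymes: Mapping[str, Enzyme],
) -> BipartiteNetwork:
    """Build the biomarker-enzyme network from relation pairs.

    Duplicate relation rows collapse to one edge; endpoints must resolve in
    their catalogs.
    """
    edges: dict[tuple[str, str], None] = {}
    for b, e in relations:
        if b not in biomarkers or e not in enzymes:
            raise ValueError(f"relation ({b!r}, {e!r}) has an endpoint missing "
                             "from the biomarker/enzyme catalogs")
        edges[(b, e)] = None
    return BipartiteNetwork(edges, left_role="biomarker", right_role="enzyme")


def node_degrees(network: BipartiteNetwork, role: str,
                 *, normalized: bool = False) -> DegreeTable:
    """Degree-centrality table for one partition of the network.

    ``role`` is the partition's role label (e.g. 'biomarker', 'enzyme',
    'target'). With ``normalized`` the raw degree is divided by the size of
    the opposite partition.
    """
    if role == network.left_role:
        degs, other = network.degrees("left"), len(network.right_nodes)
    elif role == network.right_role:
        degs, other = network.degrees("right"), len(network.left_nodes)
    else:
        raise ValueError(
            f"unknown role {role!r}; this network has partitions "
            f"{network.left_role!r} and {network.right_role!r}")
    if normalized and other:
        return DegreeTable.from_degrees({n: d / other for n, d in degs.items()}, role)
    return DegreeTable.from_degrees(degs, role)


def select_hubs(table: DegreeTable, min_degree: float) -> list[str]:
    """Nodes with degree strictly greater than ``min_degree``, table order kept."""
    if min_degree < 0:
        raise ValueError("min_degree must be >= 0")
    return [r.node_id for r in table if r.degree > min_degree]


def enzyme_function_tally(network: BipartiteNetwork,
                          enzymes: Mapping[str, Enzyme]) -> list[tuple[str, int]]:
    """Count enzymes per function category among the network's enzyme nodes.

    An enzyme carrying k categories contributes one count to each of them.
    Ordered count-descending, category-name-ascending.
    """
    counts: dict[str, int] = {}
    for eid in network.right_nodes:
        for fun in enzymes[eid].functions:
            counts[fun] = counts.get(fun, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
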