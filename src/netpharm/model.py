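"""Domain types shared by every pipeline stage.

All binding affinities are carried in pKd units (``-log10`` of a molar
dissociation constant); raw Kd values must be converted at the boundary
with :func:`pkd_from_kd`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "SYSTEMS",
    "PLATFORMS",
    "TRENDS",
    "Biomarker",
    "Enzyme",
    "TargetProtein",
    "Pathway",
    "DockingScoreMatrix",
    "BipartiteNetwork",
    "NetworkSummary",
    "PathwayScore",
    "StudyConfig",
    "StudyBundle",
    "pkd_from_kd",
    "kd_from_pkd",
    "round_half_up",
]

#: The three physiological systems a target protein may belong to.
SYSTEMS: tuple[str, ...] = ("nervous", "immune", "endocrine")

#: Detection platforms admitted for a biomarker.
PLATFORMS: tuple[str, ...] = ("GC-MS", "LC-MS", "1H-NMR", "multiple")

#: Concentration trends admitted for a biomarker.
TRENDS: tuple[str, ...] = ("up", "down", "unknown")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round ``x`` half-up to ``ndigits`` decimals (0.005 -> 0.01).

    Python's builtin ``round`` is banker's rounding; reported network means
    use conventional half-up rounding instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pkd_from_kd(kd: float) -> float:
    """Convert a dissociation constant (mol/L) to the pKd scale.

    >>> round(pkd_from_kd(3e-6), 2)
    5.52
    """
    if not math.isfinite(kd) or kd <= 0:
        raise ValueError(f"Kd must be a positive finite molar value, got {kd!r}")
    return -math.log10(kd)


def kd_from_pkd(pkd: float) -> float:
    """Invert :func:`pkd_from_kd`: return the molar dissociation constant."""
    if not math.isfinite(pkd):
        raise ValueError(f"pKd must be finite, got {pkd!r}")
    return 10.0 ** (-pkd)


@dataclass(frozen=True, slots=True)
class Biomarker:
    """A plasma metabolite with accession, detection platform and trend."""

    id: str
    name: str = ""
    platform: str = "multiple"
    trend: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("biomarker id must be non-empty")
        if self.platform not in PLATFORMS:
            raise ValueError(
                f"biomarker {self.id}: platform {self.platform!r} not in {PLATFORMS}"
            )
        if self.trend not in TRENDS:
            raise ValueError(
                f"biomarker {self.id}: trend {self.trend!r} not in {TRENDS}"
            )


@dataclass(frozen=True, slots=True)
class Enzyme:
    """An enzyme with accession and a (possibly empty) set of function labels."""

    id: str
    name: str = ""
    functions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("enzyme id must be non-empty")
        object.__setattr__(self, "functions", frozenset(self.functions))


@dataclass(frozen=True, slots=True)
class TargetProtein:
    """A target protein with a non-empty subset of system memberships."""

    id: str
    name: str = ""
    systems: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("target id must be non-empty")
        systems = frozenset(self.systems)
        object.__setattr__(self, "systems", systems)
        unknown = systems - set(SYSTEMS)
        if unknown:
            raise ValueError(
                f"target {self.id}: unknown system label(s) {sorted(unknown)}; "
                f"allowed: {SYSTEMS}"
            )
        if not systems:
            raise ValueError(f"target {self.id}: systems set must be non-empty")


@dataclass(frozen=True, slots=True)
class Pathway:
    """A pathway (KEGG-style id) with a set of member target accessions."""

    id: str
    name: str = ""
    members: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("pathway id must be non-empty")
        object.__setattr__(self, "members", frozenset(self.members))


class DockingScoreMatrix:
    """Biomarker x target affinity grid in pKd units.

    Missing entries (NaN) mean "no measured interaction" and never pass any
    threshold; they are distinct from a legal score of zero.
    """

    __slots__ = ("biomarker_ids", "target_ids", "scores", "_brow", "_tcol")

    def __init__(
        self,
        biomarker_ids: Sequence[str],
        target_ids: Sequence[str],
        scores: np.ndarray,
    ) -> None:
        biomarker_ids = list(biomarker_ids)
        target_ids = list(target_ids)
        scores = np.asarray(scores, dtype=float)
        if len(biomarker_ids) < 1 or len(target_ids) < 1:
            raise ValueError("score matrix needs at least one biomarker and one target")
        if len(set(biomarker_ids)) != len(biomarker_ids):
            raise ValueError("duplicate biomarker ids in score matrix")
        if len(set(target_ids)) != len(target_ids):
            raise ValueError("duplicate target ids in score matrix")
        if scores.shape != (len(biomarker_ids), len(target_ids)):
            raise ValueError(
                f"scores shape {scores.shape} does not match "
                f"({len(biomarker_ids)}, {len(target_ids)})"
            )
        present = scores[~np.isnan(scores)]
        if present.size and (not np.all(np.isfinite(present)) or np.any(present < 0)):
            raise ValueError("present scores must be finite and >= 0")
        self.biomarker_ids = biomarker_ids
        self.target_ids = target_ids
        self.scores = scores
        self._brow = {b: i for i, b in enumerate(biomarker_ids)}
        self._tcol = {t: j for j, t in enumerate(target_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape  # type: ignore[return-value]

    def get(self, biomarker_id: str, target_id: str) -> float | None:
        """Score for a pair, or ``None`` when missing."""
        v = self.scores[self._brow[biomarker_id], self._tcol[target_id]]
        return None if np.isnan(v) else float(v)

    def iter_present(self) -> Iterator[tuple[str, str, float]]:
        """Yield (biomarker, target, pKd) for every non-missing cell."""
        rows, cols = np.nonzero(~np.isnan(self.scores))
        for i, j in zip(rows.tolist(), cols.tolist()):
            yield self.biomarker_ids[i], self.target_ids[j], float(self.scores[i, j])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DockingScoreMatrix):
            return NotImplemented
        return (
            self.biomarker_ids == other.biomarker_ids
            and self.target_ids == other.target_ids
            and np.array_equal(self.scores, other.scores, equal_nan=True)
        )

    def __repr__(self) -> str:
        n, m = self.shape
        return f"DockingScoreMatrix({n} biomarkers x {m} targets)"


class BipartiteNetwork:
    """Two disjoint node partitions joined by cross-partition edges.

    Nodes are derived from the edge set, so an isolated node cannot exist by
    construction. Edge weights (pKd) are optional.
    """

    __slots__ = ("left_role", "right_role", "_edges")

    def __init__(
        self,
        edges: Mapping[tuple[str, str], float | None] | Iterable[tuple[str, str]],
        left_role: str = "biomarker",
        right_role: str = "target",
    ) -> None:
        if isinstance(edges, Mapping):
            edge_map = {(str(l), str(r)): w for (l, r), w in edges.items()}
        else:
            edge_map = {(str(l), str(r)): None for l, r in edges}
        for l, r in edge_map:
            if l == r:
                raise ValueError(f"self-edge not allowed: {l!r}")
        self.left_role = left_role
        self.right_role = right_role
        self._edges = edge_map

    @property
    def left_nodes(self) -> frozenset[str]:
        return frozenset(l for l, _ in self._edges)

    @property
    def right_nodes(self) -> frozenset[str]:
        return frozenset(r for _, r in self._edges)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def edges(self) -> list[tuple[str, str, float | None]]:
        """Edges as (left, right, weight), sorted for determinism."""
        return sorted((l, r, w) for (l, r), w in self._edges.items())

    def weight(self, left: str, right: str) -> float | None:
        return self._edges[(left, right)]

    def has_edge(self, left: str, right: str) -> bool:
        return (left, right) in self._edges

    def degrees(self, side: str) -> dict[str, int]:
        """Degree per node on ``side`` ('left'/'right' or a role name)."""
        if side in ("left", self.left_role):
            idx = 0
        elif side in ("right", self.right_role):
            idx = 1
        else:
            raise ValueError(
                f"unknown side {side!r}; expected 'left'/'right' or "
                f"{self.left_role!r}/{self.right_role!r}"
            )
        out: dict[str, int] = {}
        for pair in self._edges:
            out[pair[idx]] = out.get(pair[idx], 0) + 1
        return out

    def summary(self) -> "NetworkSummary":
        """Node/edge counts and the two mean-partner ratios."""
        n_left, n_right, n_edges = len(self.left_nodes), len(self.right_nodes), self.n_edges
        return NetworkSummary(
            n_left=n_left,
            n_right=n_right,
            n_edges=n_edges,
            mean_right_per_left=(n_edges / n_left) if n_left else 0.0,
            mean_left_per_right=(n_edges / n_right) if n_right else 0.0,
        )

    def to_networkx(self):
        """Export to a ``networkx.Graph`` with bipartite/role attributes."""
        import networkx as nx

        g = nx.Graph()
        for l in sorted(self.left_nodes):
            g.add_node(l, bipartite=0, role=self.left_role)
        for r in sorted(self.right_nodes):
            g.add_node(r, bipartite=1, role=self.right_role)
        for (l, r), w in sorted(self._edges.items()):
            if w is None:
                g.add_edge(l, r)
            else:
                g.add_edge(l, r, weight=w)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BipartiteNetwork):
            return NotImplemented
        return self._edges == other._edges

    def __repr__(self) -> str:
        return (
            f"BipartiteNetwork({len(self.left_nodes)} {self.left_role} x "
            f"{len(self.right_nodes)} {self.right_role}, {self.n_edges} edges)"
        )


@dataclass(frozen=True, slots=True)
class NetworkSummary:
    """Size summary of a bipartite network.

    The mean fields are exact ratios; use :meth:`rounded` for the 2-decimal
    half-up values used in reports.
    """

    n_left: int
    n_right: int
    n_edges: int
    mean_right_per_left: float
    mean_left_per_right: float

    @property
    def is_empty(self) -> bool:
        return self.n_edges == 0

    def rounded(self, ndigits: int = 2) -> tuple[float, float]:
        return (
            round_half_up(self.mean_right_per_left, ndigits),
            round_half_up(self.mean_left_per_right, ndigits),
        )


@dataclass(frozen=True, slots=True)
class PathwayScore:
    """A pathway's computed index for one system, with edge provenance."""

    pathway_id: str
    system: str
    score: float
    contributing_edges: tuple[tuple[str, str, float], ...] = ()
    pathway_name: str = ""

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"pathway {self.pathway_id}: score must be non-negative")
        if (self.score == 0) != (len(self.contributing_edges) == 0):
            raise ValueError(
                f"pathway {self.pathway_id}: score is zero iff no edge contributes"
            )


@dataclass(frozen=True, slots=True)
class StudyConfig:
    """Pipeline-wide analysis parameters with their default values."""

    threshold_pkd: float = 5.52
    comparator: str = "greater"
    count_mode: str = "contributing_biomarkers"
    top_k: int = 10
    hub_min_degree: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.threshold_pkd <= 15.0):
            raise ValueError(f"threshold_pkd {self.threshold_pkd} outside [0, 15]")
        if self.comparator not in ("greater", "greater_equal"):
            raise ValueError(f"unknown comparator {self.comparator!r}")
        if self.count_mode not in (
            "n_biomarkers",
            "contributing_biomarkers",
            "per_biomarker_edge_count",
        ):
            raise ValueError(f"unknown count_mode {self.count_mode!r}")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.hub_min_degree < 0:
            raise ValueError("hub_min_degree must be >= 0")


@dataclass(slots=True)
class StudyBundle:
    """All tabular inputs of one study, cross-referenced and validated."""

    biomarkers: dict[str, Biomarker] = field(default_factory=dict)
    enzymes: dict[str, Enzyme] = field(default_factory=dict)
    relations: list[tuple[str, str]] = field(default_factory=list)
    targets: dict[str, TargetProtein] = field(default_factory=dict)
    scores: DockingScoreMatrix | None = None
    pathways: dict[str, Pathway] = field(default_factory=dict)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StudyBundle):
            return NotImplemented
        return (
            self.biomarkers == other.biomarkers
            and self.enzymes == other.enzymes
            and sorted(self.relations) == sorted(other.relations)
            and self.targets == other.targets
            and self.scores == other.scores
            and self.pathways == other.pathways
        )
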