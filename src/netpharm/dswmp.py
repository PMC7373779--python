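"""Docking-score-weighted pathway index (DSWMP) and top-k pathway ranking.

The index sums passing pKd scores over edges whose target belongs to a
pathway, normalized by a biomarker count. The normalization is ambiguous in
the defining formula, so three readings are implemented and selected by
``count_mode``:

* ``n_biomarkers`` — divide the edge-weight sum by the total number of
  biomarkers in the docking matrix.
* ``contributing_biomarkers`` (default) — divide by the number of
  biomarkers with at least one passing edge into the pathway.
* ``per_biomarker_edge_count`` — divide each biomarker's weight sum by its
  own pathway edge count, then sum the per-biomarker means.

Every report names the mode used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .model import Pathway, PathwayScore

__all__ = [
    "COUNT_MODES",
    "DswmpConfig",
    "AlluvialTable",
    "dswmp_score",
    "score_all_pathways",
    "top_k",
    "cross_system_overlap",
]

COUNT_MODES = ("n_biomarkers", "contributing_biomarkers", "per_biomarker_edge_count")

Edge = tuple[str, str, float]


@dataclass(frozen=True, slots=True)
class DswmpConfig:
    count_mode: str = "contributing_biomarkers"
    top_k: int = 10

    def __post_init__(self) -> None:
        if self.count_mode not in COUNT_MODES:
            raise ValueError(f"unknown count_mode {self.count_mode!r}; "
                             f"expected one of {COUNT_MODES}")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass(frozen=True, slots=True)
class AlluvialTable:
    """System -> pathway presence rows underlying the cross-system plot."""

    rows: tuple[tuple[str, str, float], ...]  # (system, pathway_id, score)

    def pathway_systems(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for system, pid, _ in self.rows:
            out.setdefault(pid, set()).add(system)
        return {pid: frozenset(s) for pid, s in sorted(out.items())}

    def overlap_classes(self) -> dict[str, int]:
        """Pathway -> number of systems whose top-k contains it."""
        return {pid: len(s) for pid, s in self.pathway_systems().items()}


def dswmp_score(edges: Sequence[Edge], pathway: Pathway,
                config: DswmpConfig | None = None,
                *, n_biomarkers: int | None = None) -> PathwayScore:
    """Score one pathway against a thresholded weighted edge list.

    ``n_biomarkers`` (the matrix row count) is required by the
    ``n_biomarkers`` mode; when omitted it defaults to the number of
    distinct biomarkers in ``edges``. A pathway that no edge touches scores
    a legal 0; a pathway with an empty member set is a scoring error.
    """
    config = config or DswmpConfig()
    if not pathway.members:
        raise ValueError(f"pathway {pathway.id} has an empty member set; "
                         "cannot be scored (distinct from a zero score)")
    hits = tuple(sorted((b, t, s) for b, t, s in edges if t in pathway.members))
    if not hits:
        return PathwayScore(pathway.id, system="", score=0.0,
                            contributing_edges=(), pathway_name=pathway.name)
    per_b: dict[str, list[float]] = {}
    for b, _, s in hits:
        per_b.setdefault(b, []).append(s)
    if config.count_mode == "n_biomarkers":
        n = n_biomarkers if n_biomarkers is not None else len({b for b, _, _ in edges})
        if n < 1:
            raise ValueError("n_biomarkers must be >= 1")
        score = sum(s for _, _, s in hits) / n
    elif config.count_mode == "contributing_biomarkers":
        score = sum(s for _, _, s in hits) / len(per_b)
    else:  # per_biomarker_edge_count
        score = sum(sum(ss) / len(ss) for ss in per_b.values())
    return PathwayScore(pathway.id, system="", score=score,
                        contributing_edges=hits, pathway_name=pathway.name)


def score_all_pathways(
    edges_by_system: Mapping[str, Sequence[Edge]],
    pathways: Mapping[str, Pathway],
    config: DswmpConfig | None = None,
    *, n_biomarkers: int | None = None,
) -> dict[str, list[PathwayScore]]:
    """One score per (system, pathway); each system's list is ranked.

    Ordering is score-descending with pathway-id-ascending tie-break;
    scores are kept unrounded (round only for display).
    """
    config = config or DswmpConfig()
    if not pathways:
        raise ValueError("pathway catalog is empty")
    out: dict[str, list[PathwayScore]] = {}
    for system, edges in edges_by_system.items():
        scored = []
        for pid in sorted(pathways):
            ps = dswmp_score(edges, pathways[pid], config, n_biomarkers=n_biomarkers)
            scored.append(PathwayScore(ps.pathway_id, system, ps.score,
                                       ps.contributing_edges, ps.pathway_name))
        scored.sort(key=lambda p: (-p.score, p.pathway_id))
        out[system] = scored
    return out


def top_k(scores: Sequence[PathwayScore], k: int) -> list[PathwayScore]:
    """First ``k`` rows of the ranked list (shorter when fewer pathways)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(scores, key=lambda p: (-p.score, p.pathway_id))
    return list(ranked[:k])


def cross_system_overlap(
    top_by_system: Mapping[str, Sequence[PathwayScore]],
) -> AlluvialTable:
    """Tabulate which top-ranked pathways recur across systems."""
    rows: list[tuple[str, str, float]] = []
    for system in sorted(top_by_system):
        for ps in top_by_system[system]:
            rows.append((system, ps.pathway_id, ps.score))
    return AlluvialTable(tuple(rows))
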