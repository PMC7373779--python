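"""Biomarker-target interaction networks from thresholded docking scores.

The default rule keeps a pair when its pKd is *strictly greater* than 5.52
(the pKd of a 3 uM dissociation constant); '>=' is available via the
comparator field. Thresholds outside the calibrated [4.82, 6.11] pKd window
trigger a warning because the rule's reported accuracy was established
inside it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

from .model import SYSTEMS, BipartiteNetwork, DockingScoreMatrix, NetworkSummary, TargetProtein

__all__ = [
    "ThresholdRule",
    "SystemMembershipClass",
    "threshold_edges",
    "build_mti_network",
    "summarize_network",
    "system_membership_classes",
    "shared_targets",
]

logger = logging.getLogger(__name__)

#: Display class per system-membership count, as used in network figures.
MEMBERSHIP_COLORS = {1: "blue", 2: "yellow", 3: "red"}


@dataclass(frozen=True, slots=True)
class ThresholdRule:
    """Docking-score acceptance rule on the pKd scale."""

    threshold: float = 5.52
    comparator: str = "greater"
    calibrated_range: tuple[float, float] = (4.82, 6.11)

    def __post_init__(self) -> None:
        if not (self.threshold == self.threshold and abs(self.threshold) != float("inf")):
            raise ValueError("threshold must be finite")
        if self.comparator not in ("greater", "greater_equal"):
            raise ValueError(f"unknown comparator {self.comparator!r}")
        lo, hi = self.calibrated_range
        if lo > hi:
            raise ValueError("calibrated_range lower bound exceeds upper bound")

    def passes(self, score: float) -> bool:
        if self.comparator == "greater":
            return score > self.threshold
        return score >= self.threshold


@dataclass(frozen=True, slots=True)
class SystemMembershipClass:
    """Per-target count of containing systems (1-3) with its display color."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for t, c in self.counts.items():
            if c not in (1, 2, 3):
                raise ValueError(f"target {t}: membership count {c} not in 1..3")

    def color(self, target_id: str) -> str:
        return MEMBERSHIP_COLORS[self.counts[target_id]]

    def class_sizes(self) -> dict[int, int]:
        sizes = {1: 0, 2: 0, 3: 0}
        for c in self.counts.values():
            sizes[c] += 1
        return sizes


def threshold_edges(matrix: DockingScoreMatrix,
                    rule: ThresholdRule | None = None) -> list[tuple[str, str, float]]:
    """Pairs whose score passes the rule, as (biomarker, target, pKd).

    Missing matrix entries never pass. Output is sorted by (biomarker,
    target) for determinism.
    """
    rule = rule or ThresholdRule()
    lo, hi = rule.calibrated_range
    if not (lo <= rule.threshold <= hi):
        msg = (f"threshold {rule.threshold} pKd is outside the calibrated "
               f"range [{lo}, {hi}]")
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return sorted((b, t, s) for b, t, s in matrix.iter_present() if rule.passes(s))


def build_mti_network(edges: list[tuple[str, str, float]], system: str,
                      targets: Mapping[str, TargetProtein]) -> BipartiteNetwork:
    """Restrict thresholded edges to targets of one physiological system.

    Biomarkers and targets left with no surviving edge are excluded; pKd
    edge weights are preserved.
    """
    if system not in SYSTEMS:
        raise ValueError(f"unknown system {system!r}; expected one of {SYSTEMS}")
    kept = {
        (b, t): s for b, t, s in edges
        if t in targets and system in targets[t].systems
    }
    return BipartiteNetwork(kept, left_role="biomarker", right_role="target")


def summarize_network(network: BipartiteNetwork) -> NetworkSummary:
    """Node/edge counts with mean partners per side (zeros when empty)."""
    return network.summary()


def system_membership_classes(targets: Mapping[str, TargetProtein]) -> SystemMembershipClass:
    """Classify every catalog target by how many systems contain it."""
    for t in targets.values():
        if not t.systems:
            raise ValueError(f"target {t.id} has an empty systems set")
    return SystemMembershipClass({tid: len(t.systems) for tid, t in targets.items()})


def shared_targets(networks: Mapping[str, BipartiteNetwork]) -> list[str]:
    """Targets present in all three per-system networks, sorted."""
    if len(networks) < 3:
        raise ValueError("shared_targets needs one network per system (three)")
    sets = [net.right_nodes for net in networks.values()]
    return sorted(frozenset.intersection(*sets))
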