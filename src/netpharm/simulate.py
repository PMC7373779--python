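"""Synthetic study bundles and exact-shape bipartite fixtures.

Two generators live here:

* :func:`gen_study` draws a full study bundle (biomarker/enzyme/target
  catalogs, relations, docking scores, pathways) with the statistical
  structure the analysis stages assume, from a :class:`SimulationSpec`.
* :func:`gen_fixture_network` builds a bipartite network with *exactly* the
  requested node and edge counts and no isolated node, which
  :func:`attach_scores` can dress with a score matrix whose thresholding
  reconstructs the network.

Randomness: one global seed is mapped to an independent substream per
component (see :func:`substream`), so adding a component never perturbs the
draws of earlier ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import (
    PLATFORMS,
    SYSTEMS,
    Biomarker,
    BipartiteNetwork,
    DockingScoreMatrix,
    Enzyme,
    Pathway,
    StudyBundle,
    TargetProtein,
)

__all__ = [
    "ScoreModel",
    "SimulationSpec",
    "FixtureSpec",
    "substream",
    "gen_study",
    "gen_fixture_network",
    "attach_scores",
]


def substream(seed: int, component: str) -> np.random.Generator:
    """Deterministic per-component RNG derived from one global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(component.encode("utf-8"))])
    )


@dataclass(frozen=True, slots=True)
class ScoreModel:
    """Two-component truncated-normal mixture around a pKd threshold.

    A pair passes with probability ``pass_fraction``; passing scores are
    drawn from Normal(mu_above, sigma_above) truncated to (threshold, inf),
    failing ones from Normal(mu_below, sigma_below) truncated to
    [0, threshold].
    """

    pass_fraction: float = 0.08
    threshold: float = 5.52
    mu_above: float = 6.2
    sigma_above: float = 0.5
    mu_below: float = 4.0
    sigma_below: float = 1.0
    missing_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pass_fraction <= 1.0):
            raise ValueError(f"pass_fraction {self.pass_fraction} outside [0, 1]")
        if not (0.0 <= self.missing_fraction <= 1.0):
            raise ValueError(f"missing_fraction {self.missing_fraction} outside [0, 1]")
        if self.sigma_above <= 0 or self.sigma_below <= 0:
            raise ValueError("score model sigmas must be positive")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")

    def _trunc(self, lo: float, hi: float, mu: float, sigma: float,
               size: int, rng: np.random.Generator) -> np.ndarray:
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size,
                                   random_state=rng)

    def draw_above(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Scores strictly above the threshold."""
        out = self._trunc(self.threshold, np.inf, self.mu_above,
                          self.sigma_above, size, rng)
        # truncnorm can return the boundary itself at float precision
        return np.nextafter(out, np.inf, where=out <= self.threshold, out=out)

    def draw_below(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Scores at or below the threshold (and >= 0)."""
        return self._trunc(0.0, self.threshold, self.mu_below,
                           self.sigma_below, size, rng)


@dataclass(frozen=True, slots=True)
class SystemSizes:
    """Target-set sizes for (nervous, immune, endocrine) with overlaps.

    ``pair_overlaps`` are the full pairwise intersection sizes (each
    includes the triple overlap) in the order (nervous&immune,
    nervous&endocrine, immune&endocrine).
    """

    sizes: tuple[int, int, int] = (155, 60, 125)
    pair_overlaps: tuple[int, int, int] = (14, 14, 14)
    triple_overlap: int = 9

    def region_counts(self) -> dict[frozenset[str], int]:
        """Exclusive Venn-region sizes; raises if any region is negative."""
        a, b, c = self.sizes
        ab, ac, bc = self.pair_overlaps
        t = self.triple_overlap
        regions = {
            frozenset(SYSTEMS): t,
            frozenset({"nervous", "immune"}): ab - t,
            frozenset({"nervous", "endocrine"}): ac - t,
            frozenset({"immune", "endocrine"}): bc - t,
            frozenset({"nervous"}): a - ab - ac + t,
            frozenset({"immune"}): b - ab - bc + t,
            frozenset({"endocrine"}): c - ac - bc + t,
        }
        bad = {tuple(sorted(k)): v for k, v in regions.items() if v < 0}
        if bad:
            raise ValueError(
                f"infeasible system overlap configuration; negative region(s): {bad}")
        return regions

    @property
    def n_targets(self) -> int:
        return sum(self.region_counts().values())


@dataclass(frozen=True, slots=True)
class SimulationSpec:
    """Knobs of the synthetic study generator (defaults echo the study shape)."""

    n_biomarkers: int = 36
    n_enzymes: int = 350
    enzyme_degree_law: str = "powerlaw"
    powerlaw_exponent: float = 2.0
    max_enzyme_degree: int = 8
    up_fraction: float = 0.35
    system_sizes: SystemSizes = field(default_factory=SystemSizes)
    n_pathways: int = 40
    pathway_size_range: tuple[int, int] = (5, 30)
    score_model: ScoreModel = field(default_factory=ScoreModel)
    docked_biomarker_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_biomarkers", "n_enzymes", "n_pathways"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.enzyme_degree_law not in ("uniform", "powerlaw"):
            raise ValueError(f"unknown enzyme_degree_law {self.enzyme_degree_law!r}")
        if not (0.0 <= self.up_fraction <= 1.0):
            raise ValueError("up_fraction outside [0, 1]")
        if not (0.0 < self.docked_biomarker_fraction <= 1.0):
            raise ValueError("docked_biomarker_fraction outside (0, 1]")
        lo, hi = self.pathway_size_range
        if lo < 1 or hi < lo:
            raise ValueError(f"bad pathway_size_range {self.pathway_size_range}")
        self.system_sizes.region_counts()  # fail fast on infeasible overlaps


@dataclass(frozen=True, slots=True)
class FixtureSpec:
    """Exact-shape bipartite network request: n_left / n_right / n_edges."""

    n_left: int
    n_right: int
    n_edges: int
    seed: int = 0

    def __post_init__(self) -> None:
        lo = max(self.n_left, self.n_right)
        hi = self.n_left * self.n_right
        if self.n_left < 1 or self.n_right < 1:
            raise ValueError("n_left and n_right must be >= 1")
        if not (lo <= self.n_edges <= hi):
            raise ValueError(
                f"infeasible fixture: need max(n_left, n_right) <= n_edges <= "
                f"n_left * n_right, i.e. {lo} <= n_edges <= {hi}; got {self.n_edges}")


_ENZYME_FUNCTIONS = (
    "Hydrolase", "Transferase", "Acyltransferase", "Oxidoreductase",
    "Lyase", "Ligase", "Isomerase", "Aminotransferase",
)
_METABOLITE_STEMS = (
    "octadecanoate", "sphingoid", "glycinate", "glutaminoid", "cholinate",
    "hexose", "citroid", "lysolipid", "alaninate", "phenylalaninate",
    "ureide", "valinate", "lactoid", "aminoxide", "oxalate", "thionine",
)


def _biomarker_id(i: int) -> str:
    return f"HMDB{7000000 + i:07d}"


def _protein_id(prefix: str, i: int) -> str:
    # UniProt-shaped: letter, digit, letter, two alphanumerics, digit
    if not (0 <= i < 26000):
        raise ValueError("protein index out of range for id scheme")
    return f"{prefix}{i // 2600}{chr(ord('A') + (i // 100) % 26)}{i % 100:02d}4"


def gen_study(spec: SimulationSpec) -> StudyBundle:
    """Draw a full synthetic study bundle; same spec + seed is reproducible."""
    bundle = StudyBundle()

    # biomarker catalog
    rng = substream(spec.seed, "biomarkers")
    ups = rng.random(spec.n_biomarkers) < spec.up_fraction
    for i in range(spec.n_biomarkers):
        bid = _biomarker_id(i)
        bundle.biomarkers[bid] = Biomarker(
            id=bid,
            name=f"{_METABOLITE_STEMS[i % len(_METABOLITE_STEMS)]}-{i:02d}",
            platform=PLATFORMS[i % len(PLATFORMS)],
            trend="up" if ups[i] else "down",
        )
    bids = list(bundle.biomarkers)

    # enzyme catalog + relations with a skewed biomarker-degree law
    rng = substream(spec.seed, "enzymes")
    if spec.enzyme_degree_law == "powerlaw":
        ks = np.arange(1, spec.max_enzyme_degree + 1)
        pk = ks.astype(float) ** (-spec.powerlaw_exponent)
        degrees = rng.choice(ks, size=spec.n_enzymes, p=pk / pk.sum())
    else:
        degrees = rng.integers(1, spec.max_enzyme_degree + 1, size=spec.n_enzymes)
    degrees = np.minimum(degrees, spec.n_biomarkers)
    for i in range(spec.n_enzymes):
        eid = _protein_id("E", i)
        n_fun = int(rng.integers(0, 3))
        funs = frozenset(rng.choice(_ENZYME_FUNCTIONS, size=n_fun, replace=False))
        bundle.enzymes[eid] = Enzyme(eid, f"enzyme-{i:03d}", funs)
        partners = rng.choice(bids, size=int(degrees[i]), replace=False)
        bundle.relations.extend((str(b), eid) for b in sorted(partners))

    # target catalog honouring the requested Venn-region sizes
    rng = substream(spec.seed, "targets")
    regions = spec.system_sizes.region_counts()
    i = 0
    for systems in sorted(regions, key=lambda s: tuple(sorted(s))):
        for _ in range(regions[systems]):
            tid = _protein_id("T", i)
            bundle.targets[tid] = TargetProtein(tid, f"target-{i:03d}", systems)
            i += 1
    tids = list(bundle.targets)

    # docking score matrix: Bernoulli(pass_fraction) mixture per pair
    rng = substream(spec.seed, "scores")
    sm = spec.score_model
    n_docked = max(1, round(spec.docked_biomarker_fraction * len(bids)))
    docked = sorted(rng.choice(bids, size=n_docked, replace=False))
    grid = np.empty((len(docked), len(tids)))
    passes = rng.random(grid.shape) < sm.pass_fraction
    grid[passes] = sm.draw_above(int(passes.sum()), rng)
    grid[~passes] = sm.draw_below(int((~passes).sum()), rng)
    if sm.missing_fraction > 0:
        grid[rng.random(grid.shape) < sm.missing_fraction] = np.nan
    bundle.scores = DockingScoreMatrix(docked, tids, grid)

    # pathways drawing members from the target catalog
    rng = substream(spec.seed, "pathways")
    lo, hi = spec.pathway_size_range
    hi = min(hi, len(tids))
    lo = min(lo, hi)
    for k in range(spec.n_pathways):
        pid = f"hsa{10000 + k:05d}"
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(str(t) for t in rng.choice(tids, size=size, replace=False))
        bundle.pathways[pid] = Pathway(pid, f"pathway-{k:02d}", members)

    return bundle


def gen_fixture_network(spec: FixtureSpec, *, left_prefix: str = "B",
                        right_prefix: str = "T") -> BipartiteNetwork:
    """Bipartite network with exactly the requested shape, no isolated node.

    A spanning assignment first gives every node one edge, then the
    remaining edges are sampled uniformly without replacement from the
    unused cross-partition pairs.
    """
    rng = np.random.default_rng(spec.seed)
    nl, nr, ne = spec.n_left, spec.n_right, spec.n_edges
    lefts = [f"{left_prefix}{i:03d}" for i in range(nl)]
    rights = [f"{right_prefix}{j:03d}" for j in range(nr)]
    lperm = rng.permutation(nl)
    rperm = rng.permutation(nr)
    # (i mod nl, i mod nr) for i < max(nl, nr) are pairwise distinct because
    # indices collide only at multiples of lcm(nl, nr) >= max(nl, nr)
    edges: set[tuple[int, int]] = {
        (int(lperm[i % nl]), int(rperm[i % nr])) for i in range(max(nl, nr))
    }
    pool = np.array(
        [(i, j) for i in range(nl) for j in range(nr) if (i, j) not in edges],
        dtype=int,
    ).reshape(-1, 2)
    extra = ne - len(edges)
    if extra:
        pick = rng.choice(len(pool), size=extra, replace=False)
        edges.update((int(i), int(j)) for i, j in pool[pick])
    return BipartiteNetwork(
        {(lefts[i], rights[j]): None for i, j in edges},
        left_role="biomarker", right_role="target",
    )


def attach_scores(network: BipartiteNetwork, score_model: ScoreModel | None = None,
                  seed: int = 0, *, missing_nonedges: bool = False) -> DockingScoreMatrix:
    """Dress a network with a score matrix that thresholds back to it.

    Every edge receives a score strictly above the model threshold; every
    non-edge pair receives one at or below it (or NaN when
    ``missing_nonedges``), so thresholding with the strict 'greater'
    comparator reconstructs the input edge set exactly.
    """
    if network.n_edges == 0:
        raise ValueError("cannot attach scores to an empty network")
    sm = score_model or ScoreModel()
    rng = np.random.default_rng(seed)
    bids = sorted(network.left_nodes)
    tids = sorted(network.right_nodes)
    grid = np.full((len(bids), len(tids)), np.nan)
    mask = np.zeros(grid.shape, dtype=bool)
    for i, b in enumerate(bids):
        for j, t in enumerate(tids):
            mask[i, j] = network.has_edge(b, t)
    grid[mask] = sm.draw_above(int(mask.sum()), rng)
    if not missing_nonedges:
        grid[~mask] = sm.draw_below(int((~mask).sum()), rng)
    return DockingScoreMatrix(bids, tids, grid)
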