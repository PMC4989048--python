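"""Cross-study DEG comparison: universe harmonisation, multi-set
intersections and hypergeometric overlap significance.

Studies are compared on the intersection of their measured gene universes
(the conservative valid choice when no common platform annotation exists).
Pairwise overlap significance is a one-sided upper-tail hypergeometric test;
intersections are reported both direction-blind and direction-aware (up with
up, down with down).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .phenonet import hypergeom_upper_tail

__all__ = [
    "StudyDEGs",
    "OverlapResult",
    "harmonize_universe",
    "overlap_sets",
    "hypergeometric_overlap",
]


@dataclass
class StudyDEGs:
    label: str
    universe: set[str]
    up: set[str]
    down: set[str]
    log2fc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.up & self.down:
            raise ValueError(f"{self.label}: up and down DEG sets overlap")
        if not (self.up | self.down) <= self.universe:
            raise ValueError(f"{self.label}: DEGs outside the study universe")

    @property
    def degs(self) -> set[str]:
        return self.up | self.down

    def restricted(self, universe: set[str]) -> "StudyDEGs":
        return StudyDEGs(
            label=self.label,
            universe=set(universe),
            up=self.up & universe,
            down=self.down & universe,
            log2fc={g: v for g, v in self.log2fc.items() if g in universe},
        )


@dataclass
class OverlapResult:
    universe_size: int
    pairwise: dict[tuple[str, str], dict]
    common: set[str]
    common_directional: set[str]
    common_log2fc: dict[str, dict[str, float]]


def harmonize_universe(studies: list[StudyDEGs]):
    """Intersect study universes; DEG sets are restricted accordingly.

    Returns ``(universe, restricted_studies)``.
    """
    if len(studies) < 2:
        raise ValueError("need at least two studies to harmonise")
    universe = set.intersection(*(s.universe for s in studies))
    if not universe:
        raise ValueError("study universes share no genes")
    return universe, [s.restricted(universe) for s in studies]


def hypergeometric_overlap(a: set[str], b: set[str], universe: set[str]) -> float:
    """P(overlap >= observed) under random draws of |a| and |b| from the universe."""
    if not universe:
        raise ValueError("universe is empty")
    if not (a <= universe and b <= universe):
        raise ValueError("both sets must be contained in the universe")
    return hypergeom_upper_tail(len(a & b), len(universe), len(a), len(b))


def overlap_sets(studies: list[StudyDEGs], direction_aware: bool = False) -> OverlapResult:
    """All pairwise and the full intersection of study DEG sets.

    ``direction_aware`` restricts intersections to genes changing in the same
    direction in every study of the comparison; the default (direction-blind)
    compares the union of up- and down-regulated sets. The result carries the
    per-study log2 fold changes of the common genes and a hypergeometric
    overlap p-value per study pair.
    """
    universe, studies = harmonize_universe(studies)
    pairwise = {}
    for s1, s2 in combinations(studies, 2):
        if direction_aware:
            inter = (s1.up & s2.up) | (s1.down & s2.down)
        else:
            inter = s1.degs & s2.degs
        pairwise[(s1.label, s2.label)] = {
            "n_overlap": len(inter),
            "genes": sorted(inter),
            "p": hypergeometric_overlap(s1.degs, s2.degs, universe),
        }
    common = set.intersection(*(s.degs for s in studies))
    common_dir = set.intersection(*(s.up for s in studies)) | set.intersection(
        *(s.down for s in studies)
    )
    common_main = common_dir if direction_aware else common
    table = {
        g: {s.label: s.log2fc.get(g, float("nan")) for s in studies}
        for g in sorted(common_main)
    }
    return OverlapResult(
        universe_size=len(universe),
        pairwise=pairwise,
        common=common,
        common_directional=common_dir,
        common_log2fc=table,
    )
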