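"""Genealogy representation and family discovery.

Holds individuals with parent links, sex and monozygotic-twin labels;
discovers trios and three-generation families (proband with both parents and
two or more genotyped offspring, the unit of the transmission assay);
computes couple-descendant sets used to excuse legitimate inheritors of a
DNM allele; and confirms recorded parent-child links against
haplotype-sharing (IBD) summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"

PATERNAL = "paternal"
MATERNAL = "maternal"


class PedigreeError(ValueError):
    """Structural problem in the pedigree (duplicate ids, cycles, sex clash)."""


@dataclass(frozen=True)
class Individual:
    id: str
    sex: str = UNKNOWN
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    twin_group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sex not in (MALE, FEMALE, UNKNOWN):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.father_id == self.id or self.mother_id == self.id:
            raise PedigreeError(f"{self.id} is its own parent")


@dataclass
class ThreeGenFamily:
    """Proband with both parents and >=2 offspring: transmission-assay unit."""

    proband: Individual
    father: Individual
    mother: Individual
    offspring: List[Individual]


@dataclass(frozen=True)
class IbdSegment:
    chrom: str
    start_cm: float
    end_cm: float
    n_markers: int
    proband_haplotype: str  # paternal | maternal

    def __post_init__(self) -> None:
        if self.end_cm <= self.start_cm:
            raise ValueError("segment end must exceed start")

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm


@dataclass
class IbdSummary:
    """Haplotype sharing between a pair, as a fraction of autosomal map length."""

    pair: Tuple[str, str]
    shared_fraction: float
    segments: List[IbdSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction outside [0, 1]")


class PedigreeGraph:
    """Individuals with parent links; cycle-checked at construction."""

    def __init__(self, records: Iterable[Individual]):
        self._individuals: Dict[str, Individual] = {}
        for rec in records:
            if rec.id in self._individuals:
                raise PedigreeError(f"duplicate individual id {rec.id!r}")
            self._individuals[rec.id] = rec
        self._children: Dict[str, List[str]] = {i: [] for i in self._individuals}
        for rec in self._individuals.values():
            for parent in (rec.father_id, rec.mother_id):
                if parent is not None and parent in self._children:
                    self._children[parent].append(rec.id)
        for kids in self._children.values():
            kids.sort()
        self._check_parent_sex()
        self._check_acyclic()

    # -- construction checks -------------------------------------------------

    def _check_parent_sex(self) -> None:
        for rec in self._individuals.values():
            father = self._individuals.get(rec.father_id) if rec.father_id else None
            mother = self._individuals.get(rec.mother_id) if rec.mother_id else None
            if father is not None and father.sex == FEMALE:
                raise PedigreeError(f"father {father.id} of {rec.id} is female")
            if mother is not None and mother.sex == MALE:
                raise PedigreeError(f"mother {mother.id} of {rec.id} is male")

    def _check_acyclic(self) -> None:
        # Iterative DFS over parent links; a back edge means someone is
        # their own ancestor.
        WHITE, GREY, BLACK = 0, 1, 2
        color = {i: WHITE for i in self._individuals}
        for start in self._individuals:
            if color[start] != WHITE:
                continue
            stack: List[Tuple[str, int]] = [(start, 0)]
            while stack:
                node, stage = stack.pop()
                parents = [
                    p
                    for p in self._parent_ids(node)
                    if p is not None and p in self._individuals
                ]
                if stage == 0:
                    if color[node] == GREY:
                        raise PedigreeError(f"cyclic ancestry through {node!r}")
                    if color[node] == BLACK:
                        continue
                    color[node] = GREY
                    stack.append((node, 1))
                    for p in parents:
                        if color[p] == GREY:
                            raise PedigreeError(f"cyclic ancestry through {p!r}")
                        if color[p] == WHITE:
                            stack.append((p, 0))
                else:
                    color[node] = BLACK

    def _parent_ids(self, ind_id: str) -> Tuple[Optional[str], Optional[str]]:
        rec = self._individuals[ind_id]
        return rec.father_id, rec.mother_id

    # -- basic access --------------------------------------------------------

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._individuals

    def __len__(self) -> int:
        return len(self._individuals)

    def get(self, ind_id: str) -> Individual:
        return self._individuals[ind_id]

    def individuals(self) -> List[Individual]:
        return [self._individuals[i] for i in sorted(self._individuals)]

    def children_of(self, ind_id: str) -> List[Individual]:
        return [self._individuals[c] for c in self._children.get(ind_id, [])]

    def parents_of(self, ind_id: str) -> Tuple[Optional[Individual], Optional[Individual]]:
        rec = self._individuals[ind_id]
        father = self._individuals.get(rec.father_id) if rec.father_id else None
        mother = self._individuals.get(rec.mother_id) if rec.mother_id else None
        return father, mother

    def ancestors(self, ind_id: str) -> Set[str]:
        out: Set[str] = set()
        frontier = [ind_id]
        while frontier:
            node = frontier.pop()
            for p in self._parent_ids(node):
                if p is not None and p in self._individuals and p not in out:
                    out.add(p)
                    frontier.append(p)
        return out

    def trios(self) -> List[Tuple[Individual, Individual, Individual]]:
        """(proband, father, mother) for every individual with both parents present."""
        out = []
        for rec in self.individuals():
            father, mother = self.parents_of(rec.id)
            if father is not None and mother is not None:
                out.append((rec, father, mother))
        return out

    def mz_twin_of(self, ind_id: str) -> Optional[Individual]:
        rec = self._individuals[ind_id]
        if rec.twin_group is None:
            return None
        for other in self._individuals.values():
            if other.id != ind_id and other.twin_group == rec.twin_group:
                return other
        return None

    def twin_pairs(self) -> List[Tuple[str, str]]:
        groups: Dict[str, List[str]] = {}
        for rec in self._individuals.values():
            if rec.twin_group is not None:
                groups.setdefault(rec.twin_group, []).append(rec.id)
        return [tuple(sorted(m)) for m in groups.values() if len(m) == 2]


def build_pedigree(records: Iterable[Individual]) -> PedigreeGraph:
    return PedigreeGraph(records)


def find_three_generation_families(
    graph: PedigreeGraph, min_offspring: int = 2
) -> List[ThreeGenFamily]:
    """Probands with both parents and at least ``min_offspring`` offspring.

    Output order follows sorted proband id, so it is invariant to the input
    record order of the pedigree.
    """
    families = []
    for proband, father, mother in graph.trios():
        offspring = graph.children_of(proband.id)
        if len(offspring) >= min_offspring:
            families.append(ThreeGenFamily(proband, father, mother, offspring))
    return families


def descendants_of_pair(graph: PedigreeGraph, father: str, mother: str) -> Set[str]:
    """All individuals having BOTH members of the couple among their ancestors.

    In the common case these are the children of the couple and everything
    below them; half-sibling lineages through one member only are NOT
    included.  These individuals could legitimately inherit a DNM that arose
    in a gamete of the pair, so they are excused from the outside-carrier
    counts.
    """

    def down(start: str) -> Set[str]:
        out: Set[str] = set()
        frontier = [c.id for c in graph.children_of(start)]
        while frontier:
            node = frontier.pop()
            if node in out:
                continue
            out.add(node)
            frontier.extend(c.id for c in graph.children_of(node))
        return out

    for ind in (father, mother):
        if ind not in graph:
            raise KeyError(f"unknown individual {ind!r}")
    return down(father) & down(mother)


def confirm_relationships(
    graph: PedigreeGraph,
    ibd: Sequence[IbdSummary],
    threshold: float = 0.45,
) -> List[Tuple[Tuple[str, str], bool]]:
    """Confirm recorded parent-child links by haplotype sharing.

    A parent and child share one haplotype along essentially the whole
    autosomal map, so the shared fraction is ~1 for a genuine link and far
    lower for sample swaps.  Pairs in ``ibd`` that are not recorded as
    parent-child in the pedigree are skipped with a warning.
    """
    out = []
    for summary in ibd:
        a, b = summary.pair
        if a not in graph or b not in graph:
            warnings.warn(f"IBD summary for unknown pair {summary.pair}")
            continue
        if not _is_parent_child(graph, a, b):
            warnings.warn(f"IBD summary for non-parent-child pair {summary.pair}")
            continue
        out.append((summary.pair, summary.shared_fraction >= threshold))
    return out


def _is_parent_child(graph: PedigreeGraph, a: str, b: str) -> bool:
    rec_a, rec_b = graph.get(a), graph.get(b)
    return a in (rec_b.father_id, rec_b.mother_id) or b in (
        rec_a.father_id,
        rec_a.mother_id,
    )
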