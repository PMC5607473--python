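"""Parent-of-origin assignment for high-quality DNMs.

Two complementary methods:

* **Three-generation haplotype sharing** — an offspring carrying the DNM on
  the proband's paternal haplotype assigns the mutation to the father; an
  offspring inheriting that haplotype without the allele assigns it to the
  mother (and symmetrically).  Votes only count on identity-by-descent
  segments of at least 0.8 cM with 200 consecutive panel markers, and
  conflicting votes leave the DNM unphased.

* **Read-pair tracing** — read pairs physically linking the DNM allele to
  nearby markers whose parental origin is known from the phased panel.  The
  DNM is assigned to the parental chromosome carrying the supporting marker
  alleles, and only when all support points to a single parent.

The two calls are merged into a consensus; disagreements are counted and
excluded from the phased output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .config import RunConfig
from .datatypes import DNMCandidate, SiteEvidence
from .pedigree import MATERNAL, PATERNAL, ThreeGenFamily
from .transmission import CARRIER, MISSING, offspring_call

UNPHASED = "unphased"
DISCORDANT = "discordant"

METHOD_THREE_GEN = "three_gen"
METHOD_READ_PAIR = "read_pair"
METHOD_CONSENSUS = "consensus"

ORIGINS = (PATERNAL, MATERNAL, UNPHASED, DISCORDANT)


@dataclass
class PhaseCall:
    candidate_key: tuple
    origin: str
    method: str
    support: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")

    @property
    def phased(self) -> bool:
        return self.origin in (PATERNAL, MATERNAL)


@dataclass
class InheritanceAssignment:
    """Which proband haplotype an offspring carries at a site, and the
    size of the IBD segment supporting that assignment."""

    haplotype: str  # paternal | maternal (of the proband)
    segment_cm: float
    segment_markers: int

    def __post_init__(self) -> None:
        if self.haplotype not in (PATERNAL, MATERNAL):
            raise ValueError(f"unknown haplotype {self.haplotype!r}")


@dataclass
class ReadPairCount:
    """Read pairs traversing one DNM/marker site combination.

    ``n_ref_a1`` counts pairs joining the DNM reference allele to marker
    allele 1, and so on.  ``n_multi`` counts pairs supporting three or more
    haplotypes or inconsistent with every biallelic combination; they never
    contribute phase support.
    """

    proband_id: str
    dnm_chrom: str
    dnm_pos: int
    marker_chrom: str
    marker_pos: int
    n_ref_a1: int
    n_ref_a2: int
    n_alt_a1: int
    n_alt_a2: int
    n_multi: int = 0

    def __post_init__(self) -> None:
        if min(self.n_ref_a1, self.n_ref_a2, self.n_alt_a1, self.n_alt_a2, self.n_multi) < 0:
            raise ValueError("negative read-pair counts")


def phase_by_three_gen(
    cand: DNMCandidate,
    fam: ThreeGenFamily,
    inheritance: Mapping[str, InheritanceAssignment],
    offspring_ev: Mapping[str, SiteEvidence],
    config: Optional[RunConfig] = None,
) -> PhaseCall:
    """Phase by segregation to the proband's offspring.

    Offspring abstain when their IBD segment at the site is shorter than the
    configured minimum (0.8 cM / 200 markers), when they have no haplotype
    assignment, or when their genotype call is missing under the assay's
    missingness rules.  Unanimous votes give the origin; conflicts or no
    votes give unphased.
    """
    cfg = config or RunConfig()
    votes: List[str] = []
    for off in fam.offspring:
        assign = inheritance.get(off.id)
        if assign is None:
            continue
        if (
            assign.segment_cm < cfg.min_segment_cm
            or assign.segment_markers < cfg.min_segment_markers
        ):
            continue
        status = offspring_call(offspring_ev.get(off.id), cfg)
        if status == MISSING:
            continue
        on_paternal = assign.haplotype == PATERNAL
        if status == CARRIER:
            votes.append(PATERNAL if on_paternal else MATERNAL)
        else:
            votes.append(MATERNAL if on_paternal else PATERNAL)
    support = {
        "paternal_votes": votes.count(PATERNAL),
        "maternal_votes": votes.count(MATERNAL),
    }
    if not votes:
        return PhaseCall(cand.key, UNPHASED, METHOD_THREE_GEN, support)
    if all(v == votes[0] for v in votes):
        return PhaseCall(cand.key, votes[0], METHOD_THREE_GEN, support)
    return PhaseCall(cand.key, UNPHASED, METHOD_THREE_GEN, support)


def phase_by_read_tracing(
    cand: DNMCandidate,
    counts: Sequence[ReadPairCount],
    marker_paternal_allele: Mapping[Tuple[str, str, int], int],
    config: Optional[RunConfig] = None,
) -> PhaseCall:
    """Phase by read pairs linking the DNM allele to phased marker alleles.

    ``marker_paternal_allele`` maps (proband, chrom, pos) to the marker
    allele index (1 or 2) sitting on the proband's paternal chromosome;
    markers without an entry have unresolved origin and are dropped.  Only
    alt-allele-bearing pairs assign origin, within the configured distance
    of the DNM.  The call requires single-sided support: at least
    ``min_pair_support`` pairs for one parent and exactly zero for the other.
    """
    cfg = config or RunConfig()
    paternal = 0
    maternal = 0
    for rc in counts:
        if rc.proband_id != cand.proband_id:
            continue
        if (rc.dnm_chrom, rc.dnm_pos) != (cand.site.chrom, cand.site.pos):
            continue
        if rc.marker_chrom != rc.dnm_chrom:
            continue
        if abs(rc.marker_pos - rc.dnm_pos) > cfg.pair_window_bp:
            continue
        pat_allele = marker_paternal_allele.get(
            (rc.proband_id, rc.marker_chrom, rc.marker_pos)
        )
        if pat_allele not in (1, 2):
            continue
        alt_to_a1, alt_to_a2 = rc.n_alt_a1, rc.n_alt_a2
        if pat_allele == 1:
            paternal += alt_to_a1
            maternal += alt_to_a2
        else:
            paternal += alt_to_a2
            maternal += alt_to_a1
    support = {"paternal_pairs": paternal, "maternal_pairs": maternal}
    if paternal >= cfg.min_pair_support and maternal == 0:
        return PhaseCall(cand.key, PATERNAL, METHOD_READ_PAIR, support)
    if maternal >= cfg.min_pair_support and paternal == 0:
        return PhaseCall(cand.key, MATERNAL, METHOD_READ_PAIR, support)
    return PhaseCall(cand.key, UNPHASED, METHOD_READ_PAIR, support)


def consensus_phase(a: PhaseCall, b: PhaseCall) -> PhaseCall:
    """Merge a three-generation call and a read-pair call.

    Agreement keeps the origin; both-phased disagreement is discordant (the
    DNM is excluded from the phased output but counted); one-sided phase
    information carries through; neither phased stays unphased.
    """
    if a.candidate_key != b.candidate_key:
        raise ValueError("consensus over different candidates")
    support = {**{f"{METHOD_THREE_GEN}_{k}": v for k, v in a.support.items()},
               **{f"{METHOD_READ_PAIR}_{k}": v for k, v in b.support.items()}}
    if a.phased and b.phased:
        if a.origin == b.origin:
            return PhaseCall(a.candidate_key, a.origin, METHOD_CONSENSUS, support)
        return PhaseCall(a.candidate_key, DISCORDANT, METHOD_CONSENSUS, support)
    if a.phased:
        return PhaseCall(a.candidate_key, a.origin, METHOD_CONSENSUS, support)
    if b.phased:
        return PhaseCall(a.candidate_key, b.origin, METHOD_CONSENSUS, support)
    return PhaseCall(a.candidate_key, UNPHASED, METHOD_CONSENSUS, support)


def phase_summary_from_counts(
    n_three_gen: int,
    n_read_pair: int,
    n_both: int,
    n_discordant: int,
    n_dnms: int,
) -> pd.DataFrame:
    """Phasing summary table from method counts.

    The consensus set is the union of both phased sets minus the
    discordant calls: ``three_gen + read_pair - both - discordant``.
    """
    n_consensus = n_three_gen + n_read_pair - n_both - n_discordant
    rows = [
        ("three_gen", n_three_gen),
        ("read_pair", n_read_pair),
        ("both", n_both),
        ("both_discordant", n_discordant),
        ("consensus", n_consensus),
    ]
    df = pd.DataFrame(rows, columns=["phased_set", "count"])
    df["fraction_of_dnms"] = (
        df["count"] / n_dnms if n_dnms > 0 else float("nan")
    )
    return df


def summarize_phasing(
    three_gen_calls: Sequence[PhaseCall],
    read_pair_calls: Sequence[PhaseCall],
    consensus_calls: Sequence[PhaseCall],
    n_dnms: int,
) -> pd.DataFrame:
    """Summary table over actual phase calls (one consensus call per DNM)."""
    n_three = sum(c.phased for c in three_gen_calls)
    n_read = sum(c.phased for c in read_pair_calls)
    three_phased = {c.candidate_key: c.origin for c in three_gen_calls if c.phased}
    read_phased = {c.candidate_key: c.origin for c in read_pair_calls if c.phased}
    both_keys = set(three_phased) & set(read_phased)
    n_both = len(both_keys)
    n_disc = sum(three_phased[k] != read_phased[k] for k in both_keys)
    df = phase_summary_from_counts(n_three, n_read, n_both, n_disc, n_dnms)
    n_consensus_actual = sum(c.phased for c in consensus_calls)
    expected = int(df.loc[df.phased_set == "consensus", "count"].iloc[0])
    if n_consensus_actual != expected:
        raise AssertionError(
            f"consensus set identity violated: {n_consensus_actual} != {expected}"
        )
    return df
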