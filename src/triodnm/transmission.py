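"""Transmission assay in three-generation families, and the FoxoG covariate.

A germline DNM sits on one specific proband haplotype, so among the
proband's offspring every carrier of that haplotype must carry the allele
and every carrier of the other haplotype must not.  Candidates whose
segregation pattern admits such a haplotype are labelled consistent, the
rest inconsistent; candidates without at least two informative offspring on
distinct proband haplotypes cannot be assessed.  These labels form the
response of the quality classifier.

FoxoG quantifies 8-oxoguanine damage: a real C>A (or G>T) variant is
supported by read pairs of both sequencing orientations roughly equally,
while oxidative artifacts are confined to one orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

from .config import RunConfig
from .datatypes import HOM_ALT, MISSING, DNMCandidate, SiteEvidence, VariantSite
from .pedigree import MALE, MATERNAL, PATERNAL, ThreeGenFamily

CONSISTENT = "consistent"
INCONSISTENT = "inconsistent"
UNEVALUABLE = "unevaluable"

CARRIER = "carrier"
NON_CARRIER = "non_carrier"


@dataclass
class TransmissionLabel:
    candidate_key: tuple
    label: str
    n_offspring_informative: int

    def __post_init__(self) -> None:
        if self.label not in (CONSISTENT, INCONSISTENT, UNEVALUABLE):
            raise ValueError(f"unknown label {self.label!r}")


def foxog_metric(site: VariantSite, ev: SiteEvidence) -> float:
    """Strand-orientation affinity of the alt allele; 0 outside C>A / G>T.

    For C>A substitutions the artifact-prone orientation is F2R1, for the
    reverse-complement G>T it is F1R2.  The metric is the fraction of
    alt-supporting, orientation-resolved read pairs in the artifact
    orientation; 0 when no pairs are orientation-resolved.
    """
    sub = site.substitution
    if sub not in ("C>A", "G>T"):
        return 0.0
    denom = ev.f1r2_alt + ev.f2r1_alt
    if denom == 0:
        return 0.0
    artifact = ev.f2r1_alt if sub == "C>A" else ev.f1r2_alt
    return artifact / denom


def offspring_call(
    ev: Optional[SiteEvidence], config: Optional[RunConfig] = None
) -> str:
    """Carrier status of one offspring under the assay's missingness rules.

    Calls are missing below 10x depth; alt-carrying calls additionally
    require at least 2 alt reads and allelic balance >= 0.1.
    """
    cfg = config or RunConfig()
    if ev is None or ev.genotype == MISSING:
        return MISSING
    if ev.depth < cfg.offspring_min_depth:
        return MISSING
    if ev.carries_alt:
        if ev.alt_reads < cfg.offspring_min_alt_reads:
            return MISSING
        if ev.informative_reads == 0:
            return MISSING
        ab = ev.alt_reads / ev.informative_reads
        if ab < cfg.offspring_min_ab:
            return MISSING
        return CARRIER
    return NON_CARRIER


def assess_transmission(
    cand: DNMCandidate,
    fam: ThreeGenFamily,
    inheritance: Mapping[str, str],
    offspring_ev: Mapping[str, SiteEvidence],
    config: Optional[RunConfig] = None,
) -> TransmissionLabel:
    """Label a candidate by haplotype-consistent segregation to offspring.

    ``inheritance`` maps offspring id to the proband haplotype (``paternal``
    or ``maternal``) inherited at the site; offspring without an assignment
    abstain.  On the X chromosome, a male offspring called as a carrier but
    not homozygous-alt makes the candidate inconsistent outright.
    """
    cfg = config or RunConfig()
    on_x = cand.site.chrom == cfg.x_chrom

    statuses: Dict[str, Tuple[str, str]] = {}  # id -> (haplotype, status)
    for off in fam.offspring:
        hap = inheritance.get(off.id)
        if hap not in (PATERNAL, MATERNAL):
            continue
        status = offspring_call(offspring_ev.get(off.id), cfg)
        if status == MISSING:
            continue
        if on_x and off.sex == MALE and status == CARRIER:
            ev = offspring_ev.get(off.id)
            if ev is not None and ev.genotype != HOM_ALT:
                return TransmissionLabel(cand.key, INCONSISTENT, len(statuses) + 1)
        statuses[off.id] = (hap, status)

    n_informative = len(statuses)
    haplotypes = {hap for hap, _ in statuses.values()}
    if n_informative < cfg.min_assay_offspring or haplotypes != {PATERNAL, MATERNAL}:
        return TransmissionLabel(cand.key, UNEVALUABLE, n_informative)

    for carrier_hap in (PATERNAL, MATERNAL):
        ok = all(
            (status == CARRIER) == (hap == carrier_hap)
            for hap, status in statuses.values()
        )
        if ok:
            return TransmissionLabel(cand.key, CONSISTENT, n_informative)
    return TransmissionLabel(cand.key, INCONSISTENT, n_informative)
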