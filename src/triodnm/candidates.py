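"""DNM candidate extraction from trio read evidence.

A variant becomes a DNM candidate for a proband when the proband carries the
alternative allele with adequate depth and allelic balance, neither parent
shows meaningful alt support, few individuals outside the couple's
descendants carry the allele, and the local alignment context is clean
(soft-clipping bound).  Probands whose genome-wide alignment statistics or
candidate load are extreme are removed wholesale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .config import RunConfig
from .datatypes import HOM_ALT, DNMCandidate, SiteEvidence, VariantSite
from .pedigree import MALE, PedigreeGraph, descendants_of_pair

logger = logging.getLogger(__name__)


def allelic_balance(ev: SiteEvidence) -> float:
    """Alt reads over ref+alt reads; undefined when no informative reads."""
    total = ev.ref_reads + ev.alt_reads
    if total == 0:
        raise ZeroDivisionError("no informative reads: allelic balance undefined")
    return ev.alt_reads / total


def classify_carriers(
    site: VariantSite,
    evidence: Mapping[str, SiteEvidence],
    excluded: Set[str],
    config: Optional[RunConfig] = None,
) -> Tuple[int, int]:
    """Count possible and likely alt-allele carriers outside ``excluded``.

    Possible carriers are individuals whose called genotype contains the alt
    allele.  Likely carriers additionally satisfy depth strictly over 12,
    allelic-balance deviation from 0.5 strictly below 0.25, and genotype
    quality strictly over 20.
    """
    cfg = config or RunConfig()
    n_possible = 0
    n_likely = 0
    for ind_id, ev in evidence.items():
        if ind_id in excluded or not ev.carries_alt:
            continue
        n_possible += 1
        if ev.depth <= cfg.likely_min_depth or ev.gq <= cfg.likely_min_gq:
            continue
        if ev.informative_reads == 0:
            continue
        if abs(allelic_balance(ev) - 0.5) < cfg.likely_max_ab_dev:
            n_likely += 1
    return n_possible, n_likely


@dataclass
class ProbandStats:
    """Genome-wide per-proband evidence aggregates."""

    mean_depth: float
    mean_softclip: float
    mean_nfrac: float


def compute_proband_stats(
    evidence_by_individual: Mapping[str, Mapping[tuple, SiteEvidence]],
) -> Dict[str, ProbandStats]:
    out: Dict[str, ProbandStats] = {}
    for ind, site_evs in evidence_by_individual.items():
        evs = list(site_evs.values())
        if not evs:
            continue
        n = len(evs)
        out[ind] = ProbandStats(
            mean_depth=sum(e.depth for e in evs) / n,
            mean_softclip=sum(e.softclip_frac for e in evs) / n,
            mean_nfrac=sum(e.n_frac for e in evs) / n,
        )
    return out


def _is_x_male(site: VariantSite, proband_sex: str, cfg: RunConfig) -> bool:
    return site.chrom == cfg.x_chrom and proband_sex == MALE


def evaluate_trio_site(
    site: VariantSite,
    proband_ev: SiteEvidence,
    father_ev: SiteEvidence,
    mother_ev: SiteEvidence,
    proband_sex: str,
    n_possible: int,
    n_likely: int,
    config: Optional[RunConfig] = None,
) -> Tuple[bool, List[str]]:
    """Apply the candidate filter set to one trio at one site.

    Returns ``(retained, failed_rules)``.  Rules, in order: proband carries
    alt (hemizygous treatment on male X); hom-alt probands keep at most one
    ref read; parental depth (12 autosomal, father 6 on male-proband X);
    parental alt reads <= 1; parental AB <= 0.05; proband depth >= 12;
    proband AB >= 0.15; outside-carrier caps (10 possible / 3 likely); site
    mean soft-clip <= 10%.
    """
    cfg = config or RunConfig()
    failed: List[str] = []
    x_male = _is_x_male(site, proband_sex, cfg)

    if not proband_ev.carries_alt:
        return False, ["proband_not_carrier"]
    if x_male:
        # hemizygous: any alt genotype qualifies but ref support must be <=1
        if proband_ev.ref_reads > cfg.max_homalt_ref_reads:
            failed.append("x_male_ref_reads")
    elif proband_ev.genotype == HOM_ALT and proband_ev.ref_reads > cfg.max_homalt_ref_reads:
        failed.append("homalt_ref_reads")

    father_min = cfg.min_parent_depth_x_male if x_male else cfg.min_parent_depth
    if father_ev.depth < father_min:
        failed.append("father_depth")
    if mother_ev.depth < cfg.min_parent_depth:
        failed.append("mother_depth")
    for name, ev in (("father", father_ev), ("mother", mother_ev)):
        if ev.alt_reads > cfg.max_parent_alt_reads:
            failed.append(f"{name}_alt_reads")
        if ev.informative_reads > 0 and allelic_balance(ev) > cfg.max_parent_ab:
            failed.append(f"{name}_ab")

    if proband_ev.depth < cfg.min_proband_depth:
        failed.append("proband_depth")
    if proband_ev.informative_reads == 0:
        return False, failed + ["proband_no_informative_reads"]
    if allelic_balance(proband_ev) < cfg.min_proband_ab:
        failed.append("proband_ab")

    if n_possible > cfg.max_possible_carriers:
        failed.append("possible_carriers")
    if n_likely > cfg.max_likely_carriers:
        failed.append("likely_carriers")
    if proband_ev.softclip_frac > cfg.max_site_softclip:
        failed.append("site_softclip")
    return (not failed, failed)


def extract_candidates(
    dataset,
    graph: PedigreeGraph,
    config: Optional[RunConfig] = None,
) -> List[DNMCandidate]:
    """Run the candidate filter set over every trio and every site.

    Probands are restricted to genome-wide mean coverage above the
    configured gate (20x).  Sites without parental evidence are not
    evaluable and are skipped with a log message.
    """
    cfg = config or RunConfig()
    stats = compute_proband_stats(dataset.evidence_by_individual)
    out: List[DNMCandidate] = []
    for proband, father, mother in graph.trios():
        pstats = stats.get(proband.id)
        if pstats is None or pstats.mean_depth <= cfg.min_proband_coverage:
            continue
        excluded = descendants_of_pair(graph, father.id, mother.id)
        proband_sites = dataset.evidence_by_individual.get(proband.id, {})
        for site_key, proband_ev in sorted(proband_sites.items()):
            if not proband_ev.carries_alt:
                continue
            site = dataset.variant_index.get(site_key)
            if site is None:
                continue
            site_evidence = dataset.evidence_by_site.get(site_key, {})
            father_ev = site_evidence.get(father.id)
            mother_ev = site_evidence.get(mother.id)
            if father_ev is None or mother_ev is None:
                logger.info(
                    "skipping %s for %s: missing parental evidence", site_key, proband.id
                )
                continue
            n_poss, n_likely = classify_carriers(site, site_evidence, excluded, cfg)
            retained, _ = evaluate_trio_site(
                site,
                proband_ev,
                father_ev,
                mother_ev,
                proband.sex,
                n_poss,
                n_likely,
                cfg,
            )
            if not retained:
                continue
            out.append(
                DNMCandidate(
                    proband_id=proband.id,
                    site=site,
                    proband_ev=proband_ev,
                    father_ev=father_ev,
                    mother_ev=mother_ev,
                    proband_ab=allelic_balance(proband_ev),
                    n_possible_outside=n_poss,
                    n_likely_outside=n_likely,
                    gatk_pass=site.gatk_pass,
                )
            )
    return out


def filter_probands(
    candidates: Sequence[DNMCandidate],
    proband_stats: Mapping[str, ProbandStats],
    config: Optional[RunConfig] = None,
) -> Tuple[List[DNMCandidate], List[str]]:
    """Drop all candidates of probands with extreme genome-wide statistics.

    A proband is removed when its genome-wide mean soft-clip fraction
    exceeds 10%, its mean N fraction exceeds 1.5%, or it has more than 300
    candidates.
    """
    cfg = config or RunConfig()
    counts: Dict[str, int] = {}
    for cand in candidates:
        counts[cand.proband_id] = counts.get(cand.proband_id, 0) + 1
    excluded = []
    for proband_id, n in sorted(counts.items()):
        st = proband_stats.get(proband_id)
        too_clipped = st is not None and st.mean_softclip > cfg.proband_max_softclip
        too_many_n = st is not None and st.mean_nfrac > cfg.proband_max_nfrac
        if too_clipped or too_many_n or n > cfg.proband_max_candidates:
            excluded.append(proband_id)
    excluded_set = set(excluded)
    kept = [c for c in candidates if c.proband_id not in excluded_set]
    return kept, excluded
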