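"""End-to-end orchestration: sample QC -> candidate extraction ->
transmission labelling -> GAM scoring -> phasing -> twin validation.

``run_pipeline`` is a pure function of (dataset, config): identical inputs
give identical outputs, file for file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Set, Tuple

import pandas as pd

from . import io as tio
from .candidates import compute_proband_stats, extract_candidates, filter_probands
from .config import RunConfig
from .datatypes import DNMCandidate
from .gam import TransmissionGamResults, fit_transmission_gam
from .pedigree import ThreeGenFamily, confirm_relationships, find_three_generation_families
from .phasing import (
    PhaseCall,
    consensus_phase,
    phase_by_read_tracing,
    phase_by_three_gen,
    summarize_phasing,
)
from .reports import TwinCheck, pooled_twin_discordance, twin_concordance, variant_summary
from .sample_qc import evaluate_lane_metrics
from .transmission import (
    CONSISTENT,
    INCONSISTENT,
    UNEVALUABLE,
    TransmissionLabel,
    assess_transmission,
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    candidates: List[DNMCandidate]
    excluded_probands: List[str]
    labels: List[TransmissionLabel]
    gam: Optional[TransmissionGamResults]
    scores: pd.DataFrame
    high_quality: List[DNMCandidate]
    three_gen_calls: List[PhaseCall]
    read_pair_calls: List[PhaseCall]
    consensus_calls: List[PhaseCall]
    phase_summary: pd.DataFrame
    twin_checks: List[TwinCheck]
    variant_summary: pd.DataFrame
    counts: Dict[str, int] = field(default_factory=dict)

    def summary_dict(self) -> Dict[str, object]:
        out = dict(self.counts)
        out["twin"] = pooled_twin_discordance(self.twin_checks)
        return out


def _lane_failures(dataset: tio.Dataset) -> Set[str]:
    bad = set()
    for m in dataset.lane_metrics:
        ok, _ = evaluate_lane_metrics(m)
        if not ok and m.sample_id is not None:
            bad.add(m.sample_id)
    return bad


def _unconfirmed_children(dataset: tio.Dataset, cfg: RunConfig) -> Set[str]:
    out = set()
    if not dataset.ibd:
        return out
    for (parent, child), ok in confirm_relationships(
        dataset.pedigree, dataset.ibd, cfg.relationship_threshold
    ):
        if not ok:
            out.add(child)
    return out


def label_candidates(
    candidates: List[DNMCandidate],
    families: Mapping[str, ThreeGenFamily],
    dataset: tio.Dataset,
    cfg: RunConfig,
    excluded_offspring: Set[str] = frozenset(),
) -> List[TransmissionLabel]:
    """Transmission labels for candidates of three-generation probands."""
    labels = []
    for cand in candidates:
        fam = families.get(cand.proband_id)
        if fam is None:
            continue
        chrom, pos = cand.site.chrom, cand.site.pos
        inheritance = {}
        for off in fam.offspring:
            if off.id in excluded_offspring:
                continue
            assign = dataset.inheritance.get((off.id, chrom, pos))
            if assign is not None:
                inheritance[off.id] = assign.haplotype
        offspring_ev = {
            off.id: ev
            for off in fam.offspring
            if (ev := dataset.evidence_by_site.get(cand.site.key, {}).get(off.id))
        }
        labels.append(assess_transmission(cand, fam, inheritance, offspring_ev, cfg))
    return labels


def phase_high_quality(
    high_quality: List[DNMCandidate],
    families: Mapping[str, ThreeGenFamily],
    dataset: tio.Dataset,
    cfg: RunConfig,
) -> Tuple[List[PhaseCall], List[PhaseCall], List[PhaseCall]]:
    counts_by_site: Dict[Tuple[str, str, int], list] = {}
    for rc in dataset.pair_counts:
        counts_by_site.setdefault((rc.proband_id, rc.dnm_chrom, rc.dnm_pos), []).append(rc)
    three_calls, read_calls, consensus = [], [], []
    for cand in high_quality:
        fam = families.get(cand.proband_id)
        if fam is not None:
            inheritance = {
                off.id: assign
                for off in fam.offspring
                if (
                    assign := dataset.inheritance.get(
                        (off.id, cand.site.chrom, cand.site.pos)
                    )
                )
            }
            offspring_ev = {
                off.id: ev
                for off in fam.offspring
                if (ev := dataset.evidence_by_site.get(cand.site.key, {}).get(off.id))
            }
            a = phase_by_three_gen(cand, fam, inheritance, offspring_ev, cfg)
        else:
            from .phasing import METHOD_THREE_GEN, UNPHASED

            a = PhaseCall(cand.key, UNPHASED, METHOD_THREE_GEN, {})
        rows = counts_by_site.get((cand.proband_id, cand.site.chrom, cand.site.pos), [])
        b = phase_by_read_tracing(cand, rows, dataset.marker_phase, cfg)
        three_calls.append(a)
        read_calls.append(b)
        consensus.append(consensus_phase(a, b))
    return three_calls, read_calls, consensus


def run_twin_checks(
    high_quality: List[DNMCandidate], dataset: tio.Dataset, cfg: RunConfig
) -> List[TwinCheck]:
    checks = []
    by_proband: Dict[str, List[DNMCandidate]] = {}
    for cand in high_quality:
        by_proband.setdefault(cand.proband_id, []).append(cand)
    for a, b in dataset.pedigree.twin_pairs():
        for proband, twin in ((a, b), (b, a)):
            dnms = by_proband.get(proband, [])
            if not dnms:
                continue
            twin_ev = {
                c.site.key: ev
                for c in dnms
                if (ev := dataset.evidence_by_site.get(c.site.key, {}).get(twin))
            }
            checks.append(twin_concordance(proband, twin, dnms, twin_ev, cfg))
    return checks


def run_pipeline(
    dataset: tio.Dataset,
    config: Optional[RunConfig] = None,
    out_dir=None,
) -> PipelineResult:
    """Execute every stage on a loaded dataset; optionally write outputs."""
    cfg = config or RunConfig()
    counts: Dict[str, int] = {"n_variants": len(dataset.variants)}

    try:
        bad_samples = _lane_failures(dataset)
        bad_samples |= _unconfirmed_children(dataset, cfg)
        counts["n_excluded_samples"] = len(bad_samples)
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError("sample_qc", str(exc))

    try:
        cands = extract_candidates(dataset, dataset.pedigree, cfg)
        cands = [
            c
            for c in cands
            if not {c.proband_id}.intersection(bad_samples)
        ]
        stats = compute_proband_stats(dataset.evidence_by_individual)
        cands, excluded_probands = filter_probands(cands, stats, cfg)
        counts["n_candidates"] = len(cands)
        counts["n_excluded_probands"] = len(excluded_probands)
    except Exception as exc:
        raise PipelineError("candidate_extraction", str(exc))

    families = {
        f.proband.id: f
        for f in find_three_generation_families(dataset.pedigree, cfg.min_assay_offspring)
    }

    try:
        labels = label_candidates(cands, families, dataset, cfg, bad_samples)
        counts["n_labelled"] = sum(1 for l in labels if l.label != UNEVALUABLE)
        counts["n_consistent"] = sum(1 for l in labels if l.label == CONSISTENT)
        counts["n_inconsistent"] = sum(1 for l in labels if l.label == INCONSISTENT)
    except Exception as exc:
        raise PipelineError("transmission", str(exc))

    try:
        if cfg.gam_cutoff == 0.0:
            # degenerate cutoff: every candidate is retained; no model needed
            gam = None
            scores = _null_scores(cands)
        else:
            gam = fit_transmission_gam(cands, labels, cfg)
            scores = gam.score_candidates(cands, cutoff=cfg.gam_cutoff)
        hq_mask = scores.high_quality.to_numpy()
        high_quality = [c for c, keep in zip(cands, hq_mask) if keep]
        counts["n_high_quality"] = len(high_quality)
    except Exception as exc:
        raise PipelineError("gam_scoring", str(exc))

    try:
        three_calls, read_calls, consensus = phase_high_quality(
            high_quality, families, dataset, cfg
        )
        phase_summary = summarize_phasing(
            three_calls, read_calls, consensus, len(high_quality)
        )
        counts["n_phased"] = sum(c.phased for c in consensus)
    except Exception as exc:
        raise PipelineError("phasing", str(exc))

    try:
        twin_checks = run_twin_checks(high_quality, dataset, cfg)
    except Exception as exc:
        raise PipelineError("twin_validation", str(exc))

    var_df = pd.DataFrame(
        {
            "is_snp": [v.is_snp for v in dataset.variants],
            "biallelic": [v.biallelic for v in dataset.variants],
            "gatk_pass": [v.gatk_pass for v in dataset.variants],
            "phase_score": [v.phase_score for v in dataset.variants],
            "imputation_info": [v.imputation_info for v in dataset.variants],
        }
    )
    var_summary = variant_summary(var_df)

    result = PipelineResult(
        candidates=cands,
        excluded_probands=excluded_probands,
        labels=labels,
        gam=gam,
        scores=scores,
        high_quality=high_quality,
        three_gen_calls=three_calls,
        read_pair_calls=read_calls,
        consensus_calls=consensus,
        phase_summary=phase_summary,
        twin_checks=twin_checks,
        variant_summary=var_summary,
        counts=counts,
    )
    if out_dir is not None:
        twin_df = pd.DataFrame(
            [
                {
                    "proband": t.proband_id,
                    "twin": t.twin_id,
                    "n_dnms": t.n_dnms,
                    "n_verifiable": t.n_verifiable,
                    "n_discordant": t.n_discordant,
                    "discordance": t.discordance,
                }
                for t in twin_checks
            ],
            columns=["proband", "twin", "n_dnms", "n_verifiable", "n_discordant", "discordance"],
        )
        tio.write_results(
            out_dir,
            scores,
            consensus,
            dataset,
            cfg,
            {
                "phase_summary": phase_summary,
                "variant_summary": var_summary,
                "twin_checks": twin_df,
            },
        )
    return result


def _null_scores(cands: List[DNMCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "proband_id": [c.proband_id for c in cands],
            "chrom": [c.site.chrom for c in cands],
            "pos": [c.site.pos for c in cands],
            "ref": [c.site.ref for c in cands],
            "alt": [c.site.alt for c in cands],
            "response": [1.0] * len(cands),
            "high_quality": [True] * len(cands),
            "extrapolated": [False] * len(cands),
        }
    )
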