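"""Validation summaries: MZ-twin concordance, phase-method comparison, and
variant summary tables.

Monozygotic twins share their pre-twinning genome, so a proband's germline
DNMs should be verifiable in the co-twin; discordance flags post-twinning
(somatic) mutations or residual artifacts and serves as an independent
check of the call set, since twins play no role in the calibration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import pandas as pd

from .config import RunConfig
from .datatypes import HET, DNMCandidate, SiteEvidence, SiteKey
from .phasing import PhaseCall


@dataclass
class TwinCheck:
    proband_id: str
    twin_id: str
    n_dnms: int
    n_verifiable: int
    n_discordant: int

    def __post_init__(self) -> None:
        if not self.n_discordant <= self.n_verifiable <= self.n_dnms:
            raise ValueError("twin counts must nest: discordant <= verifiable <= dnms")

    @property
    def discordance(self) -> float:
        if self.n_verifiable == 0:
            return float("nan")
        return self.n_discordant / self.n_verifiable


def twin_concordance(
    proband_id: str,
    twin_id: str,
    dnms: Sequence[DNMCandidate],
    twin_ev: Mapping[SiteKey, SiteEvidence],
    config: Optional[RunConfig] = None,
) -> TwinCheck:
    """Check a proband's high-quality DNMs against the MZ co-twin.

    Twin calls are missing below 10x depth; heterozygous twin calls are
    additionally missing without >=2 alt reads and allelic balance >= 0.1.
    A verifiable twin call lacking the DNM allele is discordant; presence
    (het or hom-alt) is concordant.
    """
    cfg = config or RunConfig()
    n_verifiable = 0
    n_discordant = 0
    for cand in dnms:
        if cand.proband_id != proband_id:
            raise ValueError(f"candidate {cand.key} does not belong to {proband_id}")
        ev = twin_ev.get(cand.site.key)
        if ev is None or ev.genotype == "missing" or ev.depth < cfg.twin_min_depth:
            continue
        if ev.genotype == HET:
            if ev.alt_reads < cfg.twin_min_alt_reads or ev.informative_reads == 0:
                continue
            if ev.alt_reads / ev.informative_reads < cfg.twin_min_ab:
                continue
        n_verifiable += 1
        if not ev.carries_alt:
            n_discordant += 1
    return TwinCheck(proband_id, twin_id, len(dnms), n_verifiable, n_discordant)


def pooled_twin_discordance(checks: Sequence[TwinCheck]) -> Dict[str, float]:
    """Count-weighted (pooled) and per-pair mean discordance."""
    total_ver = sum(c.n_verifiable for c in checks)
    total_disc = sum(c.n_discordant for c in checks)
    pooled = total_disc / total_ver if total_ver else float("nan")
    fractions = [c.discordance for c in checks if c.n_verifiable > 0]
    mean_per_pair = sum(fractions) / len(fractions) if fractions else float("nan")
    return {
        "n_pairs": len(checks),
        "n_verifiable": total_ver,
        "n_discordant": total_disc,
        "pooled_discordance": pooled,
        "mean_per_pair_discordance": mean_per_pair,
    }


SUMMARY_COLUMNS = ["total", "gatk_pass", "phase_pass", "imputation_pass"]


def variant_summary(variants: pd.DataFrame, score_cutoff: float = 0.8) -> pd.DataFrame:
    """Variant counts stratified by type and allele structure.

    ``variants`` needs boolean/numeric columns ``is_snp``, ``biallelic``,
    ``gatk_pass`` and optional ``phase_score``/``imputation_info`` columns
    (NaN when unavailable).  The pass columns count values strictly above
    ``score_cutoff``.  Total rows are sums over SNP and indel rows.
    """
    df = variants.copy()
    for col in ("phase_score", "imputation_info"):
        if col not in df.columns:
            df[col] = float("nan")
    rows = []
    for vtype, is_snp in (("Indel", False), ("SNP", True)):
        for allele, biallelic in (("Biallelic", True), ("Non-biallelic", False)):
            sub = df[(df.is_snp == is_snp) & (df.biallelic == biallelic)]
            rows.append(
                {
                    "variant_type": vtype,
                    "allele": allele,
                    "total": len(sub),
                    "gatk_pass": int(sub.gatk_pass.sum()),
                    "phase_pass": int((sub.phase_score > score_cutoff).sum()),
                    "imputation_pass": int((sub.imputation_info > score_cutoff).sum()),
                }
            )
    out = pd.DataFrame(rows)
    for allele in ("Biallelic", "Non-biallelic"):
        sub = out[out.allele == allele]
        rows.append(
            {
                "variant_type": "Total",
                "allele": allele,
                **{c: int(sub[c].sum()) for c in SUMMARY_COLUMNS},
            }
        )
    return pd.DataFrame(rows)


def check_summary_additivity(summary: pd.DataFrame) -> bool:
    """Total rows must equal the SNP+indel sums, column by column."""
    for allele in summary.allele.unique():
        sub = summary[summary.allele == allele]
        total = sub[sub.variant_type == "Total"]
        parts = sub[sub.variant_type != "Total"]
        if total.empty:
            continue
        for col in SUMMARY_COLUMNS:
            if int(total[col].iloc[0]) != int(parts[col].sum()):
                return False
    return True


def phase_comparison(
    three_gen_calls: Sequence[PhaseCall], read_pair_calls: Sequence[PhaseCall]
) -> Dict[str, object]:
    """Concordance between the phasing methods on DNMs phased by both."""
    three = {c.candidate_key: c.origin for c in three_gen_calls if c.phased}
    read = {c.candidate_key: c.origin for c in read_pair_calls if c.phased}
    both = set(three) & set(read)
    n_disc = sum(three[k] != read[k] for k in both)
    frac = n_disc / len(both) if both else None
    return {
        "n_both": len(both),
        "n_discordant": n_disc,
        "discrepancy": frac,
        "defined": bool(both),
    }
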