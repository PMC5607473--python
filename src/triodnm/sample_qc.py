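"""Sequencing-run and sample quality control.

Three independent checks run before any variant-level work:

* per-lane alignment metrics screened against fixed rule bounds;
* a chip-concordance mismatch rate (sequenced bases disagreeing with the
  sample's homozygous chip genotypes) with a 2% ceiling;
* a contamination surrogate: the fraction of heterozygous marker pairs whose
  spanning read pairs support a third haplotype, with a 0.1% ceiling.

The module also provides the variance-ratio imputation informativeness:
``info = Var(E(theta | chip data)) / (p (1 - p))`` where theta in {0, 1} is
the per-haplotype allele count and p the allele frequency — 1 for perfectly
recovered dosages, 0 for dosages carrying only the allele frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np


class QcUndefinedError(ValueError):
    """A QC statistic has an empty denominator and is undefined."""


@dataclass
class LaneMetrics:
    lane_id: str
    mean_base_quality: float
    pct_duplicates: float
    mean_n_per_read: float
    pct_mapq_lt20: float
    pct_unmapped: float
    pct_both_unmapped: float
    pct_first_unmapped: float
    pct_second_unmapped: float
    chip_mismatch_rate: float
    sample_id: Optional[str] = None  # owning sample, for pipeline plumbing

    def __post_init__(self) -> None:
        for name in (
            "pct_duplicates",
            "pct_mapq_lt20",
            "pct_unmapped",
            "pct_both_unmapped",
            "pct_first_unmapped",
            "pct_second_unmapped",
        ):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.chip_mismatch_rate is not None and not 0.0 <= self.chip_mismatch_rate <= 1.0:
            raise ValueError("chip_mismatch_rate outside [0, 1]")


# (rule name, attribute, direction, bound): fail when value <lo> bound.
# Inequalities are strict, exactly as the rule list is printed.
LANE_RULES: List[Tuple[str, str, str, float]] = [
    ("mean_base_quality", "mean_base_quality", "lt", 25.0),
    ("pct_duplicates", "pct_duplicates", "gt", 50.0),
    ("mean_n_per_read", "mean_n_per_read", "gt", 30.0),
    ("pct_mapq_lt20", "pct_mapq_lt20", "gt", 11.0),
    ("pct_unmapped", "pct_unmapped", "gt", 40.0),
    ("pct_both_unmapped", "pct_both_unmapped", "gt", 40.0),
    ("pct_first_unmapped", "pct_first_unmapped", "gt", 40.0),
    ("pct_second_unmapped", "pct_second_unmapped", "gt", 40.0),
    ("chip_mismatch_rate", "chip_mismatch_rate", "gt", 0.02),
]


def evaluate_lane_metrics(m: LaneMetrics) -> Tuple[bool, List[str]]:
    """Screen one lane against the rule table.

    Returns ``(passed, failed_rule_names)``.  A missing (None) metric is an
    evaluation error — no rule may silently pass.
    """
    failed = []
    for name, attr, direction, bound in LANE_RULES:
        value = getattr(m, attr)
        if value is None:
            raise QcUndefinedError(f"lane {m.lane_id}: metric {name} missing")
        if direction == "lt":
            tripped = value < bound
        else:
            tripped = value > bound
        if tripped:
            failed.append(name)
    return (not failed, failed)


def chip_mismatch_rate(
    pileup_bases: Iterable[Mapping[str, int]],
    chip_genotypes: Sequence[str],
) -> float:
    """Fraction of sequenced bases disagreeing with homozygous chip genotypes.

    ``pileup_bases[i]`` maps base -> count at site i; ``chip_genotypes[i]``
    is the homozygous chip allele there.
    """
    pileups = list(pileup_bases)
    if len(pileups) != len(chip_genotypes):
        raise ValueError("pileup/genotype length mismatch")
    total = 0
    mismatch = 0
    for counts, allele in zip(pileups, chip_genotypes):
        for base, n in counts.items():
            total += n
            if base != allele:
                mismatch += n
    if total == 0:
        raise QcUndefinedError("no chip-typed bases: mismatch rate undefined")
    return mismatch / total


@dataclass
class HetPairSupport:
    """Per-sample tally of het-marker pairs with third-haplotype read support."""

    sample_id: str
    n_snp_pairs: int
    n_pairs_third_hap_ge2: int

    def __post_init__(self) -> None:
        if self.n_pairs_third_hap_ge2 > self.n_snp_pairs:
            raise ValueError("affected pairs exceed total pairs")


def contamination_fraction(
    h: HetPairSupport, threshold: float = 0.001
) -> Tuple[float, bool]:
    """Third-haplotype pair fraction and whether the sample is excluded (> 0.1%)."""
    if h.n_snp_pairs <= 0:
        raise QcUndefinedError(f"sample {h.sample_id}: no het SNP pairs")
    frac = h.n_pairs_third_hap_ge2 / h.n_snp_pairs
    return frac, frac > threshold


def imputation_info(
    expected_counts: Sequence[float], p: float, tol: float = 1e-6
) -> float:
    """Variance-ratio imputation informativeness for per-haplotype dosages.

    The observed (population) variance of the imputed expected allele counts
    is divided by ``p (1 - p)``.  Values above 1 + ``tol`` indicate dosages
    more dispersed than a Bernoulli(p) allele and are clipped with a warning.
    """
    d = np.asarray(expected_counts, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two dosages")
    if not 0.0 < p < 1.0:
        raise QcUndefinedError("allele frequency must lie strictly in (0, 1)")
    if d.min() < 0.0 or d.max() > 1.0:
        raise ValueError("dosages must lie in [0, 1]")
    info = float(np.var(d)) / (p * (1.0 - p))
    if info > 1.0 + tol:
        warnings.warn(f"imputation info {info:.4f} exceeds 1; clipped")
        info = 1.0 + tol
    return info
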