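"""Core value types shared across the DNM-calling pipeline.

A *de novo* mutation (DNM) is a variant carried by a proband but absent from
both parental germlines.  Every stage of the pipeline works with per-site,
per-individual read summaries (:class:`SiteEvidence`) attached to variant
sites (:class:`VariantSite`), and candidate calls are carried around as
:class:`DNMCandidate` records holding the trio evidence plus the derived
covariates used later for classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"
GENOTYPES = (HOM_REF, HET, HOM_ALT, MISSING)

SiteKey = Tuple[str, int, str, str]


@dataclass(frozen=True)
class VariantSite:
    """A biallelic variant site (multi-allelic records are dichotomized upstream).

    Parameters
    ----------
    chrom, pos
        Chromosome name and 1-based position.
    ref, alt
        Reference and alternative allele strings.
    gatk_pass
        Whether the site passes the variant caller's recommended filters.
    biallelic
        False when this record was derived by splitting a multi-allelic site.
    imputation_info, phase_score
        Optional upstream annotations: the variance-ratio imputation
        informativeness and the phasing quality score, both in [0, 1].
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gatk_pass: bool = True
    biallelic: bool = True
    imputation_info: Optional[float] = None
    phase_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ValueError(f"alt equals ref at {self.chrom}:{self.pos}")

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def substitution(self) -> Optional[str]:
        """``"C>A"``-style label for SNPs, None for indels."""
        if not self.is_snp:
            return None
        return f"{self.ref}>{self.alt}"


@dataclass
class SiteEvidence:
    """Read-level summary for one individual at one site.

    ``gq`` is the phred-scaled gap between the best and second-best genotype
    likelihoods.  ``f1r2_alt``/``f2r1_alt`` are alt-supporting read-pair
    counts stratified by sequencing orientation (the 8-oxoG artifact signal).
    ``softclip_frac`` and ``n_frac`` are the mean soft-clipped and mean
    N-base fractions of the reads covering the site.
    """

    ref_reads: int
    alt_reads: int
    depth: int
    genotype: str
    gq: float
    f1r2_alt: int = 0
    f2r1_alt: int = 0
    softclip_frac: float = 0.0
    n_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if min(self.ref_reads, self.alt_reads, self.depth) < 0:
            raise ValueError("negative read counts")
        if self.depth < self.ref_reads + self.alt_reads:
            raise ValueError("depth smaller than ref+alt reads")
        if self.f1r2_alt + self.f2r1_alt > self.alt_reads:
            raise ValueError("orientation counts exceed alt reads")
        for frac in (self.softclip_frac, self.n_frac):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")

    @property
    def carries_alt(self) -> bool:
        return self.genotype in (HET, HOM_ALT)

    @property
    def informative_reads(self) -> int:
        return self.ref_reads + self.alt_reads


@dataclass
class DNMCandidate:
    """A DNM candidate: proband + site + trio evidence + derived covariates.

    ``n_possible_outside``/``n_likely_outside`` count carriers of the alt
    allele beyond the descendants of the proband's parent pair (the
    Trio-NPOSS covariate and its stricter companion).
    """

    proband_id: str
    site: VariantSite
    proband_ev: SiteEvidence
    father_ev: SiteEvidence
    mother_ev: SiteEvidence
    proband_ab: float
    n_possible_outside: int
    n_likely_outside: int
    gatk_pass: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.proband_ab <= 1.0:
            raise ValueError("allelic balance outside [0, 1]")
        if self.n_likely_outside > self.n_possible_outside:
            raise ValueError("likely carriers exceed possible carriers")

    @property
    def key(self) -> Tuple[str, str, int, str, str]:
        return (self.proband_id,) + self.site.key
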