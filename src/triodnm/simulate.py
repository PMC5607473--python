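"""Pedigree-sequencing simulator with known truth.

Generates everything the pipeline consumes: three-generation pedigrees with
MZ twin pairs, recombinant haplotypes on a toy genome, planted germline DNMs
with known parent of origin, artifact sites with skewed allelic balance and
8-oxoG orientation bias, per-site read evidence, read-pair linkage counts
against phased markers, IBD summaries, lane metrics, and a truth table.

The toy genome defaults to two 10 Mb autosomes at a uniform 1 cM/Mb with one
panel marker per 10 kb: large enough to contain the 0.8 cM / 200-marker IBD
segments the phasing rules require, small enough for seconds-scale runs.
Crossovers per meiosis are Poisson in map length with positions uniform in
cM (Haldane, no interference).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .datatypes import (
    HET,
    HOM_ALT,
    HOM_REF,
    SiteEvidence,
    SiteKey,
    VariantSite,
)
from .pedigree import (
    FEMALE,
    MALE,
    MATERNAL,
    PATERNAL,
    IbdSegment,
    IbdSummary,
    Individual,
    PedigreeGraph,
    build_pedigree,
)
from .phasing import InheritanceAssignment, ReadPairCount
from .sample_qc import LaneMetrics

BASES = "ACGT"


@dataclass
class SimConfig:
    """Study conditions of the simulated cohort.

    ``mean_coverage`` mirrors the 34x regime of the sequencing set the
    pipeline is designed for.  ``paternal_fraction`` (0.75) is a simulator
    default chosen to exercise phasing with an asymmetric parental origin,
    not an assertion about any cohort.  Artifact allelic balance follows a
    Beta with mean 0.2 and oxoG artifacts put 95% of their alt-supporting
    pairs in the damage-prone orientation; both are documented simulator
    choices.  Planted DNM and artifact loads per proband are set so the two
    classes contribute roughly equal numbers of extracted candidates.
    """

    n_families: int = 20
    offspring_min: int = 2
    offspring_max: int = 4
    n_twin_pairs: int = 2
    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"1": 10_000_000, "2": 10_000_000}
    )
    include_x: bool = False
    x_length: int = 10_000_000
    cm_per_mb: float = 1.0
    marker_spacing: int = 10_000
    mean_coverage: float = 34.0
    dnm_per_gamete: float = 8.0
    dnm_indel_fraction: float = 0.1
    dnm_gatk_pass_prob: float = 0.99
    paternal_fraction: float = 0.75
    artifacts_per_proband: float = 24.0
    artifact_ab_alpha: float = 4.0
    artifact_ab_beta: float = 16.0
    artifact_gatk_fail_prob: float = 0.3
    artifact_recurrence: float = 2.0  # Poisson mean of unrelated extra carriers
    oxog_fraction: float = 0.5
    oxog_skew: float = 0.95
    seq_error_rate: float = 0.002
    tracing_error_rate: float = 0.002
    traceable_fraction: float = 0.6
    read_pairs_per_link: float = 6.0
    post_twinning_fraction: float = 0.03
    multiallelic_fraction: float = 0.05
    softclip_mean: float = 0.03
    nfrac_mean: float = 0.006
    n_bad_probands: int = 0
    n_bad_lanes: int = 0
    n_swapped_samples: int = 0
    seed: int = 1

    def __post_init__(self) -> None:
        for name in (
            "paternal_fraction",
            "oxog_fraction",
            "oxog_skew",
            "seq_error_rate",
            "tracing_error_rate",
            "traceable_fraction",
            "post_twinning_fraction",
            "multiallelic_fraction",
            "dnm_indel_fraction",
            "dnm_gatk_pass_prob",
            "artifact_gatk_fail_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def all_chroms(self) -> Dict[str, int]:
        out = dict(self.chrom_lengths)
        if self.include_x:
            out["X"] = self.x_length
        return out


# -- truth ---------------------------------------------------------------------


@dataclass
class TruthDNM:
    proband_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    origin: str  # paternal | maternal
    post_twinning: bool


@dataclass
class TruthArtifact:
    individual_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    oxog: bool


@dataclass
class TruthTable:
    dnms: List[TruthDNM] = field(default_factory=list)
    artifacts: List[TruthArtifact] = field(default_factory=list)
    swapped_samples: List[str] = field(default_factory=list)
    bad_lanes: List[str] = field(default_factory=list)
    bad_probands: List[str] = field(default_factory=list)
    twin_pairs: List[Tuple[str, str]] = field(default_factory=list)  # (proband, twin)

    def dnm_keys(self) -> Set[Tuple[str, str, int]]:
        return {(d.proband_id, d.chrom, d.pos) for d in self.dnms}

    def artifact_keys(self) -> Set[Tuple[str, str, int]]:
        return {(a.individual_id, a.chrom, a.pos) for a in self.artifacts}


# -- haplotypes ----------------------------------------------------------------


class FounderHap:
    __slots__ = ("hid",)

    def __init__(self, hid: int):
        self.hid = hid


class MosaicHap:
    """A gamete: mosaic over the parent's two haplotypes.

    ``indicator(pos)`` is 0 where the gamete copies ``h0`` (the parent's
    paternal haplotype) and 1 where it copies ``h1``.
    """

    __slots__ = ("h0", "h1", "breaks", "start")

    def __init__(self, h0, h1, breaks: List[int], start: int):
        self.h0 = h0
        self.h1 = h1
        self.breaks = sorted(breaks)
        self.start = start

    def indicator(self, pos: int) -> int:
        return (self.start + bisect.bisect_right(self.breaks, pos)) % 2

    def segment_bounds(self, pos: int, chrom_len: int) -> Tuple[int, int]:
        i = bisect.bisect_right(self.breaks, pos)
        left = self.breaks[i - 1] if i > 0 else 0
        right = self.breaks[i] if i < len(self.breaks) else chrom_len
        return left, right


def founder_origin(hap, pos: int) -> int:
    while isinstance(hap, MosaicHap):
        hap = hap.h0 if hap.indicator(pos) == 0 else hap.h1
    return hap.hid


# -- simulator -----------------------------------------------------------------


class Simulator:
    """Stage-wise simulation: pedigree -> genomes -> evidence -> export."""

    def __init__(self, config: Optional[SimConfig] = None):
        self.cfg = config or SimConfig()
        self.rng = np.random.default_rng(self.cfg.seed)
        self.truth = TruthTable()
        self.graph: Optional[PedigreeGraph] = None
        self.records: List[Individual] = []
        self.family_members: Dict[str, Dict[str, object]] = {}
        self.genomes: Dict[str, Dict[str, Tuple[object, object]]] = {}
        self._next_hid = 0
        self._used_positions: Dict[str, Set[int]] = {}
        self._bad_proband_set: Set[str] = set()

    # -- stage 1: pedigree ----------------------------------------------------

    def simulate_pedigree(self) -> PedigreeGraph:
        cfg = self.cfg
        records: List[Individual] = []
        for i in range(cfg.n_families):
            fam = f"F{i:03d}"
            fa, mo = f"{fam}_fa", f"{fam}_mo"
            pb, sp = f"{fam}_pb", f"{fam}_sp"
            pb_sex = MALE if self.rng.random() < 0.5 else FEMALE
            sp_sex = FEMALE if pb_sex == MALE else MALE
            records.append(Individual(fa, MALE))
            records.append(Individual(mo, FEMALE))
            twin_group = f"{fam}_twg" if i < cfg.n_twin_pairs else None
            records.append(Individual(pb, pb_sex, father_id=fa, mother_id=mo, twin_group=twin_group))
            members = {"father": fa, "mother": mo, "proband": pb, "spouse": sp, "offspring": [], "twin": None}
            if twin_group is not None:
                tw = f"{fam}_tw"
                records.append(
                    Individual(tw, pb_sex, father_id=fa, mother_id=mo, twin_group=twin_group)
                )
                members["twin"] = tw
                self.truth.twin_pairs.append((pb, tw))
            records.append(Individual(sp, sp_sex))
            n_off = int(self.rng.integers(cfg.offspring_min, cfg.offspring_max + 1))
            off_father = pb if pb_sex == MALE else sp
            off_mother = pb if pb_sex == FEMALE else sp
            for j in range(n_off):
                off = f"{fam}_c{j}"
                off_sex = MALE if self.rng.random() < 0.5 else FEMALE
                records.append(
                    Individual(off, off_sex, father_id=off_father, mother_id=off_mother)
                )
                members["offspring"].append(off)
            self.family_members[fam] = members
        self.records = records
        self.graph = build_pedigree(records)
        return self.graph

    # -- stage 2: genomes -----------------------------------------------------

    def _new_founder_chrom(self, sex: str, chrom: str):
        if chrom == "X" and sex == MALE:
            hap = FounderHap(self._next_hid)
            self._next_hid += 1
            return (None, hap)
        h0, h1 = FounderHap(self._next_hid), FounderHap(self._next_hid + 1)
        self._next_hid += 2
        return (h0, h1)

    def _meiosis(self, parent_id: str, chrom: str, length: int):
        """One gamete from ``parent_id`` on ``chrom``."""
        parent_sex = self.graph.get(parent_id).sex
        h0, h1 = self.genomes[parent_id][chrom]
        if chrom == "X" and parent_sex == MALE:
            return h1  # father's single X passes unrecombined (to daughters)
        morgans = length * self.cfg.cm_per_mb / 1e6 / 100.0
        n_x = int(self.rng.poisson(morgans))
        breaks = sorted(int(p) for p in self.rng.integers(1, length, size=n_x))
        start = int(self.rng.integers(0, 2))
        return MosaicHap(h0, h1, breaks, start)

    def _make_genome_from_parents(self, ind: Individual) -> None:
        genome = {}
        for chrom, length in self.cfg.all_chroms.items():
            if chrom == "X" and ind.sex == MALE:
                genome[chrom] = (None, self._meiosis(ind.mother_id, chrom, length))
            else:
                genome[chrom] = (
                    self._meiosis(ind.father_id, chrom, length),
                    self._meiosis(ind.mother_id, chrom, length),
                )
        self.genomes[ind.id] = genome

    def simulate_genomes(self) -> TruthTable:
        if self.graph is None:
            self.simulate_pedigree()
        cfg = self.cfg
        for fam in sorted(self.family_members):
            members = self.family_members[fam]
            for founder in (members["father"], members["mother"], members["spouse"]):
                rec = self.graph.get(founder)
                self.genomes[founder] = {
                    chrom: self._new_founder_chrom(rec.sex, chrom)
                    for chrom in cfg.all_chroms
                }
            proband = self.graph.get(members["proband"])
            self._make_genome_from_parents(proband)
            if members["twin"] is not None:
                # MZ: the twin shares the proband's gamete mosaics exactly.
                self.genomes[members["twin"]] = self.genomes[proband.id]
            for off in members["offspring"]:
                self._make_genome_from_parents(self.graph.get(off))
        self._plant_dnms()
        self._plant_artifacts()
        return self.truth

    def _unique_position(self, chrom: str) -> int:
        used = self._used_positions.setdefault(chrom, set())
        length = self.cfg.all_chroms[chrom]
        while True:
            pos = int(self.rng.integers(1, length))
            if pos not in used and pos % self.cfg.marker_spacing != 0:
                used.add(pos)
                return pos

    def _choose_chrom(self, chroms: Sequence[str]) -> str:
        lengths = np.array([self.cfg.all_chroms[c] for c in chroms], dtype=float)
        return str(self.rng.choice(list(chroms), p=lengths / lengths.sum()))

    def _random_alleles(self, indel: bool, oxog: bool = False) -> Tuple[str, str]:
        if oxog:
            return ("C", "A") if self.rng.random() < 0.5 else ("G", "T")
        ref = BASES[int(self.rng.integers(0, 4))]
        if indel:
            if self.rng.random() < 0.5:
                return ref, ref + BASES[int(self.rng.integers(0, 4))]
            return ref + BASES[int(self.rng.integers(0, 4))], ref
        alt = ref
        while alt == ref:
            alt = BASES[int(self.rng.integers(0, 4))]
        return ref, alt

    def _plant_dnms(self) -> None:
        cfg = self.cfg
        for fam in sorted(self.family_members):
            members = self.family_members[fam]
            pb = members["proband"]
            pb_sex = self.graph.get(pb).sex
            has_twin = members["twin"] is not None
            n_dnms = int(self.rng.poisson(2.0 * cfg.dnm_per_gamete))
            for _ in range(n_dnms):
                origin = PATERNAL if self.rng.random() < cfg.paternal_fraction else MATERNAL
                chroms = list(cfg.chrom_lengths)
                if cfg.include_x and not (pb_sex == MALE and origin == PATERNAL):
                    # males carry no paternally derived X
                    chroms = chroms + ["X"]
                chrom = self._choose_chrom(chroms)
                if chrom == "X" and pb_sex == MALE:
                    origin = MATERNAL
                pos = self._unique_position(chrom)
                indel = self.rng.random() < cfg.dnm_indel_fraction
                ref, alt = self._random_alleles(indel)
                post_twinning = has_twin and self.rng.random() < cfg.post_twinning_fraction
                self.truth.dnms.append(
                    TruthDNM(pb, chrom, pos, ref, alt, origin, post_twinning)
                )

    def _plant_artifacts(self) -> None:
        cfg = self.cfg
        all_ids = [r.id for r in self.records]
        for fam in sorted(self.family_members):
            pb = self.family_members[fam]["proband"]
            n_art = int(self.rng.poisson(cfg.artifacts_per_proband))
            for _ in range(n_art):
                oxog = self.rng.random() < cfg.oxog_fraction
                chrom = self._choose_chrom(list(cfg.chrom_lengths))
                pos = self._unique_position(chrom)
                indel = (not oxog) and self.rng.random() < 0.05
                ref, alt = self._random_alleles(indel, oxog=oxog)
                self.truth.artifacts.append(TruthArtifact(pb, chrom, pos, ref, alt, oxog))
                n_extra = int(self.rng.poisson(cfg.artifact_recurrence))
                if n_extra:
                    outsiders = [i for i in all_ids if not i.startswith(fam)]
                    picks = self.rng.choice(outsiders, size=min(n_extra, len(outsiders)), replace=False)
                    for ind in picks:
                        self.truth.artifacts.append(
                            TruthArtifact(str(ind), chrom, pos, ref, alt, oxog)
                        )

    # -- stage 3: evidence ----------------------------------------------------

    def _site_depth(self, ind_id: str, chrom: str) -> int:
        cov = self.cfg.mean_coverage
        if chrom == "X" and self.graph.get(ind_id).sex == MALE:
            cov = cov / 2.0
        return int(self.rng.poisson(cov))

    def _frac_draws(self, ind_id: str) -> Tuple[float, float]:
        m_sc = 0.30 if ind_id in self._bad_proband_set else self.cfg.softclip_mean
        sc = float(self.rng.beta(2.0, 2.0 * (1 - m_sc) / m_sc))
        nf = float(self.rng.beta(2.0, 2.0 * (1 - self.cfg.nfrac_mean) / self.cfg.nfrac_mean))
        # 4-decimal precision matches the on-disk representation exactly
        return round(min(sc, 1.0), 4), round(min(nf, 1.0), 4)

    def _orientation_split(self, alt_reads: int, sub: Optional[str], oxog: bool) -> Tuple[int, int]:
        if alt_reads == 0:
            return 0, 0
        if oxog and sub in ("C>A", "G>T"):
            artifact_side = int(self.rng.binomial(alt_reads, self.cfg.oxog_skew))
            other = alt_reads - artifact_side
            return (other, artifact_side) if sub == "C>A" else (artifact_side, other)
        f1r2 = int(self.rng.binomial(alt_reads, 0.5))
        return f1r2, alt_reads - f1r2

    def _evidence(
        self,
        ind_id: str,
        site: Tuple[str, int, str, str],
        kind: str,
        ab: Optional[float] = None,
        oxog: bool = False,
    ) -> Optional[SiteEvidence]:
        """One individual's read summary at one site.

        ``kind``: true genotype — het, hom_ref, hom_alt, or artifact_het
        (miscalled het whose allelic balance follows the artifact
        distribution).
        """
        chrom, pos, ref, alt = site
        depth = self._site_depth(ind_id, chrom)
        if depth == 0:
            return None
        sub = f"{ref}>{alt}" if len(ref) == 1 and len(alt) == 1 else None
        err = self.cfg.seq_error_rate
        if kind == "hom_ref":
            alt_reads = int(self.rng.binomial(depth, err))
            genotype, gq = HOM_REF, 99.0
        elif kind == "hom_alt":
            ref_reads = int(self.rng.binomial(depth, err))
            alt_reads = depth - ref_reads
            genotype, gq = HOM_ALT, 99.0
        elif kind == "het":
            alt_reads = int(self.rng.binomial(depth, 0.5))
            genotype = HET
        elif kind == "artifact_het":
            alt_reads = int(self.rng.binomial(depth, ab))
            genotype = HET if alt_reads >= 2 else HOM_REF
        else:
            raise ValueError(kind)
        ref_reads = depth - alt_reads
        if genotype == HET:
            ab_obs = alt_reads / depth
            gq = max(1.0, round(99.0 * (1.0 - 2.0 * abs(ab_obs - 0.5))))
        elif kind == "artifact_het":
            gq = 99.0
        f1r2, f2r1 = self._orientation_split(alt_reads, sub, oxog)
        sc, nf = self._frac_draws(ind_id)
        return SiteEvidence(
            ref_reads=ref_reads,
            alt_reads=alt_reads,
            depth=depth,
            genotype=genotype,
            gq=gq,
            f1r2_alt=f1r2,
            f2r1_alt=f2r1,
            softclip_frac=sc,
            n_frac=nf,
        )

    def _hemizygous(self, ind_id: str, chrom: str) -> bool:
        return chrom == "X" and self.graph.get(ind_id).sex == MALE

    def simulate_evidence(self):
        """Build sites, evidence, linkage counts, lane metrics and IBD tables."""
        cfg = self.cfg
        self._mark_bad_probands()
        variants: List[VariantSite] = []
        evidence: Dict[SiteKey, Dict[str, SiteEvidence]] = {}
        inheritance: Dict[Tuple[str, str, int], InheritanceAssignment] = {}
        marker_phase: Dict[Tuple[str, str, int], int] = {}
        pair_counts: List[ReadPairCount] = []

        fam_of = {m: fam for fam, mm in self.family_members.items() for m in self._fam_ids(fam)}

        # recurrent artifacts grouped per site
        art_by_site: Dict[Tuple[str, int], List[TruthArtifact]] = {}
        for art in self.truth.artifacts:
            art_by_site.setdefault((art.chrom, art.pos), []).append(art)

        # -- germline DNM sites
        for dnm in self.truth.dnms:
            fam = fam_of[dnm.proband_id]
            members = self.family_members[fam]
            key = (dnm.chrom, dnm.pos, dnm.ref, dnm.alt)
            variants.append(self._make_variant(key, gatk_fail_prob=1.0 - cfg.dnm_gatk_pass_prob))
            site_ev: Dict[str, SiteEvidence] = {}
            pb = dnm.proband_id
            hemi = self._hemizygous(pb, dnm.chrom)
            self._add_ev(site_ev, pb, key, "hom_alt" if hemi else "het")
            for parent in (members["father"], members["mother"]):
                self._add_ev(site_ev, parent, key, "hom_ref")
            self._add_ev(site_ev, members["spouse"], key, "hom_ref")
            if members["twin"] is not None:
                tw = members["twin"]
                if dnm.post_twinning:
                    self._add_ev(site_ev, tw, key, "hom_ref")
                else:
                    self._add_ev(site_ev, tw, key, "hom_alt" if hemi else "het")
            for off in members["offspring"]:
                carrier = self._offspring_carries(off, pb, dnm)
                kind = "hom_ref"
                if carrier:
                    kind = "hom_alt" if self._hemizygous(off, dnm.chrom) else "het"
                self._add_ev(site_ev, off, key, kind)
                assign = self._inheritance_at(off, pb, dnm.chrom, dnm.pos)
                if assign is not None:
                    inheritance[(off, dnm.chrom, dnm.pos)] = assign
            evidence[key] = site_ev
            self._maybe_link_markers(
                pb, key, marker_phase, pair_counts, true_origin=dnm.origin
            )

        # -- artifact sites
        for (chrom, pos), arts in sorted(art_by_site.items()):
            first = arts[0]
            key = (chrom, pos, first.ref, first.alt)
            variants.append(
                self._make_variant(key, gatk_fail_prob=cfg.artifact_gatk_fail_prob)
            )
            site_ev = {}
            for art in arts:
                ab = float(self.rng.beta(cfg.artifact_ab_alpha, cfg.artifact_ab_beta))
                self._add_ev(site_ev, art.individual_id, key, "artifact_het", ab=ab, oxog=art.oxog)
            # the family of the *first* (originating) carrier gets full context
            fam = fam_of[first.individual_id]
            members = self.family_members[fam]
            for rel in ("father", "mother", "spouse"):
                if members[rel] not in site_ev:
                    self._add_ev(site_ev, members[rel], key, "hom_ref")
            if members["twin"] is not None and members["twin"] not in site_ev:
                self._add_ev(site_ev, members["twin"], key, "hom_ref")
            for off in members["offspring"]:
                if off not in site_ev:
                    self._add_ev(site_ev, off, key, "hom_ref")
                assign = self._inheritance_at(off, first.individual_id, chrom, pos)
                if assign is not None:
                    inheritance[(off, chrom, pos)] = assign
            evidence[key] = site_ev
            if self.rng.random() < cfg.traceable_fraction:
                self._maybe_link_markers(
                    first.individual_id, key, marker_phase, pair_counts, true_origin=None, force=True
                )

        lane_metrics = self._lane_metrics()
        ibd = self._ibd_summaries()
        variants.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
        return variants, evidence, inheritance, marker_phase, pair_counts, lane_metrics, ibd

    # -- evidence helpers -----------------------------------------------------

    def _fam_ids(self, fam: str) -> List[str]:
        m = self.family_members[fam]
        out = [m["father"], m["mother"], m["proband"], m["spouse"], *m["offspring"]]
        if m["twin"] is not None:
            out.append(m["twin"])
        return out

    def _mark_bad_probands(self) -> None:
        fams = sorted(self.family_members)
        # bad probands drawn from non-twin families so twin checks stay intact
        candidates = [self.family_members[f]["proband"] for f in fams if self.family_members[f]["twin"] is None]
        self.truth.bad_probands = candidates[: self.cfg.n_bad_probands]
        self._bad_proband_set = set(self.truth.bad_probands)

    def _make_variant(self, key: SiteKey, gatk_fail_prob: float) -> VariantSite:
        chrom, pos, ref, alt = key
        return VariantSite(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            gatk_pass=bool(self.rng.random() >= gatk_fail_prob),
            biallelic=bool(self.rng.random() >= self.cfg.multiallelic_fraction),
            imputation_info=round(float(self.rng.beta(8.0, 2.0)), 4),
            phase_score=round(float(self.rng.beta(8.0, 2.0)), 4),
        )

    def _add_ev(self, site_ev, ind_id, key, kind, ab=None, oxog=False) -> None:
        ev = self._evidence(ind_id, key, kind, ab=ab, oxog=oxog)
        if ev is not None:
            site_ev[ind_id] = ev

    def _offspring_carries(self, off_id: str, pb_id: str, dnm: TruthDNM) -> bool:
        rec = self.graph.get(off_id)
        pb_sex = self.graph.get(pb_id).sex
        genome = self.genomes[off_id]
        if dnm.chrom not in genome:
            return False
        from_pb = genome[dnm.chrom][0 if pb_sex == MALE else 1]
        if dnm.chrom == "X":
            if rec.sex == MALE:
                from_pb = genome["X"][1] if pb_sex == FEMALE else None
                if from_pb is None:
                    return False
            elif pb_sex == MALE:
                # daughter gets father's single X unrecombined: always carries
                return True
        if not isinstance(from_pb, MosaicHap):
            return False
        side = from_pb.indicator(dnm.pos)  # 0 -> proband's paternal haplotype
        return (side == 0) == (dnm.origin == PATERNAL)

    def _inheritance_at(
        self, off_id: str, pb_id: str, chrom: str, pos: int
    ) -> Optional[InheritanceAssignment]:
        pb_sex = self.graph.get(pb_id).sex
        genome = self.genomes[off_id]
        if chrom not in genome:
            return None
        from_pb = genome[chrom][0 if pb_sex == MALE else 1]
        if chrom == "X":
            if pb_sex == MALE:
                return None  # father's X passes unrecombined; no two-haplotype signal
            if self.graph.get(off_id).sex == MALE:
                from_pb = genome["X"][1]
        if not isinstance(from_pb, MosaicHap):
            return None
        side = from_pb.indicator(pos)
        left, right = from_pb.segment_bounds(pos, self.cfg.all_chroms[chrom])
        seg_cm = (right - left) * self.cfg.cm_per_mb / 1e6
        spacing = self.cfg.marker_spacing
        n_markers = right // spacing - left // spacing
        return InheritanceAssignment(
            haplotype=PATERNAL if side == 0 else MATERNAL,
            segment_cm=round(seg_cm, 4),
            segment_markers=int(n_markers),
        )

    def _maybe_link_markers(
        self,
        pb_id: str,
        key: SiteKey,
        marker_phase: Dict[Tuple[str, str, int], int],
        pair_counts: List[ReadPairCount],
        true_origin: Optional[str],
        force: bool = False,
    ) -> None:
        """With probability ``traceable_fraction``, place a phased het marker
        within read-pair range of the site and emit linkage counts.

        ``true_origin`` None (artifact) links alt pairs to either marker
        allele at random — the mixed support leaves the site unphased."""
        cfg = self.cfg
        if not force and self.rng.random() >= cfg.traceable_fraction:
            return
        chrom, pos, _, _ = key
        if self._hemizygous(pb_id, chrom):
            return  # no het marker on a hemizygous chromosome
        delta = int(self.rng.integers(100, 900))  # inside default read-pair range
        mpos = pos + delta if self.rng.random() < 0.5 else pos - delta
        mpos = min(max(1, mpos), self.cfg.all_chroms[chrom] - 1)
        used = self._used_positions.setdefault(chrom, set())
        while mpos in used:
            mpos += 1
        used.add(mpos)
        paternal_allele = 1 if self.rng.random() < 0.5 else 2
        marker_phase[(pb_id, chrom, mpos)] = paternal_allele
        n_pairs = int(self.rng.poisson(cfg.read_pairs_per_link))
        counts = {"ra1": 0, "ra2": 0, "aa1": 0, "aa2": 0}
        dnm_on_paternal = true_origin == PATERNAL
        for _ in range(n_pairs):
            has_alt = self.rng.random() < 0.5
            if true_origin is None:
                allele_is_paternal = self.rng.random() < 0.5
            else:
                allele_is_paternal = dnm_on_paternal if has_alt else not dnm_on_paternal
            if self.rng.random() < cfg.tracing_error_rate:
                allele_is_paternal = not allele_is_paternal
            allele = paternal_allele if allele_is_paternal else 3 - paternal_allele
            counts[("aa" if has_alt else "ra") + str(allele)] += 1
        pair_counts.append(
            ReadPairCount(
                proband_id=pb_id,
                dnm_chrom=chrom,
                dnm_pos=pos,
                marker_chrom=chrom,
                marker_pos=int(mpos),
                n_ref_a1=counts["ra1"],
                n_ref_a2=counts["ra2"],
                n_alt_a1=counts["aa1"],
                n_alt_a2=counts["aa2"],
                n_multi=int(self.rng.poisson(0.05)),
            )
        )

    def _lane_metrics(self) -> List[LaneMetrics]:
        out = []
        all_ids = sorted(self.genomes)
        bad = set()
        if self.cfg.n_bad_lanes:
            # fail lanes of non-proband founders so the pedigree stays usable
            spouses = [self.family_members[f]["spouse"] for f in sorted(self.family_members)]
            bad = set(spouses[: self.cfg.n_bad_lanes])
            self.truth.bad_lanes = [f"{s}_L1" for s in sorted(bad)]
        for ind in all_ids:
            r = self.rng
            m = LaneMetrics(
                lane_id=f"{ind}_L1",
                sample_id=ind,
                mean_base_quality=float(np.round(r.normal(35, 1.0), 3)),
                pct_duplicates=float(np.round(r.uniform(5, 20), 3)),
                mean_n_per_read=float(np.round(r.uniform(1, 5), 3)),
                pct_mapq_lt20=float(np.round(r.uniform(1, 8), 3)),
                pct_unmapped=float(np.round(r.uniform(0.5, 3), 3)),
                pct_both_unmapped=float(np.round(r.uniform(0.1, 2), 3)),
                pct_first_unmapped=float(np.round(r.uniform(0.2, 2.5), 3)),
                pct_second_unmapped=float(np.round(r.uniform(0.2, 2.5), 3)),
                chip_mismatch_rate=float(np.round(r.uniform(0.0005, 0.005), 6)),
            )
            if ind in bad:
                m.mean_base_quality = float(np.round(r.uniform(20, 24.5), 3))
            out.append(m)
        return out

    def _ibd_summaries(self) -> List[IbdSummary]:
        cfg = self.cfg
        swapped = set()
        if cfg.n_swapped_samples:
            offspring = [
                o
                for f in sorted(self.family_members)
                for o in self.family_members[f]["offspring"]
            ]
            swapped = set(offspring[: cfg.n_swapped_samples])
            self.truth.swapped_samples = sorted(swapped)
        out = []
        total_cm = sum(L * cfg.cm_per_mb / 1e6 for L in cfg.chrom_lengths.values())
        for rec in self.graph.individuals():
            for parent_id, hap in ((rec.father_id, PATERNAL), (rec.mother_id, MATERNAL)):
                if parent_id is None or parent_id not in self.graph:
                    continue
                pair = (parent_id, rec.id)
                if rec.id in swapped or parent_id in swapped:
                    frac = float(self.rng.uniform(0.0, 0.05))
                    out.append(IbdSummary(pair, frac, []))
                    continue
                segments = [
                    IbdSegment(
                        chrom=c,
                        start_cm=0.0,
                        end_cm=L * cfg.cm_per_mb / 1e6,
                        n_markers=L // cfg.marker_spacing,
                        proband_haplotype=hap,
                    )
                    for c, L in sorted(cfg.chrom_lengths.items())
                ]
                shared = sum(s.length_cm for s in segments) / total_cm
                out.append(IbdSummary(pair, min(shared, 1.0), segments))
        return out

    # -- assembly -------------------------------------------------------------

    def run(self):
        """Full simulation; returns a :class:`SimResult`."""
        self.simulate_pedigree()
        self.simulate_genomes()
        (
            variants,
            evidence,
            inheritance,
            marker_phase,
            pair_counts,
            lane_metrics,
            ibd,
        ) = self.simulate_evidence()
        genetic_map = {
            chrom: [(1, 0.0), (L, L * self.cfg.cm_per_mb / 1e6)]
            for chrom, L in sorted(self.cfg.all_chroms.items())
        }
        return SimResult(
            config=self.cfg,
            records=self.records,
            graph=self.graph,
            variants=variants,
            evidence_by_site=evidence,
            inheritance=inheritance,
            marker_phase=marker_phase,
            pair_counts=pair_counts,
            lane_metrics=lane_metrics,
            ibd=ibd,
            genetic_map=genetic_map,
            truth=self.truth,
        )


@dataclass
class SimResult:
    """Everything the simulator produced, plus the truth table."""

    config: SimConfig
    records: List[Individual]
    graph: PedigreeGraph
    variants: List[VariantSite]
    evidence_by_site: Dict[SiteKey, Dict[str, SiteEvidence]]
    inheritance: Dict[Tuple[str, str, int], InheritanceAssignment]
    marker_phase: Dict[Tuple[str, str, int], int]
    pair_counts: List[ReadPairCount]
    lane_metrics: List[LaneMetrics]
    ibd: List[IbdSummary]
    genetic_map: Dict[str, List[Tuple[int, float]]]
    truth: TruthTable

    def to_dataset(self):
        from .io import Dataset

        return Dataset(
            variants=list(self.variants),
            evidence_by_site={k: dict(v) for k, v in self.evidence_by_site.items()},
            pedigree=self.graph,
            genetic_map=self.genetic_map,
            marker_phase=dict(self.marker_phase),
            pair_counts=list(self.pair_counts),
            lane_metrics=list(self.lane_metrics),
            inheritance=dict(self.inheritance),
            ibd=list(self.ibd),
        )

    def export(self, out_dir) -> None:
        from . import io as tio

        tio.export_simulation(self, out_dir)

    def classify_candidate(self, proband_id: str, chrom: str, pos: int) -> Optional[str]:
        """Truth class of a (proband, site) candidate: 'dnm', 'artifact' or None.

        An MZ twin's candidate at the co-twin's germline DNM site counts as
        a true DNM (the twins share the pre-twinning germline)."""
        if not hasattr(self, "_truth_cache"):
            twin_map: Dict[str, str] = {}
            for p, t in self.truth.twin_pairs:
                twin_map[p] = t
                twin_map[t] = p
            self._truth_cache = (
                self.truth.dnm_keys(),
                self.truth.artifact_keys(),
                twin_map,
            )
        dnm_keys, art_keys, twin_map = self._truth_cache
        if (proband_id, chrom, pos) in dnm_keys:
            return "dnm"
        partner = twin_map.get(proband_id)
        if partner is not None and (partner, chrom, pos) in dnm_keys:
            return "dnm"
        if (proband_id, chrom, pos) in art_keys:
            return "artifact"
        return None


def simulate(config: Optional[SimConfig] = None) -> SimResult:
    """One-call simulation with a fresh RNG seeded from the config."""
    return Simulator(config).run()


# -- small stand-alone generators used by the QC tests -------------------------


def simulate_dosages(
    p: float, attenuation: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Imputed dosages d = p + a (theta - p) for theta ~ Bernoulli(p).

    At attenuation 1 the dosages recover the alleles exactly (info 1); at 0
    they carry only the frequency (info 0); in between info converges to a^2.
    """
    theta = rng.random(n) < p
    return np.clip(p + attenuation * (theta.astype(float) - p), 0.0, 1.0)


def simulate_chip_pileups(
    n_sites: int,
    depth: int,
    error_rate: float,
    rng: np.random.Generator,
) -> Tuple[List[Dict[str, int]], List[str]]:
    """Homozygous chip sites with sequencing error for mismatch-rate checks."""
    pileups, genotypes = [], []
    for _ in range(n_sites):
        allele = BASES[int(rng.integers(0, 4))]
        n_err = int(rng.binomial(depth, error_rate))
        counts = {allele: depth - n_err}
        if n_err:
            other = allele
            while other == allele:
                other = BASES[int(rng.integers(0, 4))]
            counts[other] = n_err
        pileups.append(counts)
        genotypes.append(allele)
    return pileups, genotypes
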