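"""File formats: multi-sample VCF, PED(+twin), map/marker/count tables.

The VCF dialect is v4.2 with per-sample FORMAT fields GT, AD (ref,alt), DP,
GQ plus custom F1R2/F2R1 (orientation-stratified alt read-pair counts), SCF
(mean soft-clipped fraction) and NF (mean N fraction).  The pedigree file is
6-column PED extended with a 7th twin-group column (0 = none).  Everything
else is plain TSV.  Fractional values are carried at 4 decimal places so a
write/load round trip reproduces evidence exactly.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import pysam

from .config import RunConfig
from .datatypes import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    SiteEvidence,
    SiteKey,
    VariantSite,
)
from .pedigree import (
    FEMALE,
    MALE,
    UNKNOWN,
    IbdSegment,
    IbdSummary,
    Individual,
    PedigreeGraph,
    build_pedigree,
)
from .phasing import InheritanceAssignment, PhaseCall, ReadPairCount
from .sample_qc import LaneMetrics

FILE_NAMES = {
    "vcf": "variants.vcf",
    "ped": "pedigree.ped",
    "map": "genetic_map.tsv",
    "marker_phase": "marker_phase.tsv",
    "pair_counts": "pair_counts.tsv",
    "lane_metrics": "lane_metrics.tsv",
    "inheritance": "inheritance.tsv",
    "ibd": "ibd_segments.tsv",
}

FRAC_DECIMALS = 4


class DatasetConsistencyError(ValueError):
    """Cross-file identifier or ordering constraint violated."""


@dataclass
class Dataset:
    """All pipeline inputs, cross-referenced.

    Every individual appearing in the evidence must exist in the pedigree;
    genetic-map positions must be strictly increasing in bp and
    non-decreasing in cM per chromosome.
    """

    variants: List[VariantSite]
    evidence_by_site: Dict[SiteKey, Dict[str, SiteEvidence]]
    pedigree: PedigreeGraph
    genetic_map: Dict[str, List[Tuple[int, float]]] = field(default_factory=dict)
    marker_phase: Dict[Tuple[str, str, int], int] = field(default_factory=dict)
    pair_counts: List[ReadPairCount] = field(default_factory=list)
    lane_metrics: List[LaneMetrics] = field(default_factory=list)
    inheritance: Dict[Tuple[str, str, int], InheritanceAssignment] = field(
        default_factory=dict
    )
    ibd: List[IbdSummary] = field(default_factory=list)

    def __post_init__(self) -> None:
        for site_key, per_ind in self.evidence_by_site.items():
            for ind in per_ind:
                if ind not in self.pedigree:
                    raise DatasetConsistencyError(
                        f"individual {ind!r} in evidence at {site_key} absent from pedigree"
                    )
        for chrom, points in self.genetic_map.items():
            for (p0, c0), (p1, c1) in zip(points, points[1:]):
                if p1 <= p0:
                    raise DatasetConsistencyError(
                        f"map positions not strictly increasing on {chrom}"
                    )
                if c1 < c0:
                    raise DatasetConsistencyError(f"map cM decreasing on {chrom}")
        self.variant_index: Dict[SiteKey, VariantSite] = {
            v.key: v for v in self.variants
        }
        self.evidence_by_individual: Dict[str, Dict[SiteKey, SiteEvidence]] = {}
        for site_key, per_ind in self.evidence_by_site.items():
            for ind, ev in per_ind.items():
                self.evidence_by_individual.setdefault(ind, {})[site_key] = ev

    def interpolate_cm(self, chrom: str, pos: int) -> float:
        points = self.genetic_map.get(chrom)
        if not points:
            raise KeyError(f"no genetic map for chromosome {chrom!r}")
        xs = [p for p, _ in points]
        ys = [c for _, c in points]
        return float(np.interp(pos, xs, ys))


# -- VCF -----------------------------------------------------------------------

_GT_CODES = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1)}


def _vcf_header(samples: List[str], contigs: Dict[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.filters.add("gatk_fail", None, None, "Fails GATK recommended filters")
    header.info.add("IMPINFO", 1, "Float", "Imputation information (variance ratio)")
    header.info.add("PHASEQ", 1, "Float", "Phasing quality score")
    header.info.add("MULTI", 0, "Flag", "Record derived from a multi-allelic site")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Read depth per allele (ref,alt)")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.formats.add("F1R2", 1, "Integer", "Alt-supporting F1R2 read pairs")
    header.formats.add("F2R1", 1, "Integer", "Alt-supporting F2R1 read pairs")
    header.formats.add("SCF", 1, "Float", "Mean soft-clipped fraction of covering reads")
    header.formats.add("NF", 1, "Float", "Mean N fraction of covering reads")
    for s in samples:
        header.add_sample(s)
    return header


def write_vcf(
    path,
    variants: List[VariantSite],
    evidence_by_site: Dict[SiteKey, Dict[str, SiteEvidence]],
    samples: List[str],
    contigs: Dict[str, int],
) -> None:
    header = _vcf_header(samples, contigs)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for site in variants:
            rec = vcf.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                stop=site.pos - 1 + len(site.ref),
                alleles=(site.ref, site.alt),
            )
            rec.filter.add("PASS" if site.gatk_pass else "gatk_fail")
            if site.imputation_info is not None:
                rec.info["IMPINFO"] = round(site.imputation_info, FRAC_DECIMALS)
            if site.phase_score is not None:
                rec.info["PHASEQ"] = round(site.phase_score, FRAC_DECIMALS)
            if not site.biallelic:
                rec.info["MULTI"] = True
            per_ind = evidence_by_site.get(site.key, {})
            for sample in samples:
                ev = per_ind.get(sample)
                if ev is None or ev.genotype == MISSING:
                    rec.samples[sample]["GT"] = (None, None)
                    continue
                rs = rec.samples[sample]
                rs["GT"] = _GT_CODES[ev.genotype]
                rs["AD"] = (ev.ref_reads, ev.alt_reads)
                rs["DP"] = ev.depth
                rs["GQ"] = int(round(ev.gq))
                rs["F1R2"] = ev.f1r2_alt
                rs["F2R1"] = ev.f2r1_alt
                rs["SCF"] = round(ev.softclip_frac, FRAC_DECIMALS)
                rs["NF"] = round(ev.n_frac, FRAC_DECIMALS)
            vcf.write(rec)


def read_vcf(path) -> Tuple[List[VariantSite], Dict[SiteKey, Dict[str, SiteEvidence]], List[str]]:
    variants: List[VariantSite] = []
    evidence: Dict[SiteKey, Dict[str, SiteEvidence]] = {}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for line_no, rec in enumerate(vcf, start=1):
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"{path}: record {rec.chrom}:{rec.pos} is not biallelic "
                    "(multi-allelic sites must be dichotomized upstream)"
                )
            gatk_pass = "gatk_fail" not in rec.filter
            site = VariantSite(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=rec.alts[0],
                gatk_pass=gatk_pass,
                biallelic="MULTI" not in rec.info,
                imputation_info=_round_opt(rec.info.get("IMPINFO")),
                phase_score=_round_opt(rec.info.get("PHASEQ")),
            )
            variants.append(site)
            per_ind: Dict[str, SiteEvidence] = {}
            for sample in samples:
                rs = rec.samples[sample]
                gt = rs.get("GT")
                if gt is None or all(a is None for a in gt):
                    continue
                n_alt = sum(1 for a in gt if a == 1)
                genotype = (HOM_REF, HET, HOM_ALT)[n_alt]
                ad = rs.get("AD") or (0, 0)
                per_ind[sample] = SiteEvidence(
                    ref_reads=int(ad[0]),
                    alt_reads=int(ad[1]),
                    depth=int(rs.get("DP") or 0),
                    genotype=genotype,
                    gq=float(rs.get("GQ") or 0),
                    f1r2_alt=int(rs.get("F1R2") or 0),
                    f2r1_alt=int(rs.get("F2R1") or 0),
                    softclip_frac=_round_frac(rs.get("SCF")),
                    n_frac=_round_frac(rs.get("NF")),
                )
            evidence[site.key] = per_ind
    return variants, evidence, samples


def _round_frac(v) -> float:
    return 0.0 if v is None else round(float(v), FRAC_DECIMALS)


def _round_opt(v) -> Optional[float]:
    return None if v is None else round(float(v), FRAC_DECIMALS)


# -- PED -----------------------------------------------------------------------

_SEX_TO_PED = {MALE: "1", FEMALE: "2", UNKNOWN: "0"}
_PED_TO_SEX = {"1": MALE, "2": FEMALE, "0": UNKNOWN}


def write_ped(path, records: List[Individual]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fid = rec.id.split("_")[0]
            fh.write(
                "\t".join(
                    [
                        fid,
                        rec.id,
                        rec.father_id or "0",
                        rec.mother_id or "0",
                        _SEX_TO_PED[rec.sex],
                        "0",
                        rec.twin_group or "0",
                    ]
                )
                + "\n"
            )


def read_ped(path) -> List[Individual]:
    records = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"{path}:{line_no}: expected >=6 PED columns")
            _, iid, fat, mot, sex, _pheno, *rest = fields
            twin = rest[0] if rest else "0"
            records.append(
                Individual(
                    id=iid,
                    sex=_PED_TO_SEX.get(sex, UNKNOWN),
                    father_id=None if fat == "0" else fat,
                    mother_id=None if mot == "0" else mot,
                    twin_group=None if twin == "0" else twin,
                )
            )
    return records


# -- TSV tables ----------------------------------------------------------------


def write_genetic_map(path, genetic_map: Dict[str, List[Tuple[int, float]]]) -> None:
    rows = [
        {"chrom": chrom, "pos": pos, "cm": cm}
        for chrom in sorted(genetic_map)
        for pos, cm in genetic_map[chrom]
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "cm"]).to_csv(path, sep="\t", index=False)


def read_genetic_map(path) -> Dict[str, List[Tuple[int, float]]]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out: Dict[str, List[Tuple[int, float]]] = {}
    for row in df.itertuples():
        out.setdefault(row.chrom, []).append((int(row.pos), float(row.cm)))
    return out


def write_marker_phase(path, marker_phase: Dict[Tuple[str, str, int], int]) -> None:
    rows = [
        {"proband": pid, "chrom": chrom, "pos": pos, "paternal_allele": allele}
        for (pid, chrom, pos), allele in sorted(marker_phase.items())
    ]
    pd.DataFrame(
        rows, columns=["proband", "chrom", "pos", "paternal_allele"]
    ).to_csv(path, sep="\t", index=False)


def read_marker_phase(path) -> Dict[Tuple[str, str, int], int]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {
        (row.proband, row.chrom, int(row.pos)): int(row.paternal_allele)
        for row in df.itertuples()
    }


_PAIR_COLS = [
    "proband",
    "dnm_chrom",
    "dnm_pos",
    "marker_chrom",
    "marker_pos",
    "n_ref_a1",
    "n_ref_a2",
    "n_alt_a1",
    "n_alt_a2",
    "n_multi",
]


def write_pair_counts(path, counts: List[ReadPairCount]) -> None:
    rows = [
        {
            "proband": c.proband_id,
            "dnm_chrom": c.dnm_chrom,
            "dnm_pos": c.dnm_pos,
            "marker_chrom": c.marker_chrom,
            "marker_pos": c.marker_pos,
            "n_ref_a1": c.n_ref_a1,
            "n_ref_a2": c.n_ref_a2,
            "n_alt_a1": c.n_alt_a1,
            "n_alt_a2": c.n_alt_a2,
            "n_multi": c.n_multi,
        }
        for c in counts
    ]
    pd.DataFrame(rows, columns=_PAIR_COLS).to_csv(path, sep="\t", index=False)


def read_pair_counts(path) -> List[ReadPairCount]:
    df = pd.read_csv(path, sep="\t", dtype={"dnm_chrom": str, "marker_chrom": str})
    return [
        ReadPairCount(
            proband_id=row.proband,
            dnm_chrom=row.dnm_chrom,
            dnm_pos=int(row.dnm_pos),
            marker_chrom=row.marker_chrom,
            marker_pos=int(row.marker_pos),
            n_ref_a1=int(row.n_ref_a1),
            n_ref_a2=int(row.n_ref_a2),
            n_alt_a1=int(row.n_alt_a1),
            n_alt_a2=int(row.n_alt_a2),
            n_multi=int(row.n_multi),
        )
        for row in df.itertuples()
    ]


_LANE_COLS = [
    "lane_id",
    "sample_id",
    "mean_base_quality",
    "pct_duplicates",
    "mean_n_per_read",
    "pct_mapq_lt20",
    "pct_unmapped",
    "pct_both_unmapped",
    "pct_first_unmapped",
    "pct_second_unmapped",
    "chip_mismatch_rate",
]


def write_lane_metrics(path, metrics: List[LaneMetrics]) -> None:
    rows = [{c: getattr(m, c) for c in _LANE_COLS} for m in metrics]
    pd.DataFrame(rows, columns=_LANE_COLS).to_csv(path, sep="\t", index=False)


def read_lane_metrics(path) -> List[LaneMetrics]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples():
        kwargs = {c: getattr(row, c) for c in _LANE_COLS}
        kwargs["lane_id"] = str(kwargs["lane_id"])
        kwargs["sample_id"] = str(kwargs["sample_id"])
        out.append(LaneMetrics(**kwargs))
    return out


def write_inheritance(
    path, inheritance: Dict[Tuple[str, str, int], InheritanceAssignment]
) -> None:
    rows = [
        {
            "offspring": off,
            "chrom": chrom,
            "pos": pos,
            "haplotype": a.haplotype,
            "segment_cm": round(a.segment_cm, FRAC_DECIMALS),
            "segment_markers": a.segment_markers,
        }
        for (off, chrom, pos), a in sorted(inheritance.items())
    ]
    pd.DataFrame(
        rows,
        columns=["offspring", "chrom", "pos", "haplotype", "segment_cm", "segment_markers"],
    ).to_csv(path, sep="\t", index=False)


def read_inheritance(path) -> Dict[Tuple[str, str, int], InheritanceAssignment]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {
        (row.offspring, row.chrom, int(row.pos)): InheritanceAssignment(
            haplotype=row.haplotype,
            segment_cm=float(row.segment_cm),
            segment_markers=int(row.segment_markers),
        )
        for row in df.itertuples()
    }


def write_ibd(path, summaries: List[IbdSummary]) -> None:
    rows = []
    for s in summaries:
        for seg in s.segments:
            rows.append(
                {
                    "id1": s.pair[0],
                    "id2": s.pair[1],
                    "chrom": seg.chrom,
                    "start_cm": seg.start_cm,
                    "end_cm": seg.end_cm,
                    "n_markers": seg.n_markers,
                    "haplotype": seg.proband_haplotype,
                }
            )
    pd.DataFrame(
        rows,
        columns=["id1", "id2", "chrom", "start_cm", "end_cm", "n_markers", "haplotype"],
    ).to_csv(path, sep="\t", index=False)


def read_ibd(
    path, graph: PedigreeGraph, genetic_map: Dict[str, List[Tuple[int, float]]]
) -> List[IbdSummary]:
    """Segment rows -> per-pair summaries; parent-child pairs with no
    segments get shared_fraction 0 (e.g. sample swaps)."""
    total_cm = sum(points[-1][1] - points[0][1] for points in genetic_map.values())
    by_pair: Dict[Tuple[str, str], List[IbdSegment]] = {}
    if os.path.getsize(path) > 0:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        for row in df.itertuples():
            seg = IbdSegment(
                chrom=row.chrom,
                start_cm=float(row.start_cm),
                end_cm=float(row.end_cm),
                n_markers=int(row.n_markers),
                proband_haplotype=row.haplotype,
            )
            by_pair.setdefault((row.id1, row.id2), []).append(seg)
    out = []
    seen = set()
    for pair, segs in sorted(by_pair.items()):
        shared = sum(s.length_cm for s in segs) / total_cm if total_cm else 0.0
        out.append(IbdSummary(pair, min(shared, 1.0), segs))
        seen.add(pair)
    for rec in graph.individuals():
        for parent in (rec.father_id, rec.mother_id):
            if parent is None or parent not in graph:
                continue
            pair = (parent, rec.id)
            if pair not in seen:
                out.append(IbdSummary(pair, 0.0, []))
    return out


# -- dataset assembly ----------------------------------------------------------


def load_dataset(in_dir, config: Optional[RunConfig] = None) -> Dataset:
    """Load a full dataset from a directory of standard-named files.

    Optional tables (marker phase, pair counts, lane metrics, inheritance,
    IBD) may be absent and default to empty.
    """
    in_dir = Path(in_dir)
    vcf_path = in_dir / FILE_NAMES["vcf"]
    ped_path = in_dir / FILE_NAMES["ped"]
    for p in (vcf_path, ped_path):
        if not p.exists():
            raise FileNotFoundError(p)
    records = read_ped(ped_path)
    graph = build_pedigree(records)
    variants, evidence, samples = read_vcf(vcf_path)
    unknown = [s for s in samples if s not in graph]
    if unknown:
        raise DatasetConsistencyError(
            f"VCF samples absent from pedigree: {sorted(unknown)}"
        )
    genetic_map = {}
    if (in_dir / FILE_NAMES["map"]).exists():
        genetic_map = read_genetic_map(in_dir / FILE_NAMES["map"])
    marker_phase = {}
    if (in_dir / FILE_NAMES["marker_phase"]).exists():
        marker_phase = read_marker_phase(in_dir / FILE_NAMES["marker_phase"])
    pair_counts = []
    if (in_dir / FILE_NAMES["pair_counts"]).exists():
        pair_counts = read_pair_counts(in_dir / FILE_NAMES["pair_counts"])
    lane_metrics = []
    if (in_dir / FILE_NAMES["lane_metrics"]).exists():
        lane_metrics = read_lane_metrics(in_dir / FILE_NAMES["lane_metrics"])
    inheritance = {}
    if (in_dir / FILE_NAMES["inheritance"]).exists():
        inheritance = read_inheritance(in_dir / FILE_NAMES["inheritance"])
    ibd = []
    if (in_dir / FILE_NAMES["ibd"]).exists():
        ibd = read_ibd(in_dir / FILE_NAMES["ibd"], graph, genetic_map)
    return Dataset(
        variants=variants,
        evidence_by_site=evidence,
        pedigree=graph,
        genetic_map=genetic_map,
        marker_phase=marker_phase,
        pair_counts=pair_counts,
        lane_metrics=lane_metrics,
        inheritance=inheritance,
        ibd=ibd,
    )


def export_simulation(sim_result, out_dir) -> None:
    """Write a simulated dataset plus truth tables to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    contigs = {
        chrom: points[-1][0] for chrom, points in sorted(sim_result.genetic_map.items())
    }
    samples = sorted(sim_result.graph._individuals)
    write_vcf(
        out / FILE_NAMES["vcf"],
        sim_result.variants,
        sim_result.evidence_by_site,
        samples,
        contigs,
    )
    write_ped(out / FILE_NAMES["ped"], sim_result.records)
    write_genetic_map(out / FILE_NAMES["map"], sim_result.genetic_map)
    write_marker_phase(out / FILE_NAMES["marker_phase"], sim_result.marker_phase)
    write_pair_counts(out / FILE_NAMES["pair_counts"], sim_result.pair_counts)
    write_lane_metrics(out / FILE_NAMES["lane_metrics"], sim_result.lane_metrics)
    write_inheritance(out / FILE_NAMES["inheritance"], sim_result.inheritance)
    write_ibd(out / FILE_NAMES["ibd"], sim_result.ibd)
    truth = sim_result.truth
    pd.DataFrame(
        [
            {
                "proband": d.proband_id,
                "chrom": d.chrom,
                "pos": d.pos,
                "ref": d.ref,
                "alt": d.alt,
                "origin": d.origin,
                "post_twinning": int(d.post_twinning),
            }
            for d in truth.dnms
        ],
        columns=["proband", "chrom", "pos", "ref", "alt", "origin", "post_twinning"],
    ).to_csv(out / "truth_dnms.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "individual": a.individual_id,
                "chrom": a.chrom,
                "pos": a.pos,
                "ref": a.ref,
                "alt": a.alt,
                "oxog": int(a.oxog),
            }
            for a in truth.artifacts
        ],
        columns=["individual", "chrom", "pos", "ref", "alt", "oxog"],
    ).to_csv(out / "truth_artifacts.tsv", sep="\t", index=False)
    with open(out / "truth_meta.json", "w") as fh:
        json.dump(
            {
                "swapped_samples": truth.swapped_samples,
                "bad_lanes": truth.bad_lanes,
                "bad_probands": truth.bad_probands,
                "twin_pairs": truth.twin_pairs,
            },
            fh,
            indent=2,
        )
    import dataclasses

    import yaml

    with open(out / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(sim_result.config), fh, sort_keys=True)


# -- result output -------------------------------------------------------------


def write_results(
    out_dir,
    scores: pd.DataFrame,
    consensus_calls: List[PhaseCall],
    dataset: Dataset,
    config: RunConfig,
    summaries: Dict[str, pd.DataFrame],
) -> None:
    """Write the high-quality DNM VCF, summary TSVs and a provenance block.

    The DNM VCF carries one record per (proband, site) with INFO tags for
    the classifier response, the consensus parent of origin and the phasing
    method; given identical inputs and config the outputs are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_key = {c.candidate_key: c for c in consensus_calls}

    header = pysam.VariantHeader()
    contigs = {
        chrom: points[-1][0] for chrom, points in sorted(dataset.genetic_map.items())
    }
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    if not contigs:
        for chrom in sorted({v.chrom for v in dataset.variants}):
            header.contigs.add(chrom)
    header.info.add("PROBAND", 1, "String", "Proband carrying the DNM")
    header.info.add("GAMRESP", 1, "Float", "Classifier response")
    header.info.add("PHASE", 1, "String", "Parent of origin (paternal/maternal)")
    header.info.add("PHASE_METHOD", 1, "String", "Phasing method")
    hq = scores[scores.high_quality].sort_values(
        ["chrom", "pos", "proband_id"], kind="mergesort"
    )
    with pysam.VariantFile(str(out / "high_quality_dnms.vcf"), "w", header=header) as vcf:
        for row in hq.itertuples():
            rec = vcf.new_record(
                contig=row.chrom,
                start=int(row.pos) - 1,
                stop=int(row.pos) - 1 + len(row.ref),
                alleles=(row.ref, row.alt),
            )
            rec.info["PROBAND"] = row.proband_id
            rec.info["GAMRESP"] = round(float(row.response), 6)
            call = by_key.get((row.proband_id, row.chrom, int(row.pos), row.ref, row.alt))
            if call is not None and call.phased:
                rec.info["PHASE"] = call.origin
                rec.info["PHASE_METHOD"] = call.method
            vcf.write(rec)
    scores.to_csv(out / "candidate_scores.tsv", sep="\t", index=False, float_format="%.6g")
    for name, df in summaries.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format="%.6g")
    import dataclasses

    import yaml

    with open(out / "provenance.yaml", "w") as fh:
        yaml.safe_dump({"config": dataclasses.asdict(config)}, fh, sort_keys=True)
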