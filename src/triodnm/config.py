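"""Run configuration: every tunable threshold of the pipeline in one place.

Defaults are the published operating point of the procedure, so running the
pipeline with a default :class:`RunConfig` applies the standard filter set.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml


@dataclass
class RunConfig:
    # -- candidate extraction ------------------------------------------------
    min_parent_depth: int = 12
    min_parent_depth_x_male: int = 6      # father at X sites of male probands
    max_parent_alt_reads: int = 1
    max_parent_ab: float = 0.05
    min_proband_depth: int = 12
    min_proband_ab: float = 0.15
    max_homalt_ref_reads: int = 1         # hom-alt probands: <=1 ref read
    max_possible_carriers: int = 10       # beyond descendants of the parent pair
    max_likely_carriers: int = 3
    max_site_softclip: float = 0.10
    min_proband_coverage: float = 20.0    # genome-wide mean depth gate

    # -- likely-carrier definition (strict >, as printed) ---------------------
    likely_min_depth: int = 12            # depth must exceed this
    likely_max_ab_dev: float = 0.25       # |AB - 0.5| strictly below
    likely_min_gq: float = 20.0           # GQ must exceed this

    # -- per-proband exclusions ----------------------------------------------
    proband_max_softclip: float = 0.10
    proband_max_nfrac: float = 0.015
    proband_max_candidates: int = 300

    # -- transmission assay ---------------------------------------------------
    min_assay_offspring: int = 2
    offspring_min_alt_reads: int = 2
    offspring_min_ab: float = 0.1
    offspring_min_depth: int = 10

    # -- GAM scoring ----------------------------------------------------------
    gam_cutoff: float = 0.8               # response strictly above -> high quality
    gam_spline_df: int = 10
    gam_select_penalty: bool = True

    # -- phasing --------------------------------------------------------------
    min_segment_cm: float = 0.8
    min_segment_markers: int = 200
    pair_window_bp: int = 1000
    min_pair_support: int = 1

    # -- twin validation ------------------------------------------------------
    twin_min_depth: int = 10
    twin_min_alt_reads: int = 2
    twin_min_ab: float = 0.1

    # -- sample QC ------------------------------------------------------------
    contamination_threshold: float = 0.001
    relationship_threshold: float = 0.45

    # -- misc -----------------------------------------------------------------
    x_chrom: str = "X"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "max_parent_ab",
            "min_proband_ab",
            "max_site_softclip",
            "likely_max_ab_dev",
            "proband_max_softclip",
            "proband_max_nfrac",
            "offspring_min_ab",
            "gam_cutoff",
            "twin_min_ab",
            "contamination_threshold",
            "relationship_threshold",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
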