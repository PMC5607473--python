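import itertools

import numpy as np
import pytest

from conftest import make_ev, make_site
from triodnm.config import RunConfig
from triodnm.datatypes import DNMCandidate
from triodnm.pedigree import FEMALE, MALE, Individual, ThreeGenFamily
from triodnm.transmission import (
    CONSISTENT,
    INCONSISTENT,
    UNEVALUABLE,
    assess_transmission,
    foxog_metric,
    offspring_call,
)


class TestFoxog:
    def test_non_ca_substitution_is_zero(self):
        site = make_site(ref="A", alt="G")
        assert foxog_metric(site, make_ev(f1r2=3, f2r1=12)) == 0.0

    def test_pure_artifact_orientation(self):
        site = make_site(ref="C", alt="A")
        assert foxog_metric(site, make_ev(alt=10, ref=20, f1r2=0, f2r1=10)) == 1.0

    def test_symmetric_orientation(self):
        site = make_site(ref="C", alt="A")
        assert foxog_metric(site, make_ev(alt=10, ref=20, f1r2=5, f2r1=5)) == 0.5

    def test_gt_reverse_complement_swaps_roles(self):
        site = make_site(ref="G", alt="T")
        assert foxog_metric(site, make_ev(alt=10, ref=20, f1r2=10, f2r1=0)) == 1.0

    def test_indel_is_zero(self):
        site = make_site(ref="CA", alt="C")
        assert foxog_metric(site, make_ev(f1r2=4, f2r1=4)) == 0.0

    def test_no_orientation_reads_is_zero(self):
        site = make_site(ref="C", alt="A")
        assert foxog_metric(site, make_ev(alt=5, ref=20, f1r2=0, f2r1=0)) == 0.0


class TestOffspringCall:
    def test_depth_below_ten_missing(self):
        ev = make_ev(ref=4, alt=5, genotype="het")
        assert offspring_call(ev) == "missing"

    def test_alt_call_needs_two_alt_reads(self):
        ev = make_ev(ref=20, alt=1, genotype="het")
        assert offspring_call(ev) == "missing"

    def test_alt_call_needs_ab_over_point_one(self):
        ev = make_ev(ref=28, alt=2, genotype="het")  # AB 0.067
        assert offspring_call(ev) == "missing"

    def test_good_carrier(self):
        assert offspring_call(make_ev(ref=15, alt=15)) == "carrier"

    def test_hom_ref_with_depth_is_non_carrier(self):
        ev = make_ev(ref=30, alt=0, genotype="hom_ref")
        assert offspring_call(ev) == "non_carrier"


def family(n_offspring, sexes=None, x=False):
    offspring = [
        Individual(
            f"O{i}",
            (sexes or [FEMALE] * n_offspring)[i],
            father_id="P",
            mother_id="S",
        )
        for i in range(n_offspring)
    ]
    return ThreeGenFamily(
        Individual("P", MALE, father_id="F", mother_id="M"),
        Individual("F", MALE),
        Individual("M", FEMALE),
        offspring,
    )


def cand(chrom="1"):
    return DNMCandidate(
        proband_id="P",
        site=make_site(chrom=chrom),
        proband_ev=make_ev(),
        father_ev=make_ev(ref=25, alt=0, genotype="hom_ref"),
        mother_ev=make_ev(ref=25, alt=0, genotype="hom_ref"),
        proband_ab=0.5,
        n_possible_outside=0,
        n_likely_outside=0,
        gatk_pass=True,
    )


CARRIER_EV = dict(ref=14, alt=16, genotype="het")
NON_CARRIER_EV = dict(ref=30, alt=0, genotype="hom_ref")


class TestAssessTransmission:
    def test_two_offspring_distinct_haplotypes_consistent(self):
        fam = family(2)
        label = assess_transmission(
            cand(),
            fam,
            {"O0": "paternal", "O1": "maternal"},
            {"O0": make_ev(**CARRIER_EV), "O1": make_ev(**NON_CARRIER_EV)},
        )
        assert label.label == CONSISTENT
        assert label.n_offspring_informative == 2

    def test_same_haplotype_only_unevaluable(self):
        fam = family(2)
        label = assess_transmission(
            cand(),
            fam,
            {"O0": "paternal", "O1": "paternal"},
            {"O0": make_ev(**CARRIER_EV), "O1": make_ev(**CARRIER_EV)},
        )
        assert label.label == UNEVALUABLE

    def test_three_offspring_no_two_coloring_inconsistent(self):
        fam = family(3)
        label = assess_transmission(
            cand(),
            fam,
            {"O0": "paternal", "O1": "paternal", "O2": "maternal"},
            {
                "O0": make_ev(**CARRIER_EV),
                "O1": make_ev(**NON_CARRIER_EV),
                "O2": make_ev(**NON_CARRIER_EV),
            },
        )
        assert label.label == INCONSISTENT

    def test_x_male_het_carrier_inconsistent(self):
        fam = family(2, sexes=[MALE, FEMALE])
        label = assess_transmission(
            cand(chrom="X"),
            fam,
            {"O0": "paternal", "O1": "maternal"},
            {"O0": make_ev(**CARRIER_EV), "O1": make_ev(**NON_CARRIER_EV)},
        )
        assert label.label == INCONSISTENT

    def test_x_male_homalt_carrier_allowed(self):
        fam = family(2, sexes=[MALE, FEMALE])
        label = assess_transmission(
            cand(chrom="X"),
            fam,
            {"O0": "paternal", "O1": "maternal"},
            {
                "O0": make_ev(ref=1, alt=16, genotype="hom_alt"),
                "O1": make_ev(**NON_CARRIER_EV),
            },
        )
        assert label.label == CONSISTENT

    def test_missing_offspring_abstains(self):
        fam = family(3)
        label = assess_transmission(
            cand(),
            fam,
            {"O0": "paternal", "O1": "maternal"},  # O2 has no assignment
            {
                "O0": make_ev(**CARRIER_EV),
                "O1": make_ev(**NON_CARRIER_EV),
                "O2": make_ev(**CARRIER_EV),
            },
        )
        assert label.label == CONSISTENT


def oracle_label(assignments, statuses, min_offspring=2):
    """Exhaustive enumeration over both carrier-haplotype hypotheses."""
    informative = [
        (h, s) for h, s in zip(assignments, statuses) if s != "missing" and h is not None
    ]
    haps = {h for h, _ in informative}
    if len(informative) < min_offspring or haps != {"paternal", "maternal"}:
        return UNEVALUABLE
    for carrier_hap in ("paternal", "maternal"):
        if all((s == "carrier") == (h == carrier_hap) for h, s in informative):
            return CONSISTENT
    return INCONSISTENT


class TestTransmissionOracle:
    def test_all_configurations_up_to_six_offspring(self):
        """Exhaustive agreement with the enumeration oracle (autosomes)."""
        cfg = RunConfig()
        status_ev = {
            "carrier": make_ev(**CARRIER_EV),
            "non_carrier": make_ev(**NON_CARRIER_EV),
            "missing": make_ev(ref=3, alt=3, genotype="het"),  # depth 6 < 10
        }
        rng = np.random.default_rng(77)
        hap_values = ["paternal", "maternal", None]
        status_values = ["carrier", "non_carrier", "missing"]
        for n in range(1, 7):
            fam = family(n)
            if n <= 4:
                combos = itertools.product(
                    itertools.product(hap_values, repeat=n),
                    itertools.product(status_values, repeat=n),
                )
            else:
                combos = (
                    (
                        tuple(rng.choice(3) for _ in range(n)),
                        tuple(rng.choice(3) for _ in range(n)),
                    )
                    for _ in range(3000)
                )
                combos = (
                    (
                        tuple(hap_values[i] for i in hs),
                        tuple(status_values[i] for i in ss),
                    )
                    for hs, ss in combos
                )
            for haps, statuses in combos:
                inheritance = {
                    f"O{i}": h for i, h in enumerate(haps) if h is not None
                }
                evs = {f"O{i}": status_ev[s] for i, s in enumerate(statuses)}
                label = assess_transmission(cand(), fam, inheritance, evs, cfg)
                # oracle sees the post-missingness statuses
                eff = [
                    s if h is not None else "missing"
                    for h, s in zip(haps, statuses)
                ]
                want = oracle_label(haps, eff)
                assert label.label == want, (n, haps, statuses)
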