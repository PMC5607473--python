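import numpy as np

from conftest import make_ev, make_site
from triodnm.datatypes import DNMCandidate
from triodnm.pedigree import FEMALE, MALE, Individual, ThreeGenFamily
from triodnm.phasing import (
    DISCORDANT,
    METHOD_CONSENSUS,
    METHOD_READ_PAIR,
    METHOD_THREE_GEN,
    UNPHASED,
    InheritanceAssignment,
    PhaseCall,
    ReadPairCount,
    consensus_phase,
    phase_by_read_tracing,
    phase_by_three_gen,
    phase_summary_from_counts,
    summarize_phasing,
)


def fam(n=2):
    return ThreeGenFamily(
        Individual("P", MALE, father_id="F", mother_id="M"),
        Individual("F", MALE),
        Individual("M", FEMALE),
        [Individual(f"O{i}", FEMALE, father_id="P", mother_id="S") for i in range(n)],
    )


def cand(pos=1000):
    return DNMCandidate(
        proband_id="P",
        site=make_site(pos=pos),
        proband_ev=make_ev(),
        father_ev=make_ev(ref=25, alt=0, genotype="hom_ref"),
        mother_ev=make_ev(ref=25, alt=0, genotype="hom_ref"),
        proband_ab=0.5,
        n_possible_outside=0,
        n_likely_outside=0,
        gatk_pass=True,
    )


def assign(hap, cm=5.0, markers=500):
    return InheritanceAssignment(hap, cm, markers)


CARRIER = dict(ref=14, alt=16, genotype="het")
NON_CARRIER = dict(ref=30, alt=0, genotype="hom_ref")


class TestThreeGen:
    def test_carrier_on_paternal_haplotype_gives_paternal(self):
        call = phase_by_three_gen(
            cand(), fam(1), {"O0": assign("paternal")}, {"O0": make_ev(**CARRIER)}
        )
        assert call.origin == "paternal" and call.method == METHOD_THREE_GEN

    def test_non_carrier_on_paternal_haplotype_gives_maternal(self):
        call = phase_by_three_gen(
            cand(), fam(1), {"O0": assign("paternal")}, {"O0": make_ev(**NON_CARRIER)}
        )
        assert call.origin == "maternal"

    def test_conflicting_votes_unphased(self):
        call = phase_by_three_gen(
            cand(),
            fam(2),
            {"O0": assign("paternal"), "O1": assign("maternal")},
            {"O0": make_ev(**CARRIER), "O1": make_ev(**CARRIER)},
        )
        assert call.origin == UNPHASED

    def test_short_segment_abstains(self):
        call = phase_by_three_gen(
            cand(), fam(1), {"O0": assign("paternal", cm=0.5)}, {"O0": make_ev(**CARRIER)}
        )
        assert call.origin == UNPHASED

    def test_few_markers_abstains(self):
        call = phase_by_three_gen(
            cand(),
            fam(1),
            {"O0": assign("paternal", markers=150)},
            {"O0": make_ev(**CARRIER)},
        )
        assert call.origin == UNPHASED

    def test_missing_call_abstains(self):
        shallow = make_ev(ref=4, alt=4, genotype="het")  # depth 8 < 10
        call = phase_by_three_gen(
            cand(), fam(1), {"O0": assign("paternal")}, {"O0": shallow}
        )
        assert call.origin == UNPHASED


def rp(dnm_pos=1000, marker_pos=1400, aa1=0, aa2=0, ra1=0, ra2=0, multi=0):
    return ReadPairCount("P", "1", dnm_pos, "1", marker_pos, ra1, ra2, aa1, aa2, multi)


class TestReadTracing:
    MARKER_PAT = {("P", "1", 1400): 1}  # allele 1 is paternal

    def test_single_sided_support_phases(self):
        counts = [rp(aa1=7, ra2=5)]
        call = phase_by_read_tracing(cand(), counts, self.MARKER_PAT)
        assert call.origin == "paternal" and call.method == METHOD_READ_PAIR

    def test_two_sided_support_unphased(self):
        counts = [rp(aa1=5, aa2=2)]
        call = phase_by_read_tracing(cand(), counts, self.MARKER_PAT)
        assert call.origin == UNPHASED

    def test_only_multi_haplotype_pairs_unphased(self):
        counts = [rp(multi=4)]
        call = phase_by_read_tracing(cand(), counts, self.MARKER_PAT)
        assert call.origin == UNPHASED

    def test_marker_outside_window_ignored(self):
        counts = [rp(marker_pos=5000, aa1=9)]
        marker = {("P", "1", 5000): 1}
        call = phase_by_read_tracing(cand(), counts, marker)
        assert call.origin == UNPHASED

    def test_unresolved_marker_origin_dropped(self):
        counts = [rp(aa1=9)]
        call = phase_by_read_tracing(cand(), counts, {})
        assert call.origin == UNPHASED

    def test_allele2_paternal_swaps_sides(self):
        counts = [rp(aa2=6)]
        call = phase_by_read_tracing(cand(), counts, self.MARKER_PAT)
        assert call.origin == "maternal"

    def test_ref_pairs_never_assign_origin(self):
        counts = [rp(ra1=10, ra2=10)]
        call = phase_by_read_tracing(cand(), counts, self.MARKER_PAT)
        assert call.origin == UNPHASED


class TestConsensus:
    def key(self):
        return cand().key

    def pc(self, origin, method):
        return PhaseCall(self.key(), origin, method)

    def test_agreement(self):
        c = consensus_phase(
            self.pc("paternal", METHOD_THREE_GEN), self.pc("paternal", METHOD_READ_PAIR)
        )
        assert c.origin == "paternal" and c.method == METHOD_CONSENSUS

    def test_disagreement_is_discordant(self):
        c = consensus_phase(
            self.pc("paternal", METHOD_THREE_GEN), self.pc("maternal", METHOD_READ_PAIR)
        )
        assert c.origin == DISCORDANT

    def test_single_method_carries_through(self):
        c = consensus_phase(
            self.pc(UNPHASED, METHOD_THREE_GEN), self.pc("maternal", METHOD_READ_PAIR)
        )
        assert c.origin == "maternal"

    def test_neither_phased(self):
        c = consensus_phase(
            self.pc(UNPHASED, METHOD_THREE_GEN), self.pc(UNPHASED, METHOD_READ_PAIR)
        )
        assert c.origin == UNPHASED

    def test_never_invents_an_origin(self):
        rng = np.random.default_rng(0)
        origins = ["paternal", "maternal", UNPHASED]
        for _ in range(200):
            a = self.pc(origins[rng.integers(0, 3)], METHOD_THREE_GEN)
            b = self.pc(origins[rng.integers(0, 3)], METHOD_READ_PAIR)
            c = consensus_phase(a, b)
            if c.origin in ("paternal", "maternal"):
                assert c.origin in (a.origin, b.origin)


class TestSummaries:
    def test_consensus_union_arithmetic(self):
        df = phase_summary_from_counts(15746, 31834, 4566, 53, 108778)
        by = dict(zip(df.phased_set, df["count"]))
        assert by["consensus"] == 15746 + 31834 - 4566 - 53 == 42961

    def test_set_identity_on_random_calls(self):
        rng = np.random.default_rng(10)
        origins = ["paternal", "maternal", UNPHASED]
        three, read, cons = [], [], []
        for i in range(500):
            key = ("P", "1", i, "A", "G")
            a = PhaseCall(key, origins[rng.integers(0, 3)], METHOD_THREE_GEN)
            b = PhaseCall(key, origins[rng.integers(0, 3)], METHOD_READ_PAIR)
            three.append(a)
            read.append(b)
            cons.append(consensus_phase(a, b))
        df = summarize_phasing(three, read, cons, 500)
        by = dict(zip(df.phased_set, df["count"]))
        assert by["consensus"] == by["three_gen"] + by["read_pair"] - by["both"] - by["both_discordant"]
        assert by["consensus"] == sum(c.phased for c in cons)

    def test_all_unphased(self):
        calls = [PhaseCall(("P", "1", i, "A", "G"), UNPHASED, METHOD_THREE_GEN) for i in range(5)]
        calls_b = [PhaseCall(c.candidate_key, UNPHASED, METHOD_READ_PAIR) for c in calls]
        cons = [consensus_phase(a, b) for a, b in zip(calls, calls_b)]
        df = summarize_phasing(calls, calls_b, cons, 5)
        assert (df["count"] == 0).all()
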