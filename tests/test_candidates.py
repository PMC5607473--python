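import numpy as np
import pytest

from conftest import make_ev, make_site
from triodnm.candidates import (
    ProbandStats,
    allelic_balance,
    classify_carriers,
    evaluate_trio_site,
    extract_candidates,
    filter_probands,
)
from triodnm.config import RunConfig
from triodnm.datatypes import DNMCandidate
from triodnm.pedigree import FEMALE, MALE


class TestAllelicBalance:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [(10, 10, 0.5), (0, 12, 1.0), (17, 3, 0.15)],
    )
    def test_values(self, ref, alt, expected):
        assert allelic_balance(make_ev(ref=ref, alt=alt)) == pytest.approx(expected)

    def test_no_informative_reads_undefined(self):
        ev = make_ev(ref=0, alt=0, depth=5, genotype="hom_ref", f1r2=0, f2r1=0)
        with pytest.raises(ZeroDivisionError):
            allelic_balance(ev)


class TestClassifyCarriers:
    def test_no_other_carriers(self):
        site = make_site()
        evidence = {"p": make_ev(), "f": make_ev(alt=0, ref=30, genotype="hom_ref")}
        assert classify_carriers(site, evidence, {"p"}) == (0, 0)

    def test_possible_vs_likely_split(self):
        site = make_site()
        evidence = {
            "good": make_ev(ref=15, alt=15, gq=99),  # depth 30, AB 0.5, GQ 99
            "shallow": make_ev(ref=4, alt=4),  # depth 8 <= 12
        }
        assert classify_carriers(site, evidence, set()) == (2, 1)

    def test_carrier_inside_excluded_set_ignored(self):
        site = make_site()
        evidence = {"child": make_ev()}
        assert classify_carriers(site, evidence, {"child"}) == (0, 0)

    def test_likely_boundaries_strict(self):
        site = make_site()
        # depth exactly 12 is NOT over 12; GQ exactly 20 is NOT over 20
        at_depth = make_ev(ref=6, alt=6, gq=99)
        at_gq = make_ev(ref=15, alt=15, gq=20)
        assert classify_carriers(site, {"a": at_depth}, set()) == (1, 0)
        assert classify_carriers(site, {"a": at_gq}, set()) == (1, 0)


GOOD_PROBAND = dict(ref=15, alt=15)
GOOD_PARENT = dict(ref=25, alt=0, genotype="hom_ref")


def run_rules(proband=None, father=None, mother=None, sex=FEMALE, site=None,
              n_poss=0, n_likely=0, cfg=None):
    return evaluate_trio_site(
        site or make_site(),
        make_ev(**(proband or GOOD_PROBAND)),
        make_ev(**(father or GOOD_PARENT)),
        make_ev(**(mother or GOOD_PARENT)),
        sex,
        n_poss,
        n_likely,
        cfg or RunConfig(),
    )


class TestTrioRules:
    def test_clean_trio_passes(self):
        ok, failed = run_rules()
        assert ok and failed == []

    def test_parent_with_two_alt_reads_rejected(self):
        ok, failed = run_rules(father=dict(ref=28, alt=2, genotype="hom_ref"))
        assert not ok and "father_alt_reads" in failed

    def test_proband_low_ab_rejected(self):
        ok, failed = run_rules(proband=dict(ref=27, alt=3))  # AB 0.10
        assert not ok and "proband_ab" in failed

    def test_proband_ab_boundary_inclusive(self):
        ok, _ = run_rules(proband=dict(ref=17, alt=3))  # AB exactly 0.15
        assert ok

    def test_eleven_possible_carriers_rejected(self):
        ok, failed = run_rules(n_poss=11, n_likely=0)
        assert not ok and failed == ["possible_carriers"]

    def test_four_likely_carriers_rejected(self):
        ok, failed = run_rules(n_poss=4, n_likely=4)
        assert not ok and failed == ["likely_carriers"]

    def test_homalt_proband_two_ref_reads_rejected(self):
        ok, failed = run_rules(proband=dict(ref=2, alt=28, genotype="hom_alt"))
        assert not ok and "homalt_ref_reads" in failed

    def test_homalt_proband_one_ref_read_ok(self):
        ok, _ = run_rules(proband=dict(ref=1, alt=29, genotype="hom_alt"))
        assert ok

    def test_parent_shallow_depth_rejected(self):
        ok, failed = run_rules(mother=dict(ref=11, alt=0, genotype="hom_ref"))
        assert not ok and "mother_depth" in failed

    def test_parent_ab_rule_independent_of_alt_count(self):
        # one alt read out of 15: passes the count rule but 1/15 > 0.05
        ok, failed = run_rules(father=dict(ref=14, alt=1, genotype="hom_ref"))
        assert not ok and failed == ["father_ab"]

    def test_site_softclip_rejected(self):
        ok, failed = run_rules(proband=dict(ref=15, alt=15, softclip=0.15))
        assert not ok and "site_softclip" in failed

    def test_x_male_father_depth_six_suffices(self):
        site = make_site(chrom="X")
        ok, _ = run_rules(
            proband=dict(ref=0, alt=16, genotype="hom_alt"),
            father=dict(ref=7, alt=0, genotype="hom_ref"),
            sex=MALE,
            site=site,
        )
        assert ok

    def test_x_male_father_depth_five_rejected(self):
        site = make_site(chrom="X")
        ok, failed = run_rules(
            proband=dict(ref=0, alt=16, genotype="hom_alt"),
            father=dict(ref=5, alt=0, genotype="hom_ref"),
            sex=MALE,
            site=site,
        )
        assert not ok and "father_depth" in failed

    def test_x_male_proband_ref_reads_capped(self):
        site = make_site(chrom="X")
        ok, failed = run_rules(
            proband=dict(ref=3, alt=20, genotype="het"), sex=MALE, site=site
        )
        assert not ok and "x_male_ref_reads" in failed


def brute_force_retained(site, pe, fe, me, sex, n_poss, n_likely, cfg):
    """Independent rule-by-rule oracle, written directly from the filter list."""
    def ab(e):
        t = e.ref_reads + e.alt_reads
        return None if t == 0 else e.alt_reads / t

    x_male = site.chrom == cfg.x_chrom and sex == MALE
    if pe.genotype not in ("het", "hom_alt"):
        return False
    if x_male:
        if pe.ref_reads > 1:
            return False
    elif pe.genotype == "hom_alt" and pe.ref_reads > 1:
        return False
    f_min = 6 if x_male else 12
    if fe.depth < f_min or me.depth < 12:
        return False
    if fe.alt_reads > 1 or me.alt_reads > 1:
        return False
    for e in (fe, me):
        a = ab(e)
        if a is not None and a > 0.05:
            return False
    if pe.depth < 12:
        return False
    a = ab(pe)
    if a is None or a < 0.15:
        return False
    if n_poss > 10 or n_likely > 3:
        return False
    if pe.softclip_frac > 0.10:
        return False
    return True


class TestFilterOracle:
    def test_randomized_trios_match_bruteforce(self):
        rng = np.random.default_rng(123)
        cfg = RunConfig()
        n_checked = kept = 0
        for _ in range(1000):
            chrom = "X" if rng.random() < 0.3 else "1"
            sex = MALE if rng.random() < 0.5 else FEMALE
            site = make_site(chrom=chrom, pos=int(rng.integers(1, 10**6)))

            def rand_ev(carrier_bias):
                depth = int(rng.integers(0, 40))
                alt = int(rng.binomial(depth, carrier_bias)) if depth else 0
                ref = depth - alt
                gt = rng.choice(["hom_ref", "het", "hom_alt"])
                return make_ev(
                    ref=ref,
                    alt=alt,
                    depth=depth,
                    genotype=gt,
                    gq=float(rng.integers(0, 100)),
                    f1r2=0,
                    f2r1=0,
                    softclip=float(rng.uniform(0, 0.2)),
                )

            pe = rand_ev(float(rng.uniform(0, 0.8)))
            fe = rand_ev(float(rng.uniform(0, 0.1)))
            me = rand_ev(float(rng.uniform(0, 0.1)))
            n_poss = int(rng.integers(0, 15))
            n_likely = int(rng.integers(0, min(n_poss + 1, 6)))
            if pe.informative_reads == 0:
                continue
            got, _ = evaluate_trio_site(site, pe, fe, me, sex, n_poss, n_likely, cfg)
            want = brute_force_retained(site, pe, fe, me, sex, n_poss, n_likely, cfg)
            assert got == want
            n_checked += 1
            kept += got
        assert n_checked > 800 and 0 < kept < n_checked

    def test_tightening_thresholds_is_monotone(self):
        rng = np.random.default_rng(9)
        base = RunConfig()
        tighter = RunConfig(
            min_proband_ab=0.25,
            min_parent_depth=15,
            max_possible_carriers=5,
            max_site_softclip=0.05,
        )
        for _ in range(300):
            pe = make_ev(
                ref=int(rng.integers(0, 20)),
                alt=int(rng.integers(1, 25)),
                softclip=float(rng.uniform(0, 0.12)),
            )
            fe = make_ev(ref=int(rng.integers(5, 30)), alt=0, genotype="hom_ref")
            me = make_ev(ref=int(rng.integers(5, 30)), alt=0, genotype="hom_ref")
            n_poss = int(rng.integers(0, 12))
            site = make_site()
            loose, _ = evaluate_trio_site(site, pe, fe, me, FEMALE, n_poss, 0, base)
            tight, _ = evaluate_trio_site(site, pe, fe, me, FEMALE, n_poss, 0, tighter)
            assert not (tight and not loose)


class TestExtractionOnSimulation:
    def test_planted_dnms_with_covered_parents_retained(self, small_sim, small_dataset):
        cands = extract_candidates(small_dataset, small_dataset.pedigree)
        got = {(c.proband_id, c.site.chrom, c.site.pos) for c in cands}
        eligible = retained = 0
        for d in small_sim.truth.dnms:
            key = (d.chrom, d.pos, d.ref, d.alt)
            per = small_dataset.evidence_by_site[key]
            fam = d.proband_id.rsplit("_", 1)[0]
            fe = per.get(f"{fam}_fa")
            me = per.get(f"{fam}_mo")
            if fe is None or me is None or fe.depth < 12 or me.depth < 12:
                continue
            eligible += 1
            retained += (d.proband_id, d.chrom, d.pos) in got
        assert eligible > 100
        assert retained / eligible >= 0.95

    def test_bad_probands_removed_wholesale(self):
        from triodnm.simulate import SimConfig, Simulator

        sim = Simulator(SimConfig(seed=21, n_families=10, n_bad_probands=3)).run()
        ds = sim.to_dataset()
        from triodnm.candidates import compute_proband_stats

        cands = extract_candidates(ds, ds.pedigree)
        stats = compute_proband_stats(ds.evidence_by_individual)
        kept, excluded = filter_probands(cands, stats)
        assert set(excluded) == set(sim.truth.bad_probands)
        assert not {c.proband_id for c in kept} & set(excluded)

    def test_candidate_cap_drops_proband(self):
        cands = []
        site_tpl = make_site()
        for i in range(301):
            cands.append(
                DNMCandidate(
                    proband_id="p1",
                    site=make_site(pos=1000 + i),
                    proband_ev=make_ev(),
                    father_ev=make_ev(ref=25, alt=0, genotype="hom_ref"),
                    mother_ev=make_ev(ref=25, alt=0, genotype="hom_ref"),
                    proband_ab=0.5,
                    n_possible_outside=0,
                    n_likely_outside=0,
                    gatk_pass=True,
                )
            )
        stats = {"p1": ProbandStats(34.0, 0.03, 0.005)}
        kept, excluded = filter_probands(cands, stats)
        assert excluded == ["p1"] and kept == []
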