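import numpy as np
import pytest

from triodnm.pedigree import PATERNAL, find_three_generation_families
from triodnm.simulate import (
    MosaicHap,
    SimConfig,
    Simulator,
    founder_origin,
    simulate,
)
from triodnm.transmission import foxog_metric


class TestPedigreeStage:
    def test_families_discoverable(self):
        sim = Simulator(SimConfig(seed=2, n_families=10, offspring_min=2)).run()
        fams = find_three_generation_families(sim.graph)
        assert len(fams) == 10

    def test_twin_groups_present(self):
        sim = Simulator(SimConfig(seed=2, n_families=6, n_twin_pairs=3)).run()
        assert len(sim.graph.twin_pairs()) == 3

    def test_same_seed_identical_output(self):
        cfg = SimConfig(seed=9, n_families=4)
        a = Simulator(cfg).run()
        b = Simulator(cfg).run()
        assert [r.id for r in a.records] == [r.id for r in b.records]
        assert [v.key for v in a.variants] == [v.key for v in b.variants]
        assert a.evidence_by_site == b.evidence_by_site
        assert [(d.proband_id, d.chrom, d.pos) for d in a.truth.dnms] == [
            (d.proband_id, d.chrom, d.pos) for d in b.truth.dnms
        ]


class TestGenomeStage:
    def test_zero_recombination_copies_one_parental_haplotype(self):
        cfg = SimConfig(seed=3, n_families=2, cm_per_mb=0.0)
        sim = Simulator(cfg)
        sim.simulate_pedigree()
        sim.simulate_genomes()
        for ind, genome in sim.genomes.items():
            for chrom, haps in genome.items():
                for hap in haps:
                    if isinstance(hap, MosaicHap):
                        assert hap.breaks == []
                        # whole chromosome traces to a single founder haplotype
                        assert founder_origin(hap, 1) == founder_origin(
                            hap, cfg.chrom_lengths[chrom] - 1
                        )

    def test_zero_dnm_rate_empty_truth(self):
        sim = Simulator(SimConfig(seed=3, n_families=3, dnm_per_gamete=0.0)).run()
        assert sim.truth.dnms == []

    def test_dnm_count_is_poisson(self):
        rate = 6.0
        counts = []
        for seed in range(40):
            sim = Simulator(
                SimConfig(
                    seed=seed,
                    n_families=5,
                    dnm_per_gamete=rate,
                    artifacts_per_proband=0.0,
                    n_twin_pairs=0,
                )
            )
            sim.simulate_pedigree()
            sim.simulate_genomes()
            counts.append(len(sim.truth.dnms))
        mean_expected = 2 * rate * 5
        se = np.sqrt(mean_expected / len(counts))
        assert abs(np.mean(counts) - mean_expected) < 3 * se

    def test_mendelian_consistency_without_planting(self):
        sim = Simulator(
            SimConfig(seed=4, n_families=4, dnm_per_gamete=0.0, artifacts_per_proband=0.0)
        ).run()
        assert sim.variants == []
        assert sim.evidence_by_site == {}


class TestEvidenceStage:
    def test_true_het_balance_concentrates(self):
        cfg = SimConfig(seed=5, n_families=3, mean_coverage=1000, seq_error_rate=0.0,
                        artifacts_per_proband=0.0)
        sim = Simulator(cfg).run()
        for d in sim.truth.dnms:
            ev = sim.evidence_by_site[(d.chrom, d.pos, d.ref, d.alt)][d.proband_id]
            ab = ev.alt_reads / (ev.ref_reads + ev.alt_reads)
            assert abs(ab - 0.5) < 0.05

    def test_artifact_balance_fails_proband_filter_mostly(self):
        cfg = SimConfig(seed=6, n_families=6, dnm_per_gamete=0.0)
        sim = Simulator(cfg).run()
        abs_ = []
        for a in sim.truth.artifacts:
            ev = sim.evidence_by_site[(a.chrom, a.pos, a.ref, a.alt)].get(a.individual_id)
            if ev is None or ev.ref_reads + ev.alt_reads == 0:
                continue
            abs_.append(ev.alt_reads / (ev.ref_reads + ev.alt_reads))
        assert np.mean(np.array(abs_) < 0.35) > 0.8

    def test_oxog_artifact_foxog_near_one_true_het_near_half(self, small_sim):
        foxes_art, foxes_true = [], []
        site_index = {v.key: v for v in small_sim.variants}
        for a in small_sim.truth.artifacts:
            if not a.oxog:
                continue
            key = (a.chrom, a.pos, a.ref, a.alt)
            ev = small_sim.evidence_by_site[key].get(a.individual_id)
            if ev is not None and ev.alt_reads >= 4:
                foxes_art.append(foxog_metric(site_index[key], ev))
        for d in small_sim.truth.dnms:
            key = (d.chrom, d.pos, d.ref, d.alt)
            if f"{d.ref}>{d.alt}" not in ("C>A", "G>T"):
                continue
            ev = small_sim.evidence_by_site[key][d.proband_id]
            foxes_true.append(foxog_metric(site_index[key], ev))
        assert np.mean(foxes_art) > 0.85
        assert 0.35 < np.mean(foxes_true) < 0.65

    def test_paternal_fraction_one_all_paternal(self):
        sim = Simulator(SimConfig(seed=7, n_families=3, paternal_fraction=1.0)).run()
        assert all(d.origin == PATERNAL for d in sim.truth.dnms)

    def test_truth_rows_match_planted_counts(self, small_sim):
        dnm_sites = {(d.proband_id, d.chrom, d.pos) for d in small_sim.truth.dnms}
        assert len(dnm_sites) == len(small_sim.truth.dnms)
        # every truth DNM has proband evidence carrying the alt
        for d in small_sim.truth.dnms:
            ev = small_sim.evidence_by_site[(d.chrom, d.pos, d.ref, d.alt)][d.proband_id]
            assert ev.carries_alt


class TestXChromosome:
    def test_hemizygous_path_end_to_end(self):
        from triodnm.pedigree import MALE
        from triodnm.pipeline import run_pipeline

        sim = Simulator(SimConfig(seed=19, n_families=12, include_x=True)).run()
        males = {r.id for r in sim.records if r.sex == MALE}
        x_dnms = [d for d in sim.truth.dnms if d.chrom == "X"]
        assert x_dnms
        # male probands carry no paternally derived X
        assert all(d.origin == "maternal" for d in x_dnms if d.proband_id in males)
        res = run_pipeline(sim.to_dataset())
        got = {(c.proband_id, c.site.chrom, c.site.pos) for c in res.candidates}
        male_x = [d for d in x_dnms if d.proband_id in males]
        assert male_x
        assert all((d.proband_id, d.chrom, d.pos) in got for d in male_x)


class TestEndToEndRecovery:
    def test_paternal_fraction_recovered(self):
        from triodnm.pipeline import run_pipeline

        cfg = SimConfig(seed=8, n_families=35, artifacts_per_proband=6.0)
        sim = Simulator(cfg).run()
        ds = sim.to_dataset()
        res = run_pipeline(ds)
        origin_truth = {(d.proband_id, d.chrom, d.pos): d.origin for d in sim.truth.dnms}
        phased = [
            c
            for c in res.consensus_calls
            if c.phased and (c.candidate_key[0], c.candidate_key[1], c.candidate_key[2]) in origin_truth
        ]
        n_pat = sum(c.origin == PATERNAL for c in phased)
        n = len(phased)
        assert n >= 500
        p_hat = n_pat / n
        se = np.sqrt(0.75 * 0.25 / n)
        assert abs(p_hat - cfg.paternal_fraction) < 3 * se + 0.01
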