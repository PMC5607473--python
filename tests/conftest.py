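import pytest

from triodnm.datatypes import SiteEvidence, VariantSite
from triodnm.simulate import SimConfig, Simulator


def make_ev(
    ref=15,
    alt=15,
    depth=None,
    genotype="het",
    gq=99.0,
    f1r2=None,
    f2r1=None,
    softclip=0.02,
    nfrac=0.002,
):
    """Hand-built per-site read evidence with sensible defaults."""
    if depth is None:
        depth = ref + alt
    if f1r2 is None and f2r1 is None:
        f1r2, f2r1 = alt // 2, alt - alt // 2
    return SiteEvidence(
        ref_reads=ref,
        alt_reads=alt,
        depth=depth,
        genotype=genotype,
        gq=gq,
        f1r2_alt=f1r2 or 0,
        f2r1_alt=f2r1 or 0,
        softclip_frac=softclip,
        n_frac=nfrac,
    )


def make_site(chrom="1", pos=1000, ref="A", alt="G", **kw):
    return VariantSite(chrom=chrom, pos=pos, ref=ref, alt=alt, **kw)


@pytest.fixture(scope="session")
def small_sim():
    """A small default-condition simulation shared across tests."""
    return Simulator(SimConfig(seed=11, n_families=8)).run()


@pytest.fixture(scope="session")
def small_dataset(small_sim):
    return small_sim.to_dataset()
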