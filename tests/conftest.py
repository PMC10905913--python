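import numpy as np
import pytest

from dhhscan import genotype_io as gio
from dhhscan import simdata


def make_snp_map(n_snps, chrom="1", start_bp=1, spacing=1000):
    return gio.SnpMap(
        snp_id=np.array([f"{chrom}_s{i}" for i in range(n_snps)], dtype=object),
        chrom=np.array([chrom] * n_snps, dtype=object),
        pos=np.arange(start_bp, start_bp + n_snps * spacing, spacing, dtype=np.int64),
        ref=np.array(["A"] * n_snps, dtype=object),
        alt=np.array(["G"] * n_snps, dtype=object),
    )


def make_genotypes(animals, pat, mat):
    return gio.PhasedGenotypes(
        animals=list(animals),
        pat=np.asarray(pat, dtype=np.int8),
        mat=np.asarray(mat, dtype=np.int8),
    )


@pytest.fixture(scope="session")
def demo_config():
    """Small but detectable population: one fully penetrant perinatal
    lethal at 25% carrier frequency plus a planted historical recombinant
    (recombination-free gene drop so haplotype descent is exact)."""
    return simdata.SimConfig(
        seed=42,
        n_matings=2500,
        n_sires=100,
        n_mgs=150,
        n_snps_per_chrom=100,
        recomb_prob=0.0,
        lethals=[simdata.LethalSpec(mode="perinatal", carrier_frequency=0.25, start_snp=40)],
        recombinant=simdata.RecombinantSpec(frequency=0.03),
    )


@pytest.fixture(scope="session")
def demo_bundle(demo_config):
    return simdata.simulate_population(demo_config)


@pytest.fixture(scope="session")
def demo_pedigree(demo_bundle):
    df = demo_bundle.pedigree
    return gio.Pedigree(
        df.assign(
            sire=df["sire"].where(df["sire"] != "0", None),
            dam=df["dam"].where(df["dam"] != "0", None),
        )
    )


@pytest.fixture(scope="session")
def demo_trios(demo_pedigree, demo_bundle):
    return gio.build_trios(demo_pedigree, demo_bundle.geno)
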