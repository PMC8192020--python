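import numpy as np
import pandas as pd
import pytest

from admixcoal import GenotypeTable, SimulationConfig, build_two_pop_model
from admixcoal.models import ADM1_STUDY_SCALE


@pytest.fixture(scope="session")
def adm1_study():
    """The canonical study-scale admixture-pulse model."""
    return build_two_pop_model("ADM1", ADM1_STUDY_SCALE)


@pytest.fixture(scope="session")
def study_config():
    return SimulationConfig()


def make_table(geno, pops, loci=None, pos=None, ref=None, alt=None):
    """Small genotype-table builder for hand-written fixtures.

    ``geno``: (n_snps, n_samples) ALT dosages; ``pops``: per-sample labels.
    """
    geno = np.asarray(geno, dtype=np.int8)
    n_snps, n_samples = geno.shape
    snps = pd.DataFrame({
        "locus": loci if loci is not None else [f"L{i}" for i in range(n_snps)],
        "pos": pos if pos is not None else [1] * n_snps,
        "ref": ref if ref is not None else ["A"] * n_snps,
        "alt": alt if alt is not None else ["G"] * n_snps,
    })
    samples = [f"s{i}" for i in range(n_samples)]
    return GenotypeTable(snps, geno, samples, np.array(pops, dtype=object))


@pytest.fixture
def toy_two_pop_table():
    """2+2 diploids, three SNPs with pooled ALT counts 1, 4 and 7 (of 8)."""
    geno = [[1, 0, 0, 0],
            [2, 1, 1, 0],
            [2, 2, 2, 1]]
    return make_table(geno, ["A", "A", "B", "B"],
                      loci=["L0", "L1", "L2"], pos=[5, 3, 9])
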