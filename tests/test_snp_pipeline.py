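"""SNP filtering: completeness, exact HWE test, single-SNP, classification."""

import math
from fractions import Fraction

import numpy as np
import pytest

from admixcoal import (GenotypeTable, SimulationConfig, build_one_pop_model,
                       classify_snps, completeness_filter, first_snp_per_locus,
                       hwe_exact_pvalue, hwe_filter, simulate_dataset)
from admixcoal.snp_pipeline import filter_report, hwe_pvalues

from conftest import make_table


# -- independent exact-rational oracle for the HWE test --------------------

def hwe_oracle(n_hom_ref, n_het, n_hom_alt):
    """Exact p-value by full enumeration with rational arithmetic."""
    n = n_hom_ref + n_het + n_hom_alt
    n_a = 2 * n_hom_ref + n_het
    n_b = 2 * n_hom_alt + n_het
    fact = math.factorial

    def prob(h):
        ha, hb = (n_a - h) // 2, (n_b - h) // 2
        return (Fraction(fact(n), fact(ha) * fact(h) * fact(hb))
                * Fraction(2) ** h
                * Fraction(fact(n_a) * fact(n_b), fact(2 * n)))

    n_minor = min(n_a, n_b)
    p_obs = prob(n_het)
    return float(sum(prob(h) for h in range(n_minor % 2, n_minor + 1, 2)
                     if prob(h) <= p_obs))


def all_genotype_counts(max_n):
    for n in range(1, max_n + 1):
        for hr in range(n + 1):
            for h in range(n - hr + 1):
                yield hr, h, n - hr - h


def test_hwe_exact_matches_enumeration_oracle():
    """Exact equality with the rational-arithmetic oracle for all
    configurations up to 10 diploids."""
    for hr, h, ha in all_genotype_counts(10):
        got = hwe_exact_pvalue(hr, h, ha)
        want = hwe_oracle(hr, h, ha)
        assert got == pytest.approx(want, abs=1e-12), (hr, h, ha)


def test_hwe_two_diploid_hand_case():
    """One of each homozygote among 2 diploids: p = P(het=0) = 1/3."""
    assert hwe_exact_pvalue(1, 0, 1) == pytest.approx(1 / 3, abs=1e-12)


def test_hwe_monomorphic_and_symmetry():
    assert hwe_exact_pvalue(7, 0, 0) == 1.0
    for hr, h, ha in [(3, 2, 1), (5, 1, 4), (0, 4, 6)]:
        assert hwe_exact_pvalue(hr, h, ha) == pytest.approx(
            hwe_exact_pvalue(ha, h, hr), abs=1e-14)
    with pytest.raises(ValueError):
        hwe_exact_pvalue(-1, 0, 0)


def test_hwe_rejection_rate_on_equilibrium_data():
    """Random pairing of simulated haploids obeys HW; the exact test at
    alpha = 0.05 rejects at most 5% (+3 binomial SE) of SNPs."""
    model = build_one_pop_model("CONST", {"NPOP": 60_000})
    cfg = SimulationConfig(sample_sizes=(10,), n_loci=4_000, seed=13)
    table = simulate_dataset(model, cfg)
    pvals = hwe_pvalues(table, "pop1")
    rate = float((pvals < 0.05).mean())
    se = math.sqrt(0.05 * 0.95 / len(pvals))
    assert rate <= 0.05 + 3 * se


def test_completeness_filter_hand_pattern():
    """5 loci, 2 SNPs missing in one individual: exactly 3 loci survive."""
    geno = np.zeros((5, 4), dtype=np.int8) + 1
    geno[1, 0] = -1                      # locus L1 incomplete in pop A
    geno[3, 3] = -1                      # locus L3 incomplete in pop B
    t = make_table(geno, ["A", "A", "B", "B"],
                   loci=["L0", "L1", "L2", "L3", "L4"])
    out = completeness_filter(t)
    assert sorted(out.snps["locus"]) == ["L0", "L2", "L4"]
    # without the all-individuals requirement nothing is dropped here
    loose = completeness_filter(t, require_all_individuals=False)
    assert loose.n_snps == 5
    # no missing data: identity
    again = completeness_filter(out)
    assert again.n_snps == out.n_snps


def test_completeness_min_pops():
    geno = np.array([[1, 1, -1, -1], [1, 1, 1, 1]], dtype=np.int8)
    t = make_table(geno, ["A", "A", "B", "B"], loci=["L0", "L1"])
    assert completeness_filter(t, min_pops=2,
                               require_all_individuals=False).n_snps == 1
    assert completeness_filter(t, min_pops=1,
                               require_all_individuals=False).n_snps == 2


def test_hwe_filter_drops_deviating_locus():
    """A locus out of equilibrium in one species is removed entirely."""
    # 8 diploids per pop; SNP0: extreme heterozygote excess in pop A
    balanced = [1, 1, 1, 1, 0, 2, 0, 2]
    excess = [1] * 8
    geno = np.array([excess + balanced, balanced + balanced], dtype=np.int8)
    t = make_table(geno, ["A"] * 8 + ["B"] * 8, loci=["L0", "L1"])
    p = hwe_exact_pvalue(0, 8, 0)
    assert p < 0.05
    out = hwe_filter(t, alpha=0.05)
    assert list(out.snps["locus"]) == ["L1"]
    assert hwe_filter(t, alpha=0.0).n_snps == 2          # alpha=0: identity
    # dropping is per locus: a second SNP on L0 disappears with it
    t2 = make_table(geno, ["A"] * 8 + ["B"] * 8, loci=["L0", "L0"])
    assert hwe_filter(t2, alpha=0.05).n_snps == 0


def test_hwe_filter_survivors_match_per_locus_pvalues():
    rng = np.random.default_rng(3)
    geno = rng.integers(0, 3, size=(30, 12)).astype(np.int8)
    t = make_table(geno, ["A"] * 6 + ["B"] * 6,
                   loci=[f"L{i}" for i in range(30)])
    keep_expected = [
        f"L{i}" for i in range(30)
        if all(hwe_exact_pvalue(*np.array([(geno[i, cols] == 0).sum(),
                                           (geno[i, cols] == 1).sum(),
                                           (geno[i, cols] == 2).sum()]))
               >= 0.05
               for cols in (slice(0, 6), slice(6, 12)))]
    out = hwe_filter(t, alpha=0.05)
    assert list(out.snps["locus"]) == keep_expected


def test_first_snp_per_locus():
    geno = np.ones((5, 4), dtype=np.int8)
    t = make_table(geno, ["A", "A", "B", "B"],
                   loci=["L0", "L0", "L0", "L1", "L2"],
                   pos=[7, 3, 12, 5, 1])
    out = first_snp_per_locus(t)
    assert len(out.snps) == 3
    assert dict(zip(out.snps["locus"], out.snps["pos"])) == {
        "L0": 3, "L1": 5, "L2": 1}
    twice = first_snp_per_locus(out)
    assert twice.snps.equals(out.snps)


def test_classification_transitions_and_diagnostic():
    geno = np.array([
        [0, 0, 2, 2],     # diagnostic, A<->G transition
        [1, 0, 0, 0],     # transversion C<->A
        [2, 2, 2, 2],     # fixed ALT in both: not diagnostic
        [0, 0, 1, 2],     # segregating in B: not diagnostic
    ], dtype=np.int8)
    t = make_table(geno, ["A", "A", "B", "B"],
                   ref=["A", "C", "T", "G"], alt=["G", "A", "C", "T"])
    s = classify_snps(t, ("A", "B"))
    assert s.n_transitions == 2 and s.n_transversions == 2
    assert s.n_transitions + s.n_transversions == t.n_snps
    assert s.n_diagnostic == 1
    assert bool(s.per_snp["diagnostic"][0]) is True
    bad = make_table([[1, 0, 0, 0]], ["A", "A", "B", "B"], ref=["N"])
    with pytest.raises(ValueError):
        classify_snps(bad, ("A", "B"))


def test_simulated_ts_fraction_matches_configuration(adm1_study):
    cfg = SimulationConfig(n_loci=2000, seed=4)
    table = simulate_dataset(adm1_study, cfg)
    s = classify_snps(table, ("pop1", "pop2"))
    frac = s.n_transitions / table.n_snps
    se = math.sqrt(cfg.ts_fraction * (1 - cfg.ts_fraction) / table.n_snps)
    assert abs(frac - cfg.ts_fraction) < 4 * se


def test_filter_chain_order_and_report():
    geno = np.ones((3, 4), dtype=np.int8)
    geno[0, 0] = -1
    t = make_table(geno, ["A", "A", "B", "B"], loci=["L0", "L1", "L2"])
    stages = {"input": t, "complete": completeness_filter(t)}
    rep = filter_report(stages, ("A", "B"))
    assert list(rep["stage"]) == ["input", "complete"]
    assert rep.loc[0, "n_snps"] == 3 and rep.loc[1, "n_snps"] == 2
    assert rep.loc[1, "n_transitions"] == 2


def test_vcf_round_trip(tmp_path, adm1_study):
    cfg = SimulationConfig(n_loci=60, seed=21)
    table = simulate_dataset(adm1_study, cfg)
    vcf = tmp_path / "sim.vcf"
    pm = tmp_path / "popmap.txt"
    table.to_vcf(vcf)
    table.write_popmap(pm)
    again = GenotypeTable.from_vcf(vcf, pm)
    assert again.samples == table.samples
    np.testing.assert_array_equal(again.geno, table.geno)
    assert again.snps.equals(table.snps)
    assert list(again.sample_pops) == list(table.sample_pops)
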