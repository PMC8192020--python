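"""Coalescent-simulator correctness: closed forms, determinism, and an
independent cross-check against msprime on the same translated demography."""

import numpy as np
import pytest

from admixcoal import (SimulationConfig, build_one_pop_model,
                       build_two_pop_model, drop_mutations, expected_sfs,
                       simulate_dataset, simulate_genealogy,
                       simulate_sfs_counts)
from admixcoal import _kernel
from admixcoal.coalsim import locus_seeds_for
from admixcoal.models import ADM1_STUDY_SCALE


def tmrca_sample(model, sample_sizes, n_reps, seed):
    dem = model.compile()
    hap = [2 * n for n in sample_sizes]
    sample_pop = np.repeat(np.arange(len(hap), dtype=np.int64), hap)
    return _kernel.tmrca_many(*dem.as_tuple(), sample_pop,
                              locus_seeds_for(seed, n_reps))


def test_pair_tmrca_constant_size():
    """E[T2] = 2N generations for a pair of lineages, diploid size N."""
    n_diploid = 10_000
    m = build_one_pop_model("CONST", {"NPOP": n_diploid})
    tm = tmrca_sample(m, [1], 20_000, seed=101)  # one diploid = 2 lineages
    se = tm.std() / np.sqrt(tm.size)
    assert abs(tm.mean() - 2 * n_diploid) < 3 * se


def test_degenerate_divergence_equals_single_population():
    """ALD with TDIV1 -> 0 behaves as one ancestral population of size NANC1."""
    params = dict(NPOP1=5e3, NPOP2=5e3, NDIV11=5e3, NDIV12=5e3, NANC1=40_000,
                  TCHG1=0.0, TCHG2=0.0, TDIV1=1e-9)
    m = build_two_pop_model("ALD", params)
    tm = tmrca_sample(m, [1, 1], 8_000, seed=7)  # 4 lineages
    # E[TMRCA] for n=4 in size-N population: 2 * 2N * (1 - 1/4)
    expect = 2 * 2 * 40_000 * (1 - 0.25)
    se = tm.std() / np.sqrt(tm.size)
    assert abs(tm.mean() - expect) < 3 * se


def test_certain_pulse_moves_focal_lineages():
    """ADMIX=1 relocates every focal lineage at TAD: with a tiny donor the
    pair then coalesces almost immediately instead of waiting for TDIV1."""
    base = dict(NPOP1=1e6, NPOP2=100.0, NDIV11=1e6, NDIV12=100.0, NANC1=1e4,
                TCHG1=0.0, TCHG2=0.0, TDIV1=1e6, TAD=10.0)
    certain = build_two_pop_model("ADM1", dict(base, ADMIX=1.0))
    never = build_two_pop_model("ADM1", dict(base, ADMIX=0.0))
    tm_certain = tmrca_sample(certain, [1], 2_000, seed=3)
    tm_never = tmrca_sample(never, [1], 2_000, seed=3)
    assert tm_certain.mean() < 5_000          # ~TAD + 2*100
    assert tm_never.mean() > 5e5              # waits out TDIV1


def test_watterson_segregating_sites():
    """Mean S matches 4 N mu L_total * sum(1/i) under constant size."""
    n_diploid, n_loci, length = 10_000, 20_000, 51
    m = build_one_pop_model("CONST", {"NPOP": n_diploid})
    cfg = SimulationConfig(sample_sizes=(10,), n_loci=n_loci,
                           locus_length=length, seed=8)
    sfs = simulate_sfs_counts(m, cfg, folded=False)
    a = sum(1.0 / i for i in range(1, 20))
    expect = 4 * n_diploid * cfg.mu * n_loci * length * a
    # Var(S) ~ theta*a1 + theta^2*a2 per locus; 3-SE band via binomial-ish bound
    sd = np.sqrt(expect * 1.5)
    assert abs(sfs.total_sites - expect) < 3 * sd


def test_mutation_mean_linear_in_mu():
    m = build_one_pop_model("CONST", {"NPOP": 20_000})
    cfg = SimulationConfig(sample_sizes=(5,), n_loci=4_000, seed=12)
    s1 = simulate_sfs_counts(m, cfg).total_sites
    s2 = simulate_sfs_counts(m, cfg.with_(mu=2 * cfg.mu)).total_sites
    assert s2 / s1 == pytest.approx(2.0, rel=0.15)


def test_zero_mutation_rate_gives_no_sites():
    m = build_one_pop_model("CONST", {"NPOP": 1e4})
    g = simulate_genealogy(m, SimulationConfig(sample_sizes=(5,), seed=1), 0)
    sites = drop_mutations(g, locus_length=51, mu=0.0, seed=4)
    assert sites.shape == (0, 10)


def test_drop_mutations_matches_branch_lengths():
    """Mutation counts are Poisson with mean theta * total branch length."""
    m = build_one_pop_model("CONST", {"NPOP": 50_000})
    cfg = SimulationConfig(sample_sizes=(5,), seed=2)
    totals, expect = [], []
    for l in range(400):
        g = simulate_genealogy(m, cfg, l)
        sites = drop_mutations(g, 51, 1e-6, seed=l)
        totals.append(sites.shape[0])
        expect.append(g.total_branch_length * 1e-6 * 51)
    mean_obs, mean_exp = np.mean(totals), np.mean(expect)
    se = np.std(totals) / np.sqrt(len(totals))
    assert abs(mean_obs - mean_exp) < 3 * se


def test_dataset_determinism_and_layout(adm1_study):
    cfg = SimulationConfig(n_loci=150, seed=77)
    t1 = simulate_dataset(adm1_study, cfg)
    t2 = simulate_dataset(adm1_study, cfg)
    assert t1.snps.equals(t2.snps)
    assert np.array_equal(t1.geno, t2.geno)
    t3 = simulate_dataset(adm1_study, cfg.with_(seed=78))
    assert not (t1.snps.equals(t3.snps) and np.array_equal(t1.geno, t3.geno))
    assert t1.n_samples == 20
    assert set(t1.sample_pops) == {"pop1", "pop2"}
    assert (t1.geno >= 0).all()               # no missing calls by design


def test_empty_dataset():
    m = build_one_pop_model("CONST", {"NPOP": 1e4})
    t = simulate_dataset(m, SimulationConfig(sample_sizes=(3,), n_loci=0, seed=1))
    assert t.n_snps == 0


def test_expected_sfs_normalization_and_shape(adm1_study, study_config):
    sfs = expected_sfs(adm1_study, study_config, 500)
    assert sfs.data[sfs.polymorphic_mask()].sum() == pytest.approx(1.0, abs=1e-12)
    assert sfs.folded and sfs.sample_sizes == (20, 20)


def test_expected_sfs_constant_size_harmonic_shape():
    """Unfolded 1D expectation is proportional to 1/i under constant size."""
    m = build_one_pop_model("CONST", {"NPOP": 10_000})
    cfg = SimulationConfig(sample_sizes=(10,), seed=31)
    sfs = expected_sfs(m, cfg, 20_000, folded=False)
    i = np.arange(1, 20)
    expect = (1.0 / i) / np.sum(1.0 / i)
    assert np.abs(sfs.data[1:20] / expect - 1).max() < 0.08


def test_null_pulse_matches_no_pulse_distribution(study_config):
    """ADM1 with ADMIX=0 and plain ALD give the same expected spectrum up to
    Monte-Carlo error (the pulse consumes RNG draws, so only distributional
    equality is expected)."""
    shared = {k: ADM1_STUDY_SCALE[k] for k in
              ("NPOP1", "NPOP2", "NDIV11", "NDIV12", "NANC1",
               "TCHG1", "TCHG2", "TDIV1")}
    ald = build_two_pop_model("ALD", shared)
    null = build_two_pop_model("ADM1", dict(ADM1_STUDY_SCALE, ADMIX=0.0))
    s1 = expected_sfs(ald, study_config, 15_000)
    s2 = expected_sfs(null, study_config, 15_000)
    tv = 0.5 * np.abs(s1.data - s2.data).sum()
    # self-TV between independent 15k-replicate estimates is ~0.027
    assert tv < 0.045


def test_time_rescaling_exactness(adm1_study, study_config):
    """Jointly rescaling all sizes and times leaves cell assignment of every
    branch untouched: expected proportions are bit-identical and the mean
    tree length scales exactly — a sharp check of the waiting-time algebra."""
    c = 0.25
    scaled = build_two_pop_model("ADM1", {
        k: (v * c if k != "ADMIX" else v)
        for k, v in ADM1_STUDY_SCALE.items()})
    s1, mtl1 = expected_sfs(adm1_study, study_config, 400,
                            return_mean_tree_length=True)
    s2, mtl2 = expected_sfs(scaled, study_config, 400,
                            return_mean_tree_length=True)
    np.testing.assert_allclose(s1.data, s2.data, rtol=1e-12)
    assert mtl2 / mtl1 == pytest.approx(c, rel=1e-12)


def test_counts_match_dataset_spectrum(adm1_study):
    """simulate_sfs_counts shares per-locus streams with simulate_dataset."""
    from admixcoal import joint_sfs_from_genotypes
    cfg = SimulationConfig(n_loci=400, seed=9)
    fast = simulate_sfs_counts(adm1_study, cfg)
    table = simulate_dataset(adm1_study, cfg)
    slow = joint_sfs_from_genotypes(table, ("pop1", "pop2"))
    np.testing.assert_array_equal(fast.data, slow.data)


def test_against_msprime_reference(adm1_study, study_config):
    """Joint folded expected SFS agrees with msprime run on the same
    translated demography (branch-mode AFS, independent implementation)."""
    msprime = pytest.importorskip("msprime")
    p = ADM1_STUDY_SCALE
    dem = msprime.Demography()
    dem.add_population(name="p1", initial_size=p["NPOP1"])
    dem.add_population(name="p2", initial_size=p["NPOP2"])
    dem.add_population(name="anc", initial_size=p["NANC1"])
    for pop, npop, ndiv, tchg in (("p1", "NPOP1", "NDIV11", "TCHG1"),
                                  ("p2", "NPOP2", "NDIV12", "TCHG2")):
        beta = np.log(p[ndiv] / p[npop]) / (p["TDIV1"] - p[tchg])
        dem.add_population_parameters_change(
            time=p[tchg], population=pop, initial_size=p[npop],
            growth_rate=-beta)
    dem.add_mass_migration(time=p["TAD"], source="p1", dest="p2",
                           proportion=p["ADMIX"])
    dem.add_population_split(time=p["TDIV1"], derived=["p1", "p2"],
                             ancestral="anc")
    dem.sort_events()
    n_rep = 8_000
    afs = np.zeros((21, 21))
    reps = msprime.sim_ancestry(
        samples={"p1": 10, "p2": 10}, demography=dem, ploidy=2,
        sequence_length=1, num_replicates=n_rep, random_seed=42)
    for ts in reps:
        sets = [ts.samples(population=0), ts.samples(population=1)]
        afs += ts.allele_frequency_spectrum(
            sample_sets=sets, mode="branch", polarised=True,
            span_normalise=False)
    from admixcoal.spectra import JointSFS
    ref = JointSFS(afs, (20, 20), folded=False).fold().normalized()
    ours = expected_sfs(adm1_study, study_config, n_rep)
    tv = 0.5 * np.abs(ref.data - ours.data).sum()
    # self-TV of one 8k-replicate estimate is ~0.04; two independent
    # estimators differ by ~sqrt(2) of that
    assert tv < 0.065
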