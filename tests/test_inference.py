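"""Likelihood arithmetic, support tables, fitting and bootstrap machinery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from admixcoal import (JointSFS, SimulationConfig, aic,
                       build_one_pop_model, composite_log_likelihood,
                       fit_model, log10_to_ln, parametric_bootstrap,
                       simulate_sfs_counts, support_table)
from admixcoal.inference import snp_plus_monomorphic_ll

# the published two-population support values: (model, k, log10-likelihood)
PUBLISHED = [("ADM1", 10, -6390.633), ("ADM2", 15, -6390.714),
             ("DGF", 10, -6407.783), ("ALD", 8, -6410.675)]


def test_log10_to_ln_published_values():
    assert log10_to_ln(-6390.633) == pytest.approx(-14714.976, abs=5e-4)
    assert log10_to_ln(-6410.675) == pytest.approx(-14761.125, abs=5e-4)
    assert log10_to_ln(0.0) == 0.0


def test_aic_published_values():
    assert aic(log10_to_ln(-6390.633), 10) == pytest.approx(29449.953, abs=1e-3)
    assert aic(log10_to_ln(-6410.675), 8) == pytest.approx(29538.249, abs=1e-3)
    assert aic(0.0, 0) == 0.0


def test_support_table_reproduces_published_cells():
    """Every derivable support-table cell from the printed log10-likelihoods."""
    df = support_table(PUBLISHED).set_index("model")
    assert list(df.index) == ["ADM1", "ADM2", "DGF", "ALD"]
    assert df.loc["ADM1", "AIC"] == pytest.approx(29449.953, abs=1e-3)
    assert df.loc["ADM2", "AIC"] == pytest.approx(29460.326, abs=1e-3)
    assert df.loc["DGF", "AIC"] == pytest.approx(29528.931, abs=1e-3)
    assert df.loc["ALD", "AIC"] == pytest.approx(29538.249, abs=1e-3)
    assert df.loc["ADM2", "delta_AIC"] == pytest.approx(10.373, abs=1e-3)
    assert df.loc["DGF", "delta_AIC"] == pytest.approx(78.979, abs=1e-3)
    assert df.loc["ALD", "delta_AIC"] == pytest.approx(88.297, abs=1e-3)
    assert df.loc["ADM1", "delta_AIC"] == 0.0
    assert df.loc["ADM1", "relative_likelihood"] == 1.0
    assert df.loc["ADM2", "relative_likelihood"] == pytest.approx(8.299e-1,
                                                                  rel=1e-3)
    assert df.loc["DGF", "relative_likelihood"] == pytest.approx(7.079e-18,
                                                                 rel=1e-3)
    assert df.loc["ALD", "relative_likelihood"] == pytest.approx(9.078e-21,
                                                                 rel=1e-3)
    assert df.loc["ADM1", "ln_likelihood"] == pytest.approx(-14714.976,
                                                            abs=5e-4)


def test_aic_increasing_in_k():
    assert aic(-100.0, 5) > aic(-100.0, 4)
    with pytest.raises(ValueError):
        aic(-1.0, -1)


def _sfs_1d(counts, folded=False):
    return JointSFS(np.asarray(counts, dtype=float),
                    (len(counts) - 1,), folded=folded)


def test_composite_likelihood_hand_value():
    """Counts (2, 1) against proportions (2/3, 1/3)."""
    obs = _sfs_1d([0, 2, 1, 0])
    expected = _sfs_1d([0, 2 / 3, 1 / 3, 0])
    got = composite_log_likelihood(obs, expected)
    assert got == pytest.approx(2 * math.log(2 / 3) + math.log(1 / 3),
                                abs=1e-12)
    assert got == pytest.approx(-1.9095, abs=5e-4)


def test_composite_likelihood_uniform_closed_form():
    obs = _sfs_1d([0, 3, 1, 4, 2, 0])          # S = 10 over K = 4 cells
    expected = _sfs_1d([0, 1, 1, 1, 1, 0])
    assert composite_log_likelihood(obs, expected) == pytest.approx(
        10 * math.log(1 / 4))


def test_composite_likelihood_dimension_mismatch():
    with pytest.raises(ValueError):
        composite_log_likelihood(_sfs_1d([0, 1, 0]), _sfs_1d([0, 1, 1, 0]))
    with pytest.raises(ValueError):
        composite_log_likelihood(_sfs_1d([0, 1, 0]),
                                 _sfs_1d([0, 1, 0], folded=True))


@settings(max_examples=50, deadline=None)
@given(st.lists(st.integers(0, 30), min_size=4, max_size=9),
       st.integers(0, 10 ** 6))
def test_gibbs_inequality(counts, seed):
    """The observed proportions maximize the composite likelihood."""
    counts = [0] + counts + [0]
    obs = _sfs_1d(counts)
    s = obs.total_sites
    if s == 0:
        return
    at_obs = composite_log_likelihood(obs, obs.normalized())
    rng = np.random.default_rng(seed)
    q = rng.uniform(0.05, 1.0, size=len(counts))
    q[0] = q[-1] = 0.0
    assert composite_log_likelihood(obs, _sfs_1d(q)) <= at_obs + 1e-9


def test_monomorphic_class_penalizes_wrong_scale():
    """The monomorphic term distinguishes jointly rescaled demographies that
    the SNP-only likelihood cannot."""
    obs = _sfs_1d([0, 5, 3, 2, 0])
    exp = _sfs_1d([0, 0.5, 0.3, 0.2, 0])
    right = snp_plus_monomorphic_ll(obs, exp, mean_tree_length=1e5,
                                    mu=1e-8, total_bp=1e4)
    # q = 1e-3; S=10 observed of 1e4 sites -> q=1e-3 is the MLE scale
    worse = snp_plus_monomorphic_ll(obs, exp, mean_tree_length=1e6,
                                    mu=1e-8, total_bp=1e4)
    assert right > worse
    snp_only = composite_log_likelihood(obs, exp)
    assert snp_plus_monomorphic_ll(obs, exp, 1e5, 1e-8, 1e4) != snp_only


@pytest.fixture(scope="module")
def const_truth():
    model = build_one_pop_model("CONST", {"NPOP": 10_000})
    cfg = SimulationConfig(sample_sizes=(5,), n_loci=1500, seed=42)
    return model, cfg, simulate_sfs_counts(model, cfg)


def test_fit_recovers_constant_population_size(const_truth):
    """One-parameter fit: NPOP recovered within a factor of two."""
    model, cfg, obs = const_truth
    fit = fit_model(obs, "CONST", cfg, n_runs=1, eval_replicates=400,
                    maxiter=15, popsize=8, n_polish=1, seed=5)
    assert 5_000 < fit.params["NPOP"] < 20_000
    assert fit.k == 1
    assert fit.ln_lik == pytest.approx(fit.log10_lik * math.log(10))
    assert fit.aic == pytest.approx(2 * 1 - 2 * fit.ln_lik)
    # the best run is at least as good as every other recorded run
    finals = [r["final_value"] for r in fit.runs]
    assert max(finals) == finals[0]


def test_fit_model_input_validation(const_truth):
    model, cfg, obs = const_truth
    with pytest.raises(ValueError):
        fit_model(obs, "CONST", cfg, n_runs=0)
    with pytest.raises(ValueError):
        fit_model(obs, "CONST", cfg, strategy="magic")


def test_parametric_bootstrap_brackets_truth_and_widens(const_truth):
    model, cfg, obs = const_truth
    mle = {"NPOP": 10_000.0}
    kw = dict(n_runs=1, eval_replicates=300, maxiter=10, popsize=6,
              n_polish=0)
    ci_big = parametric_bootstrap("CONST", mle, cfg, n_boot=8, seed=2, **kw)
    lo, hi = ci_big.interval("NPOP")
    assert lo <= hi
    assert lo < 10_000 < hi
    small_cfg = cfg.with_(n_loci=300)
    ci_small = parametric_bootstrap("CONST", mle, small_cfg, n_boot=8,
                                    seed=2, **kw)
    lo2, hi2 = ci_small.interval("NPOP")
    # fewer loci -> wider interval (on log scale)
    assert math.log(hi2 / lo2) > math.log(hi / lo)


def test_parametric_bootstrap_validation(const_truth):
    model, cfg, obs = const_truth
    with pytest.raises(ValueError):
        parametric_bootstrap("CONST", {"NPOP": 1e4}, cfg, n_boot=1)
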