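"""SFS composite-likelihood fitting, AIC model comparison, bootstrap CIs.

The objective is the multinomial composite likelihood over polymorphic
joint-SFS cells, conditioning on polymorphism (SNP-only data):

    lnL(theta) = sum_cells m_cell * ln max(p_cell(theta), p_floor)

where m are observed cell counts and p the model's expected cell
probabilities, estimated by simulating locus genealogies under theta
(branch-length weighting, see :func:`admixcoal.coalsim.expected_sfs`).
Model support is compared by AIC = 2k - 2 lnL after converting
log10-likelihoods to natural logs; the "relative likelihood" reported
alongside is the likelihood ratio to the best model, 10**(log10L - log10L_best)
(not an Akaike weight — this is the convention the support table uses).

Optimization runs in transformed parameter space (log10 for sizes/times/
rates, logit for admixture proportions): bounded differential evolution
followed by a Powell polish by default, with multi-start Nelder-Mead as an
alternative strategy.
Within a run, every objective evaluation re-uses the same per-locus seeds
(common random numbers), which makes the stochastic objective
quasi-deterministic; final likelihoods are re-evaluated with a larger
seed set shared across models fitted under the same master seed, so AIC
differences are not dominated by Monte-Carlo noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .coalsim import SimulationConfig, expected_sfs, locus_seeds_for, simulate_sfs_counts
from .models import (MODEL_FREE_PARAMS, ModelSpec, ParamBounds, build_model,
                     default_bounds)
from .spectra import JointSFS

__all__ = ["FitResult", "composite_log_likelihood", "snp_plus_monomorphic_ll",
           "log10_to_ln", "aic", "support_table", "fit_model", "fit_competing_models",
           "parametric_bootstrap", "BootstrapCI"]

LN10 = math.log(10.0)

#: floor on expected cell probabilities before taking logs; finite
#: Monte-Carlo expected spectra can leave cells empty
P_FLOOR = 1.0e-8


def log10_to_ln(x: float) -> float:
    """Convert a log10-likelihood to a natural-log likelihood."""
    return x * LN10


def aic(ln_likelihood: float, k: int) -> float:
    """Akaike information criterion 2k - 2 lnL."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return 2.0 * k - 2.0 * ln_likelihood


def composite_log_likelihood(obs: JointSFS, expected: JointSFS,
                             p_floor: float = P_FLOOR) -> float:
    """Multinomial composite ln-likelihood of observed SFS counts.

    ``expected`` carries cell proportions (renormalized here over the
    polymorphic mask); monomorphic cells carry no mass on either side.
    """
    if obs.sample_sizes != expected.sample_sizes:
        raise ValueError(
            f"sample sizes differ: {obs.sample_sizes} vs {expected.sample_sizes}")
    if obs.folded != expected.folded:
        raise ValueError("observed and expected spectra must share foldedness")
    mask = obs.polymorphic_mask()
    m = obs.data[mask]
    p = expected.data[mask]
    tot = p.sum()
    if tot <= 0:
        raise ValueError("expected spectrum has no polymorphic mass")
    p = p / tot
    return float(np.sum(m * np.log(np.maximum(p, p_floor))))


def snp_plus_monomorphic_ll(obs: JointSFS, expected: JointSFS,
                            mean_tree_length: float, mu: float,
                            total_bp: float,
                            p_floor: float = P_FLOOR) -> float:
    """Composite ln-likelihood including the monomorphic site class.

    Adds ``S ln q + (total_bp - S) ln(1 - q)`` to the SNP-only composite
    likelihood, where ``q = mu * mean_tree_length`` is the per-site
    probability of being polymorphic.  The monomorphic class ties the
    likelihood to the mutation rate and total sequenced length, making the
    absolute size/time scale identifiable (SFS proportions alone are
    invariant under jointly rescaling all sizes and times).
    """
    s = obs.total_sites
    m0 = float(total_bp) - s
    if m0 < 0:
        raise ValueError("more segregating sites than sequenced sites")
    q = mu * mean_tree_length
    q = min(max(q, p_floor), 1.0 - 1e-12)
    return (composite_log_likelihood(obs, expected, p_floor=p_floor)
            + s * math.log(q) + m0 * math.log1p(-q))


@dataclass
class FitResult:
    """Best composite-likelihood fit of one model."""

    model_name: str
    params: dict[str, float]
    log10_lik: float
    k: int
    runs: list[dict] = field(default_factory=list)
    settings: dict = field(default_factory=dict)

    @property
    def ln_lik(self) -> float:
        return log10_to_ln(self.log10_lik)

    @property
    def aic(self) -> float:
        return aic(self.ln_lik, self.k)

    def model(self) -> ModelSpec:
        return build_model(self.model_name, self.params)


def support_table(fits) -> pd.DataFrame:
    """Model-support table: k, log10-likelihood, relative likelihood,
    ln-likelihood, AIC and delta-AIC, sorted by AIC (best first).

    ``fits`` is a list of FitResult or of (name, k, log10_likelihood)
    triples (e.g. printed values re-analysed).  Relative likelihood is the
    likelihood ratio to the best model, 10**(log10L - log10L_best).
    """
    rows = []
    for f in fits:
        if isinstance(f, FitResult):
            rows.append((f.model_name, f.k, f.log10_lik))
        else:
            name, k, l10 = f
            rows.append((str(name), int(k), float(l10)))
    if not rows:
        raise ValueError("at least one fit is required")
    df = pd.DataFrame(rows, columns=["model", "k", "log10_likelihood"])
    df["ln_likelihood"] = df["log10_likelihood"] * LN10
    df["AIC"] = 2.0 * df["k"] - 2.0 * df["ln_likelihood"]
    df = df.sort_values(["AIC", "model"], kind="stable").reset_index(drop=True)
    best_l10 = df.loc[0, "log10_likelihood"]
    df["relative_likelihood"] = 10.0 ** (df["log10_likelihood"] - best_l10)
    df["delta_AIC"] = df["AIC"] - df.loc[0, "AIC"]
    return df[["model", "k", "log10_likelihood", "relative_likelihood",
               "ln_likelihood", "AIC", "delta_AIC"]]


from .models import _SIZE_PARAMS as _SCALED_SIZES
from .models import _TIME_PARAMS as _SCALED_TIMES

#: reference size fixed during the shape search under scale profiling
_SCALE_ANCHOR = {
    "CONST": "NPOP", "RECENT_GROWTH": "NANC", "RECENT_DECLINE": "NANC",
    "PASTGROWTH": "NANC", "BOTTLENECK": "NPOP",
    "ALD": "NANC1", "DGF": "NANC1", "ADM1": "NANC1", "ADM2": "NANC1",
}


def _rescale_params(params: dict[str, float], c: float) -> dict[str, float]:
    """Multiply sizes and times by c, migration rates by 1/c."""
    out = {}
    for name, v in params.items():
        if name in _SCALED_SIZES or name in _SCALED_TIMES:
            out[name] = v * c
        elif name in ("MIG12", "MIG21"):
            out[name] = v / c
        else:
            out[name] = v
    return out


def _repair(name: str, p: dict[str, float]) -> dict[str, float]:
    """Project a raw search point onto the model's ordering constraints."""
    p = dict(p)
    if name in ("PASTGROWTH", "BOTTLENECK"):
        lo, hi = sorted((p["TCHG1"], p["TCHG2"]))
        p["TCHG1"], p["TCHG2"] = lo, hi
    if name == "RECENT_GROWTH":
        p["NANC"] = min(p["NANC"], p["NPOP"])
    if name == "RECENT_DECLINE":
        p["NANC"] = max(p["NANC"], p["NPOP"])
    if name in ("ALD", "DGF", "ADM1", "ADM2"):
        p["TCHG1"] = min(p["TCHG1"], p["TDIV1"])
        if name == "ADM2":
            p["TDIV2"] = min(p["TDIV2"], 0.999 * p["TDIV1"])
            p["TAD"] = min(p["TAD"], 0.999 * p["TDIV2"])
            p["TCHG2"] = min(p["TCHG2"], p["TDIV2"])
            p["TCHG3"] = min(p["TCHG3"], p["TDIV2"])
        else:
            p["TCHG2"] = min(p["TCHG2"], p["TDIV1"])
            if name == "ADM1":
                p["TAD"] = min(p["TAD"], 0.999 * p["TDIV1"])
    return p


def fit_model(obs: JointSFS, model_name: str, config: SimulationConfig,
              bounds: dict[str, ParamBounds] | None = None,
              fixed_params: dict[str, float] | None = None,
              n_runs: int = 3, eval_replicates: int = 2000,
              final_replicates: int | None = None,
              seed: int = 0, maxiter: int = 40, popsize: int = 12,
              n_polish: int = 2, strategy: str = "de",
              extra_starts: list[dict[str, float]] | None = None,
              p_floor: float = P_FLOOR, monomorphic: bool = True) -> FitResult:
    """Multi-run composite-likelihood fit of ``model_name`` to ``obs``.

    Search runs in transformed parameter space (log10 for sizes/times/
    rates, logit for admixture proportions) over broad bounds.  Each run
    maximizes the composite likelihood with bounded differential evolution
    (Sobol initialization; ``maxiter`` generations) — or multi-start
    Nelder-Mead with ``strategy='nelder-mead'`` — using
    ``eval_replicates`` genealogies per objective evaluation with common
    random numbers within the run.  ``extra_starts`` (e.g. a fitted nested
    model's parameters) are refined by local Powell searches as additional
    runs; the best ``n_polish`` runs get a higher-fidelity Powell polish.
    Every run's optimum is then re-evaluated with ``final_replicates``
    (default 20x) genealogies whose seeds derive from ``seed`` only, hence
    are shared by every model fitted under the same master seed (common
    random numbers across models), and the winner is chosen on that
    common footing.

    Points violating ordering constraints (e.g. TAD >= TDIV1) are projected
    back onto the constraint surface before evaluation.

    With ``monomorphic`` (default) the monomorphic site class (total
    sequenced length ``config.n_loci * config.locus_length``) enters the
    likelihood through an exact profile over the joint size/time scale:
    SFS proportions are invariant under rescaling all sizes and times by a
    common factor, so the search fixes one reference size (the ancestral
    size) and maximizes the SNP-only likelihood over the remaining shape;
    the scale factor that maximizes the monomorphic term is then
    ``S / (total_bp * mu * mean_tree_length)`` in closed form, and all
    sizes and times are rescaled by it (migration rates inversely).  The
    reported likelihood includes the profiled monomorphic term, which is a
    model-independent constant — AIC differences are unaffected by it.
    Without ``monomorphic`` the SNP-only likelihood is reported and the
    absolute scale is not identifiable.
    """
    if n_runs < 1 and not extra_starts:
        raise ValueError("n_runs must be >= 1 (or extra_starts supplied)")
    if strategy not in ("de", "nelder-mead"):
        raise ValueError(f"unknown strategy {strategy!r}")
    fixed_params = dict(fixed_params or {})
    all_bounds = default_bounds(model_name)
    if bounds:
        all_bounds.update(bounds)
    free = [p for p in MODEL_FREE_PARAMS[model_name] if p not in fixed_params]
    missing = [p for p in free if p not in all_bounds]
    if missing:
        raise ValueError(f"no bounds for parameters {missing}")
    if final_replicates is None:
        # one evaluation per run: can be much larger than search evaluations
        final_replicates = 20 * eval_replicates
    folded = obs.folded
    total_bp = config.n_loci * config.locus_length

    # scale profiling: anchor one size parameter during the shape search
    scale_profile = monomorphic and not (
        set(fixed_params) & (_SCALED_SIZES | _SCALED_TIMES))
    anchor = _SCALE_ANCHOR.get(model_name) if scale_profile else None
    if anchor is not None:
        b = all_bounds[anchor]
        fixed_params[anchor] = math.sqrt(b.low * b.high)  # reference size
        free = [p for p in free if p != anchor]

    def theta_from_x(x: np.ndarray) -> dict[str, float]:
        raw = dict(fixed_params)
        for name, xi in zip(free, x):
            raw[name] = all_bounds[name].inverse(float(xi))
        return _repair(model_name, raw)

    def neg_cll(x: np.ndarray, locus_seeds: np.ndarray) -> float:
        params = theta_from_x(x)
        try:
            model = build_model(model_name, params)
        except ValueError:
            return 1.0e12
        if monomorphic and not scale_profile:
            exp_sfs, mtl = expected_sfs(model, config, len(locus_seeds),
                                        folded=folded,
                                        locus_seeds=locus_seeds,
                                        return_mean_tree_length=True)
            return -snp_plus_monomorphic_ll(obs, exp_sfs, mtl, config.mu,
                                            total_bp, p_floor=p_floor)
        exp_sfs = expected_sfs(model, config, len(locus_seeds),
                               folded=folded, locus_seeds=locus_seeds)
        return -composite_log_likelihood(obs, exp_sfs, p_floor=p_floor)

    def x_from_theta(params: dict[str, float]) -> np.ndarray:
        x = np.empty(len(free))
        for i, name in enumerate(free):
            b = all_bounds[name]
            lo, hi = b.transformed_interval()
            x[i] = min(max(b.transform(params[name]), lo), hi)
        return x

    x_bounds = [all_bounds[p].transformed_interval() for p in free]
    master = np.random.SeedSequence([int(seed), 0x5EED])
    n_extra = len(extra_starts or [])
    run_seeds = master.generate_state(max(n_runs + n_extra, 1),
                                      dtype=np.uint32)
    polish_replicates = min(4 * eval_replicates, final_replicates)
    runs: list[dict] = []

    def _powell(x0, locus_seeds):
        return optimize.minimize(
            neg_cll, x0, args=(locus_seeds,), method="Powell",
            bounds=x_bounds,
            options={"maxiter": 10 * max(len(free), 1),
                     "maxfev": 40 * max(len(free), 1),
                     "xtol": 1e-3, "ftol": 1e-4})

    if not free:
        # nothing to search (e.g. CONST under scale profiling: the single
        # size is recovered entirely from the monomorphic profile)
        runs.append({"run": 0, "start": None, "best_value": np.nan,
                     "n_eval": 0, "params": theta_from_x(np.empty(0)),
                     "x": np.empty(0), "stage": "profile-only"})
    for r in range(n_runs + n_extra if free else 0):
        rng = np.random.default_rng(run_seeds[r])
        locus_seeds = locus_seeds_for(int(run_seeds[r]), eval_replicates,
                                      stream=7)
        if r >= n_runs:
            # local refinement of a supplied start (e.g. nested-model fit),
            # at polish fidelity; under scale profiling the start is first
            # rescaled into the anchored gauge to preserve its shape
            start_params = dict(extra_starts[r - n_runs])
            if anchor is not None and start_params.get(anchor, 0) > 0:
                start_params = _rescale_params(
                    start_params, fixed_params[anchor] / start_params[anchor])
            x0 = x_from_theta({**start_params, **{anchor: fixed_params[anchor]}}
                              if anchor is not None
                              else {**fixed_params, **start_params})
            res = _powell(x0, locus_seeds_for(int(run_seeds[r]),
                                              polish_replicates, stream=8))
            start = theta_from_x(x0)
            stage = "extra-start"
        elif strategy == "de":
            res = optimize.differential_evolution(
                neg_cll, x_bounds, args=(locus_seeds,), seed=rng,
                popsize=popsize, maxiter=maxiter, tol=1e-4, init="sobol",
                mutation=(0.5, 1.0), recombination=0.7, polish=False)
            start = None
            stage = "search"
        else:
            x0 = np.array([rng.uniform(lo, hi) for lo, hi in x_bounds])
            res = optimize.minimize(
                neg_cll, x0, args=(locus_seeds,), method="Nelder-Mead",
                bounds=x_bounds,
                options={"maxiter": maxiter, "fatol": 1e-3, "xatol": 1e-4,
                         "adaptive": len(free) > 4})
            start = theta_from_x(x0)
            stage = "search"
        runs.append({"run": r, "start": start,
                     "best_value": -float(res.fun), "n_eval": int(res.nfev),
                     "params": theta_from_x(res.x), "x": np.array(res.x),
                     "run_seed": int(run_seeds[r]), "stage": stage})
    # polish the best runs with a higher-fidelity local Powell pass
    runs.sort(key=lambda rec: -rec.get("best_value", -np.inf))
    if free:
        for rec in runs[:max(0, n_polish)]:
            seeds = locus_seeds_for(rec["run_seed"], polish_replicates,
                                    stream=8)
            res = _powell(rec["x"], seeds)
            if -float(res.fun) > rec["best_value"]:
                rec.update(best_value=-float(res.fun),
                           params=theta_from_x(res.x),
                           x=np.array(res.x), stage=rec["stage"] + "+polish",
                           n_eval=rec["n_eval"] + int(res.nfev))
    # re-evaluate every run's optimum under a seed set common to every
    # model fitted with the same master seed (CRN across models), and pick
    # the winner by that common-seed likelihood: per-run CRN values carry
    # seed-set-specific offsets that would otherwise distort the choice
    final_seeds = locus_seeds_for(int(seed), final_replicates, stream=11)
    for rec in runs:
        rec["final_value"] = -neg_cll(rec["x"], final_seeds)
    runs.sort(key=lambda rec: -rec["final_value"])
    final_lnl = runs[0]["final_value"]
    params = theta_from_x(runs[0]["x"])
    if scale_profile:
        params, final_lnl = _apply_scale_profile(
            model_name, params, final_lnl, obs, config, folded,
            final_seeds, total_bp)
    for rec in runs:  # strip non-serializable work arrays from the trace
        rec.pop("x", None)
    return FitResult(
        model_name=model_name, params=params,
        log10_lik=final_lnl / LN10, k=len(MODEL_FREE_PARAMS[model_name]),
        runs=runs,
        settings={"n_runs": n_runs, "eval_replicates": eval_replicates,
                  "final_replicates": final_replicates, "seed": int(seed),
                  "maxiter": maxiter, "fixed_params": fixed_params,
                  "monomorphic": monomorphic, "scale_profile": scale_profile})


def _apply_scale_profile(model_name, shape_params, snp_lnl, obs, config,
                         folded, final_seeds, total_bp):
    """Closed-form scale step of the profiled monomorphic likelihood.

    SFS proportions are exactly invariant under multiplying all sizes and
    times by c (migration rates by 1/c), so the monomorphic term
    ``S ln q + (total_bp - S) ln(1 - q)`` with ``q = mu * c * L(shape)``
    is maximized at ``q = S / total_bp``; the rescaled parameters attain
    the profile maximum, and the profiled term is a model-independent
    constant added to the SNP-only likelihood.
    """
    model = build_model(model_name, shape_params)
    _, mtl = expected_sfs(model, config, len(final_seeds), folded=folded,
                          locus_seeds=final_seeds,
                          return_mean_tree_length=True)
    s = obs.total_sites
    q_hat = s / float(total_bp)
    c = q_hat / (config.mu * mtl)
    lnl = snp_lnl + s * math.log(q_hat) + (total_bp - s) * math.log1p(-q_hat)
    return _rescale_params(shape_params, c), lnl


def _translate_params(src: dict[str, float], dst_name: str,
                      bounds: dict[str, ParamBounds]) -> dict[str, float]:
    """Map a fitted model's parameters onto another model's parameter set,
    filling parameters the source model lacks with mild defaults."""
    out = {}
    for name in MODEL_FREE_PARAMS[dst_name]:
        if name in src:
            out[name] = src[name]
            continue
        # extra parameters start at their null boundary so the translated
        # point scores (almost) exactly the source model's likelihood and
        # local refinement can only improve on it
        if name == "ADMIX":
            out[name] = bounds["ADMIX"].low if "ADMIX" in bounds else 1e-4
        elif name == "TAD":
            out[name] = 0.3 * src.get("TDIV1", 1e4)
        elif name in ("MIG12", "MIG21"):
            out[name] = bounds[name].low if name in bounds else 1e-10
        elif name == "TDIV2":
            out[name] = 0.5 * src.get("TDIV1", 1e4)
        elif name == "NPOP3":
            out[name] = src.get("NPOP2", src.get("NPOP", 1e4))
        elif name == "NDIV13":
            out[name] = src.get("NDIV12", src.get("NANC", 1e4))
        elif name == "TCHG3":
            out[name] = src.get("TCHG2", src.get("TCHG", 1e3))
        elif name == "NANC2":
            out[name] = src.get("NANC1", src.get("NANC", 1e4))
        else:
            b = bounds[name]
            lo, hi = b.transformed_interval()
            out[name] = b.inverse(0.5 * (lo + hi))
    # clip into the search box so transforms stay finite
    for name, b in bounds.items():
        if name in out:
            out[name] = min(max(out[name], b.low), b.high)
    return _repair(dst_name, out)


def fit_competing_models(obs: JointSFS, model_names: list[str],
                         config: SimulationConfig, seed: int = 0,
                         cross_starts: bool = True, max_rounds: int = 3,
                         **fit_kwargs) -> dict[str, FitResult]:
    """Fit several models to the same spectrum with symmetric effort.

    After an independent search per model, each model is repeatedly
    refined from every competitor's current fitted parameters (translated
    across parameter sets, extra parameters at their null boundary) until
    no model improves, so that nested pairs cannot be ranked apart by
    optimizer luck alone.  All fits share the master seed, hence the
    common-random-number final evaluation; AIC differences between the
    returned fits are therefore directly comparable.
    """
    fits = {name: fit_model(obs, name, config, seed=seed, **fit_kwargs)
            for name in model_names}
    if not cross_starts or len(model_names) < 2:
        return fits
    for _ in range(max_rounds):
        improved = False
        for name in model_names:
            bounds = default_bounds(name)
            if fit_kwargs.get("bounds"):
                bounds.update(fit_kwargs["bounds"])
            starts = [_translate_params(fits[o].params, name, bounds)
                      for o in model_names if o != name]
            starts.append(dict(fits[name].params))
            kw = dict(fit_kwargs)
            kw.update(n_runs=0, extra_starts=starts, n_polish=0)
            refined = fit_model(obs, name, config, seed=seed, **kw)
            if refined.ln_lik > fits[name].ln_lik + 0.5:
                fits[name] = refined
                improved = True
            elif refined.ln_lik > fits[name].ln_lik:
                fits[name] = refined
        if not improved:
            break
    return fits


@dataclass
class BootstrapCI:
    """Parametric-bootstrap 2.5/97.5% quantiles per parameter."""

    table: pd.DataFrame            # index: parameter; columns: low, high
    estimates: pd.DataFrame        # one row per successful bootstrap refit
    n_boot: int
    seed: int

    def interval(self, param: str) -> tuple[float, float]:
        row = self.table.loc[param]
        return float(row["low"]), float(row["high"])


def parametric_bootstrap(model_name: str, mle_params: dict[str, float],
                         config: SimulationConfig, n_boot: int,
                         seed: int = 0,
                         bounds: dict[str, ParamBounds] | None = None,
                         fixed_params: dict[str, float] | None = None,
                         max_fail_fraction: float = 0.5,
                         **fit_kwargs) -> BootstrapCI:
    """Simulate ``n_boot`` datasets under the fitted model, refit each, and
    return per-parameter 2.5%/97.5% quantiles of the refitted estimates."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    defaults = {"n_runs": 1, "eval_replicates": 800, "maxiter": 20,
                "popsize": 8, "n_polish": 1}
    defaults.update(fit_kwargs)
    model = build_model(model_name, mle_params)
    boot_seeds = np.random.SeedSequence([int(seed), 0xB007]).generate_state(
        n_boot, dtype=np.uint32)
    rows = []
    failures = 0
    for b in range(n_boot):
        bcfg = config.with_(seed=int(boot_seeds[b]) & 0x7FFFFFFF)
        boot_obs = simulate_sfs_counts(model, bcfg, folded=True)
        try:
            fit = fit_model(boot_obs, model_name, config, bounds=bounds,
                            fixed_params=fixed_params,
                            seed=int(boot_seeds[b]) & 0x7FFFFFFF,
                            extra_starts=[dict(mle_params)], **defaults)
        except (RuntimeError, ValueError):
            failures += 1
            continue
        rows.append(fit.params)
    if failures > max_fail_fraction * n_boot:
        raise RuntimeError(
            f"{failures}/{n_boot} bootstrap refits failed "
            f"(> {max_fail_fraction:.0%} allowed)")
    if not rows:
        raise RuntimeError("no successful bootstrap refits")
    est = pd.DataFrame(rows)
    table = pd.DataFrame({
        "low": est.quantile(0.025),
        "high": est.quantile(0.975),
    })
    return BootstrapCI(table=table, estimates=est, n_boot=n_boot,
                       seed=int(seed))
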