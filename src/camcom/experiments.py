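"""Verification experiments: parameter recovery and coverage.

Self-contained, seedable experiments that exercise the estimators on
synthetic data with known truth.  They back the acceptance checks and
the reproducibility script; each returns a plain dict of numbers
computed at run time.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import accumulation, prep, simulate
from .community import AugmentedModelConfig, fit_community_model, richness_summary
from .occupancy import ModelSpec, fit_occupancy, occupancy_neg_loglik, stacked_richness_fit
from .prep import DetectionMatrix


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


# ---------------------------------------------------------------------------
# Likelihood oracle
# ---------------------------------------------------------------------------

def enumeration_neg_loglik(y: np.ndarray, psi: np.ndarray, p: np.ndarray) -> float:
    """Brute-force likelihood: sum over all 2^S joint latent occupancy
    configurations (independent of the closed-form implementation)."""
    y = np.asarray(y, dtype=float)
    total = 0.0
    for zs in itertools.product([0, 1], repeat=y.shape[0]):
        lik = 1.0
        for i, z in enumerate(zs):
            lik *= psi[i] if z else 1.0 - psi[i]
            for obs in y[i][~np.isnan(y[i])]:
                if z:
                    lik *= p[i] if obs else 1.0 - p[i]
                elif obs:
                    lik = 0.0
        total += lik
    return -np.log(total)


def likelihood_oracle_check(n_instances: int = 120, seed: int = 0) -> dict:
    """Compare the model likelihood against latent-state enumeration on
    random small instances (<= 6 sites x <= 4 occasions)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        s, j = rng.integers(1, 7), rng.integers(1, 5)
        y = (rng.random((s, j)) < 0.4).astype(float)
        y[rng.random((s, j)) < 0.2] = np.nan
        b, a = rng.normal(0, 1.5, 2), rng.normal(0, 1.5, 2)
        x1 = np.column_stack([np.ones(s), rng.normal(size=s)])
        x2 = np.column_stack([np.ones(s), rng.normal(size=s)])
        keep = ~np.isnan(y).all(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ours = occupancy_neg_loglik(b, a, y, x1, x2)
        oracle = enumeration_neg_loglik(y[keep], expit(x1 @ b)[keep],
                                        expit(x2 @ a)[keep])
        worst = max(worst, abs(ours - oracle))
    return {"max_abs_diff": worst, "n_instances": n_instances}


# ---------------------------------------------------------------------------
# MLE parameter recovery
# ---------------------------------------------------------------------------

def mle_recovery_experiment(n_datasets: int = 100, n_sites: int = 58,
                            n_occasions: int = 6, psi: float = 0.6,
                            p: float = 0.3, seed: int = 0) -> dict:
    """Wald-interval coverage and bias of the constant occupancy model.

    Histories are simulated directly from the single-season model at the
    given truth; each dataset is fitted and 95% Wald intervals on the
    logit scale are checked against the generating values.
    """
    rng = np.random.default_rng(seed)
    covs = pd.DataFrame({"site_id": [f"s{i}" for i in range(n_sites)]})
    cover_psi = cover_p = n_fit = 0
    biases = []
    for r in range(n_datasets):
        z = rng.random(n_sites) < psi
        y = ((rng.random((n_sites, n_occasions)) < p) & z[:, None]).astype(float)
        if y.sum() == 0:
            continue
        m = DetectionMatrix("x", y, covs["site_id"].tolist())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_occupancy(m, ModelSpec(), covs, n_starts=3, seed=r)
        n_fit += 1
        b, se_b = fit.coef["psi:(Intercept)"], fit.se["psi:(Intercept)"]
        a, se_a = fit.coef["p:(Intercept)"], fit.se["p:(Intercept)"]
        cover_psi += abs(b - logit(psi)) < 1.96 * se_b
        cover_p += abs(a - logit(p)) < 1.96 * se_a
        biases.append(expit(b) - psi)
    return {
        "coverage_psi": cover_psi / n_fit,
        "coverage_p": cover_p / n_fit,
        "median_bias_psi": float(np.median(biases)),
        "n_datasets": n_fit,
    }


# ---------------------------------------------------------------------------
# Guild-detection ordering
# ---------------------------------------------------------------------------

def guild_ordering_experiment(n_reps: int = 50, n_species: int = 24,
                              seed: int = 0) -> dict:
    """Stacked-model recovery of guild-ordered detection.

    Communities are generated with detection fully determined by guild
    (herbivore > omnivore > insectivore > carnivore on the daily logit
    scale, within-guild SD 0) and balanced guild composition; success
    means the stacked estimates order herbivore > omnivore > both
    insectivore and carnivore (the last two are near-tied by design).
    """
    assert n_species % 4 == 0
    params = simulate.CommunityParams(
        n_species_true=n_species, sigma_v=0.0,
        alpha_p={"herbivore": 2.8, "omnivore": 1.5, "insectivore": 0.7})
    seeds = _child_seeds(seed, 3 * n_reps)
    ok = 0
    est = []
    guilds = ("herbivore", "omnivore", "insectivore", "carnivore")
    for r in range(n_reps):
        sites = simulate.simulate_landscape(simulate.LandscapeParams(),
                                            seeds[3 * r])
        species = simulate.simulate_community(params, seeds[3 * r + 1])
        species["guild"] = np.tile(guilds, n_species // 4)
        plan = simulate.default_deployment_plan(sites["site_id"],
                                                failure_prob=0.0)
        records, deployments = simulate.simulate_detections(
            species, sites, plan, params, seeds[3 * r + 2])
        events = prep.collapse_events(records)
        mats = prep.build_all_matrices(events, deployments)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stacked_richness_fit(
                mats, species[["species", "mass_kg", "guild"]], sites,
                model_set=(ModelSpec((), ("guild",)),), seed=r)
        p = res.guild_p.set_index("guild")["p"]
        if set(p.index) >= set(guilds):
            est.append(p[list(guilds)].to_numpy())
            if (p["herbivore"] > p["omnivore"] > p["insectivore"]
                    and p["omnivore"] > p["carnivore"]):
                ok += 1
    mean_p = np.mean(est, axis=0)
    return {
        "recovery_rate": ok / n_reps,
        "n_reps": n_reps,
        "mean_p": dict(zip(("herbivore", "omnivore", "insectivore",
                            "carnivore"), map(float, mean_p))),
    }


# ---------------------------------------------------------------------------
# Community-richness coverage
# ---------------------------------------------------------------------------

def richness_coverage_experiment(n_reps: int = 20, true_n: int = 30,
                                 seed: int = 0,
                                 mcmc: AugmentedModelConfig | None = None) -> dict:
    """95% CRI coverage of true community size over replicate surveys.

    Each replicate is a full default-condition synthetic survey (three
    staggered arrays, ~30 days, guild-structured detection) in which a
    few of the ``true_n`` species go undetected by chance; the augmented
    model's 95% credible interval for N is checked against the truth.
    """
    covered = bounded = 0
    obs_counts, medians = [], []
    seeds = _child_seeds(seed, 2 * n_reps)
    for r in range(n_reps):
        comm = simulate.CommunityParams(n_species_true=true_n)
        ds = simulate.simulate_dataset(community=comm, seed=seeds[2 * r])
        events = prep.collapse_events(ds["records"])
        mats = prep.build_all_matrices(events, ds["deployments"])
        cfg = mcmc or AugmentedModelConfig()
        cfg = AugmentedModelConfig(M=cfg.M, n_chains=cfg.n_chains,
                                   n_iter=cfg.n_iter, burn_in=cfg.burn_in,
                                   thin=cfg.thin, seed=seeds[2 * r + 1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = fit_community_model(mats, cfg)
        s = richness_summary(post)
        lo, hi = s["cri95"]
        covered += lo <= true_n <= hi
        bounded += (post.N >= post.n_observed).all()
        obs_counts.append(s["n_observed"])
        medians.append(s["median"])
    return {
        "coverage": covered / n_reps,
        "n_covered": covered,
        "n_reps": n_reps,
        "all_draws_at_least_observed": bounded == n_reps,
        "mean_observed": float(np.mean(obs_counts)),
        "median_posterior_median": float(np.median(medians)),
    }


# ---------------------------------------------------------------------------
# Accumulation endpoint
# ---------------------------------------------------------------------------

def accumulation_endpoint_check(seeds=(0, 1, 2), seed: int = 0) -> dict:
    """Endpoint invariance on a synthetic survey plus the two-sample
    worked example (step-1 mean 1.5 under order enumeration)."""
    ds = simulate.simulate_dataset(seed=seed)
    events = prep.collapse_events(ds["records"])
    samples = accumulation.daily_species_sets(events, ds["deployments"])
    observed = len(set().union(*samples))
    endpoint_ok = all(
        accumulation.accumulation_curve(samples, n_perm=10, seed=s)
        .mean_richness[-1] == observed
        for s in seeds)
    two = accumulation.accumulation_curve(
        [frozenset({"A"}), frozenset({"A", "B"})], n_perm=4000, seed=seed)
    return {
        "observed_richness": observed,
        "endpoint_invariant": endpoint_ok,
        "two_sample_step1_mean": float(two.mean_richness[0]),
        "two_sample_step2_mean": float(two.mean_richness[1]),
    }
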