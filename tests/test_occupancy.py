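"""Single-season occupancy likelihood, fitting, AIC machinery and the
stacked multi-species model."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from camcom import prep
from camcom.occupancy import (
    AveragedModel,
    ModelSpec,
    build_design,
    fit_occupancy,
    guild_detection,
    load_model,
    model_average,
    occupancy_neg_loglik,
    parameter_importance,
    rank_models,
    save_model,
    stacked_richness_fit,
)
from camcom.prep import DetectionMatrix


def _matrix(values):
    values = np.asarray(values, dtype=float)
    return DetectionMatrix(species="x", values=values,
                           sites=[f"s{i}" for i in range(values.shape[0])])


def _designs(n_sites):
    ones = np.ones((n_sites, 1))
    return ones, ones


def brute_force_neg_loglik(y, psi, p):
    """Oracle: sum the likelihood over every joint latent occupancy
    configuration across sites (2^S terms)."""
    y = np.asarray(y, dtype=float)
    n_sites = y.shape[0]
    total_lik = 0.0
    for zs in itertools.product([0, 1], repeat=n_sites):
        lik = 1.0
        for i, z in enumerate(zs):
            lik *= psi[i] if z else 1.0 - psi[i]
            for j in range(y.shape[1]):
                if np.isnan(y[i, j]):
                    continue
                if z:
                    lik *= p[i] if y[i, j] else 1.0 - p[i]
                elif y[i, j]:
                    lik *= 0.0
        total_lik += lik
    return -np.log(total_lik)


class TestNegLoglik:
    def test_certain_occupancy_reduces_to_bernoulli_product(self):
        m = _matrix([[1, 0, 1]])
        xp, xq = _designs(1)
        # logit(psi) = 40 puts psi at 1 to machine precision
        nll = occupancy_neg_loglik(np.array([40.0]), np.array([0.0]), m, xp, xq)
        assert nll == pytest.approx(-np.log(0.125), abs=1e-9)

    def test_all_zero_history_mixes_in_absence(self):
        m = _matrix([[0, 0]])
        xp, xq = _designs(1)
        nll = occupancy_neg_loglik(np.array([0.0]), np.array([0.0]), m, xp, xq)
        assert nll == pytest.approx(-np.log(0.5 * 0.25 + 0.5), abs=1e-12)

    def test_missing_occasion_contributes_nothing(self):
        m = _matrix([[1, np.nan]])
        xp, xq = _designs(1)
        nll = occupancy_neg_loglik(np.array([0.0]), np.array([0.0]), m, xp, xq)
        assert nll == pytest.approx(-np.log(0.25), abs=1e-12)

    def test_all_missing_site_excluded_with_warning(self):
        m = _matrix([[1, 0], [np.nan, np.nan]])
        xp, xq = _designs(2)
        with pytest.warns(UserWarning, match="all-missing"):
            nll = occupancy_neg_loglik(np.array([0.0]), np.array([0.0]), m, xp, xq)
        assert nll == pytest.approx(-np.log(0.5 * 0.25), abs=1e-12)

    def test_nonfinite_predictor_rejected(self):
        m = _matrix([[1, 0]])
        xp, xq = _designs(1)
        with pytest.raises(ValueError, match="non-finite"):
            occupancy_neg_loglik(np.array([np.inf]), np.array([0.0]), m, xp, xq)

    def test_agrees_with_latent_state_enumeration(self):
        # random small instances against the 2^S brute-force oracle
        rng = np.random.default_rng(42)
        for _ in range(120):
            s = rng.integers(1, 7)
            j = rng.integers(1, 5)
            y = rng.random((s, j)) < 0.4
            y = y.astype(float)
            y[rng.random((s, j)) < 0.2] = np.nan
            b = rng.normal(0, 1.5, 2)
            a = rng.normal(0, 1.5, 2)
            x1 = np.column_stack([np.ones(s), rng.normal(size=s)])
            x2 = np.column_stack([np.ones(s), rng.normal(size=s)])
            psi, p = expit(x1 @ b), expit(x2 @ a)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ours = occupancy_neg_loglik(b, a, _matrix(y), x1, x2)
            keep = ~np.isnan(y).all(axis=1)
            oracle = brute_force_neg_loglik(y[keep], psi[keep], p[keep])
            assert ours == pytest.approx(oracle, abs=1e-10)


def _simulate_histories(rng, n_sites, n_occ, psi, p):
    z = rng.random(n_sites) < psi
    y = (rng.random((n_sites, n_occ)) < p) & z[:, None]
    return y.astype(float)


def _covs(n_sites, rng=None):
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame({
        "site_id": [f"s{i}" for i in range(n_sites)],
        "border_m": rng.uniform(0, 9000, n_sites),
        "edge_m": rng.uniform(0, 4000, n_sites),
        "river_m": rng.uniform(0, 3000, n_sites),
        "habitat": rng.choice(["montane", "lowland"], n_sites),
    })


class TestFit:
    def test_parameter_recovery_large_sample(self):
        rng = np.random.default_rng(1)
        y = _simulate_histories(rng, 500, 6, psi=0.6, p=0.4)
        m = DetectionMatrix("x", y, [f"s{i}" for i in range(500)])
        fit = fit_occupancy(m, ModelSpec(), _covs(500))
        assert fit.converged
        psi_hat = expit(fit.coef["psi:(Intercept)"])
        p_hat = expit(fit.coef["p:(Intercept)"])
        se_psi = fit.se["psi:(Intercept)"]
        assert abs(fit.coef["psi:(Intercept)"] - logit(0.6)) < 3 * se_psi
        assert abs(psi_hat - 0.6) < 0.1 and abs(p_hat - 0.4) < 0.05

    def test_saturated_detections_hit_boundary(self):
        y = np.ones((20, 5))
        m = DetectionMatrix("x", y, [f"s{i}" for i in range(20)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_occupancy(m, ModelSpec(), _covs(20))
        assert fit.boundary
        assert expit(fit.coef["psi:(Intercept)"]) > 0.999
        assert expit(fit.coef["p:(Intercept)"]) > 0.999

    def test_estimated_psi_exceeds_naive_when_detection_imperfect(self):
        rng = np.random.default_rng(5)
        y = _simulate_histories(rng, 200, 4, psi=0.5, p=0.25)
        m = DetectionMatrix("x", y, [f"s{i}" for i in range(200)])
        fit = fit_occupancy(m, ModelSpec(), _covs(200))
        assert expit(fit.coef["psi:(Intercept)"]) > m.naive_occupancy()

    def test_no_detections_rejected(self):
        m = DetectionMatrix("x", np.zeros((5, 4)), [f"s{i}" for i in range(5)])
        with pytest.raises(ValueError, match="no detections"):
            fit_occupancy(m, ModelSpec(), _covs(5))

    def test_covariate_effect_recovery(self):
        rng = np.random.default_rng(7)
        covs = _covs(400, rng)
        z_border = (covs["border_m"] - covs["border_m"].mean()) / covs["border_m"].std(ddof=1)
        psi = expit(0.3 + 1.0 * z_border.to_numpy())
        z = rng.random(400) < psi
        y = ((rng.random((400, 6)) < 0.4) & z[:, None]).astype(float)
        m = DetectionMatrix("x", y, covs["site_id"].tolist())
        fit = fit_occupancy(m, ModelSpec(("border",)), covs)
        est, se = fit.coef["psi:border"], fit.se["psi:border"]
        assert abs(est - 1.0) < 3 * se


class TestModelSelection:
    def test_akaike_weights_from_printed_aic_set(self):
        aics = [1151.59, 1152.57, 1153.59, 1154.56, 1154.56, 1323.63]
        t = rank_models(aics).table
        assert np.allclose(np.round(t["weight"], 2),
                           [0.41, 0.25, 0.15, 0.09, 0.09, 0.00])
        assert t["delta"].iloc[0] == 0.0
        assert t["weight"].sum() == pytest.approx(1.0, abs=1e-10)
        assert (np.diff(t["cum_weight"]) >= -1e-12).all()

    def test_single_model_gets_weight_one(self):
        assert rank_models([100.0]).table["weight"].iloc[0] == 1.0

    def test_equal_aic_models_split_weight(self):
        t = rank_models([10.0, 10.0]).table
        assert np.allclose(t["weight"], [0.5, 0.5])

    def test_weights_invariant_to_aic_shift(self):
        w1 = rank_models([3.0, 5.0, 9.0]).table["weight"]
        w2 = rank_models([103.0, 105.0, 109.0]).table["weight"]
        assert np.allclose(w1, w2)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rank_models([])


def _toy_fit(label_terms, coef, var, loglik):
    names = [f"psi:(Intercept)"] + [f"psi:{t}" for t in label_terms]
    spec = ModelSpec(tuple(label_terms))
    k = len(names) + 1
    names = names + ["p:(Intercept)"]
    coef = list(coef) + [0.0]
    vcov = np.diag(list(var) + [0.1])
    from camcom.occupancy import OccupancyFit
    return OccupancyFit(spec=spec, coef=pd.Series(coef, index=names),
                        k_psi=len(names) - 1, vcov=vcov, loglik=loglik,
                        converged=True, boundary=False)


class TestModelAveraging:
    def test_identical_models_average_to_themselves(self):
        f1 = _toy_fit([], [1.0], [0.04], -10.0)
        f2 = _toy_fit([], [1.0], [0.04], -10.0)
        avg = model_average([f1, f2])
        assert avg.coef["psi:(Intercept)"] == pytest.approx(1.0)
        assert avg.se["psi:(Intercept)"] == pytest.approx(0.2)

    def test_weighted_mean_of_estimates(self):
        # AIC difference chosen so weights are exactly (0.75, 0.25)
        d = 2.0 * np.log(3.0)
        f1 = _toy_fit([], [1.0], [0.0], -10.0)
        f2 = _toy_fit([], [2.0], [0.0], -10.0 - d / 2.0)
        avg = model_average([f1, f2])
        assert np.allclose(avg.weights, [0.75, 0.25])
        assert avg.coef["psi:(Intercept)"] == pytest.approx(1.25)

    def test_result_invariant_to_sub_floor_model(self):
        f1 = _toy_fit([], [1.0], [0.01], -10.0)
        f2 = _toy_fit([], [1.5], [0.01], -11.0)
        f3 = _toy_fit([], [9.0], [0.01], -20.0)   # weight << 0.01
        a12 = model_average([f1, f2])
        a123 = model_average([f1, f2, f3])
        assert a12.coef["psi:(Intercept)"] == pytest.approx(
            a123.coef["psi:(Intercept)"], abs=1e-6)

    def test_full_averaging_counts_absent_terms_as_zero(self):
        # logliks chosen so both models share the same AIC (equal weights)
        f1 = _toy_fit(["border"], [0.0, 2.0], [0.01, 0.01], -9.0)
        f2 = _toy_fit([], [0.0], [0.01], -10.0)
        avg = model_average([f1, f2])
        assert avg.coef["psi:border"] == pytest.approx(1.0)
        nat = model_average([f1, f2], method="natural")
        assert nat.coef["psi:border"] == pytest.approx(2.0)

    def test_no_model_above_floor_rejected(self):
        f1 = _toy_fit([], [1.0], [0.01], -10.0)
        with pytest.raises(ValueError):
            model_average([f1], weight_floor=1.1)

    def test_round_trip_through_json(self, tmp_path):
        f1 = _toy_fit(["border"], [0.2, -0.7], [0.02, 0.03], -12.0)
        avg = model_average([f1])
        save_model(avg, tmp_path / "m.json")
        back = load_model(tmp_path / "m.json")
        assert isinstance(back, AveragedModel)
        pd.testing.assert_series_equal(back.coef, avg.coef)
        assert np.allclose(back.vcov, avg.vcov)


class TestParameterImportance:
    def test_term_in_every_and_no_model(self):
        f1 = _toy_fit(["border"], [0.0, 1.0], [0.01, 0.01], -10.0)
        f2 = _toy_fit(["border"], [0.0, 1.2], [0.01, 0.01], -12.0)
        t = rank_models([f1, f2])
        assert parameter_importance(t, "border") == pytest.approx(1.0)
        with pytest.raises(ValueError, match="appears in no model"):
            parameter_importance(t, "river")

    def test_partial_importance_sums_component_weights(self):
        f1 = _toy_fit(["border"], [0.0, 1.0], [0.01, 0.01], -10.0)
        f2 = _toy_fit([], [0.0], [0.01], -10.0)
        t = rank_models([f1, f2])
        w_border = parameter_importance(t, "psi:border")
        assert w_border == pytest.approx(t.table.set_index("label")
                                         .loc[f1.label, "weight"])


class TestStackedModel:
    def test_default_model_set_parameter_counts(self, matrices, dataset):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stacked_richness_fit(matrices, dataset["traits"],
                                       dataset["sites"], seed=0)
        by_label = {f.label: f.k for f in res.fits}
        assert by_label["psi(.) p(mass, guild)"] == 6
        assert by_label["psi(.) p(guild)"] == 5
        assert by_label["psi(habitat) p(mass, guild)"] == 7
        assert by_label["psi(border) p(guild)"] == 6
        assert by_label["psi(habitat) p(guild)"] == 6
        assert by_label["psi(.) p(.)"] == 2
        assert sorted(by_label.values()) == sorted([6, 5, 7, 6, 6, 2])

    def test_guild_detection_ordering_recovered(self):
        # guild-determined detection with little species noise: the
        # herbivore > omnivore > insectivore ~ carnivore pattern must
        # come back out of the stacked fit
        from camcom.simulate import (CommunityParams, LandscapeParams,
                                     default_deployment_plan,
                                     simulate_community, simulate_detections,
                                     simulate_landscape)
        params = CommunityParams(n_species_true=24, sigma_v=0.25)
        sites = simulate_landscape(LandscapeParams(), seed=21)
        species = simulate_community(params, seed=22)
        plan = default_deployment_plan(sites["site_id"], failure_prob=0.0)
        records, deployments = simulate_detections(species, sites, plan,
                                                   params, seed=23)
        events = prep.collapse_events(records)
        mats = prep.build_all_matrices(events, deployments)
        traits = species[["species", "mass_kg", "guild"]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stacked_richness_fit(mats, traits, sites["site_id"].to_frame()
                                       .merge(sites, on="site_id"),
                                       model_set=(ModelSpec((), ("guild",)),),
                                       seed=3)
        p = res.guild_p.set_index("guild")["p"]
        assert p["herbivore"] > p["omnivore"]
        assert p["omnivore"] > p["insectivore"]
        assert p["omnivore"] > p["carnivore"]

    def test_mass_null_effect_recovered(self, matrices, dataset):
        # generating mass coefficient is near zero: estimate within 3 SE
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stacked_richness_fit(matrices, dataset["traits"],
                                       dataset["sites"], seed=0)
        f = next(f for f in res.fits if "mass" in f.spec.p_terms)
        est, se = f.coef["p:mass"], f.se["p:mass"]
        assert abs(est) < 5 * se + 0.5

    def test_single_guild_rejected(self, matrices, dataset):
        traits = dataset["traits"].copy()
        traits["guild"] = "carnivore"
        with pytest.raises(ValueError, match="non-identifiable|single guild"):
            stacked_richness_fit(matrices, traits, dataset["sites"], seed=0)

    def test_exclusions_shrink_the_stack(self, matrices, dataset):
        drop = list(matrices)[:3]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stacked_richness_fit(matrices, dataset["traits"],
                                       dataset["sites"], exclude=tuple(drop),
                                       seed=0)
        assert res.n_species == len(matrices) - 3
        assert len(res.site_richness) == len(dataset["sites"])
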