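import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar, minimize

import censherit as ch
from censherit.errors import ValidationError
from censherit.gibbs import CensoredGibbsModel, ChainConfig, plan_chain
from censherit.model import CrossSectionalBlock, LongitudinalSpec, ModelSpec


class TestPlanChain:
    def test_published_protocol_retains_20072(self):
        assert plan_chain(2_017_200, 10_000, 100) == 20_072

    def test_no_burn_in_no_thinning(self):
        assert plan_chain(100, 0, 1) == 100

    def test_matches_enumeration_oracle(self):
        n, burn, thin = 1_000_000, 10_000, 37
        retained = sum(1 for it in range(1, n + 1) if it % thin == 0 and it > burn)
        assert plan_chain(n, burn, thin) == retained

    def test_burn_in_must_be_shorter_than_chain(self):
        with pytest.raises(ValidationError):
            plan_chain(100, 100, 1)
        with pytest.raises(ValidationError):
            ChainConfig(n_iterations=50, burn_in_iterations=60)


def _single_trait_model(n_fish=8, censored_bounds=None, seed=0):
    """Minimal longitudinal model: founders-only pedigree, growth rows only.

    ``censored_bounds`` maps fish index -> bound of one extra censored row.
    """
    ids = [f"f{i}" for i in range(n_fish)]
    ped = ch.Pedigree(ids, [""] * n_fish, [""] * n_fish, is_sorted=True)
    rng = np.random.default_rng(seed)
    pheno = pd.DataFrame(
        {"animal": ids, "group": "SW", "year_class": "y", "tank": "t", "sex": "F",
         "FF": np.nan, "FP": np.nan, "VF": np.nan, "GR": np.nan}
    )
    rows = []
    for i, a in enumerate(ids):
        rows.append({"animal": a, "event_index": 0, "age_days": 700.0,
                     "body_weight_g": 700.0 * (5 + rng.standard_normal()),
                     "threshold_g": np.nan, "status": "observed_below_threshold",
                     "sampling_group": "ev0"})
        if censored_bounds and i in censored_bounds:
            rows.append({"animal": a, "event_index": 1, "age_days": 800.0,
                         "body_weight_g": np.nan,
                         "threshold_g": censored_bounds[i] * 800.0,
                         "status": "censored_alive", "sampling_group": "ev1"})
    growth = pd.DataFrame(rows)
    growth["growth_rate"] = growth["body_weight_g"] / growth["age_days"]
    growth["upper_bound"] = np.where(
        growth["status"] == "censored_alive",
        growth["threshold_g"] / growth["age_days"], np.nan)
    spec = ModelSpec(blocks=[], longitudinal=LongitudinalSpec(), fullsib=False)
    return ped, pheno, growth, spec


class TestAugmentation:
    def test_no_censored_rows_is_identity(self):
        ped, pheno, growth, spec = _single_trait_model(4)
        model = CensoredGibbsModel(ped, pheno, growth, spec=spec)
        st = model.init_state()
        before = st.y_long.copy()
        model.augment_censored(st, np.random.default_rng(0))
        assert np.array_equal(st.y_long, before)

    def test_censored_draw_long_run_mean_matches_truncated_normal(self):
        # one censored row, all effects zero, unit residual variance, bound 0
        ped, pheno, growth, spec = _single_trait_model(2, censored_bounds={0: 0.0})
        model = CensoredGibbsModel(ped, pheno, growth, spec=spec)
        st = model.init_state()
        st.a[:] = 0.0
        st.r[:] = 0.0
        for b in st.b_growth:
            b[:] = 0.0
        st.comps.sigma_e_long = 1.0
        idx = np.flatnonzero(model.growth.cens)[0]
        rng = np.random.default_rng(42)
        draws = np.empty(20_000)
        for i in range(draws.size):
            model.augment_censored(st, rng)
            draws[i] = st.y_long[idx]
        target = ch.truncated_normal_mean(0.0, 1.0, 0.0)
        assert (draws <= 0).all()
        assert abs(draws.mean() - target) < 4 * draws.std() / np.sqrt(draws.size)

    def test_multiple_censored_rows_respect_their_own_bounds(self):
        ped, pheno, growth, spec = _single_trait_model(
            4, censored_bounds={0: 4.0, 1: 5.5, 2: 3.0}
        )
        model = CensoredGibbsModel(ped, pheno, growth, spec=spec)
        st = model.init_state()
        rng = np.random.default_rng(3)
        for _ in range(200):
            model.augment_censored(st, rng)
            gd = model.growth
            assert np.all(st.y_long[gd.cens] <= gd.bound[gd.cens])

    def test_missing_imputation_identity_when_complete(self, small_population):
        pop = small_population
        full = pop.phenotypes.copy()
        for c in ("FF", "FP", "VF", "GR"):
            full[c] = full[c].fillna(full[c].mean())
        model = CensoredGibbsModel(pop.pedigree, full, pop.growth)
        st = model.init_state()
        before = [y.copy() for y in st.y_blocks]
        model.augment_missing(st, np.random.default_rng(0))
        for y0, y1 in zip(before, st.y_blocks):
            assert np.array_equal(y0, y1)

    def test_missing_imputation_matches_conditional_gaussian_oracle(self):
        # two correlated traits, one missing: long-run mean of the imputed
        # value must equal the dense-algebra conditional mean
        ids = [f"f{i}" for i in range(3)]
        ped = ch.Pedigree(ids, [""] * 3, [""] * 3, is_sorted=True)
        pheno = pd.DataFrame(
            {"animal": ids, "group": "SA", "year_class": "y", "tank": "t", "sex": "F",
             "FF": [2.0, 2.5, 1.5], "FP": [np.nan, 0.5, 0.3]}
        )
        spec = ModelSpec(
            blocks=[CrossSectionalBlock("SA", "SA", ["FF", "FP"])],
            longitudinal=None, fullsib=False,
        )
        model = CensoredGibbsModel(ped, pheno, None, spec=spec)
        st = model.init_state()
        st.a[:] = 0.0
        st.b_blocks[0][:] = np.array([[1.0], [0.2]])
        R = np.array([[1.0, 0.7], [0.7, 0.8]])
        st.comps.R_blocks = [R]
        rng = np.random.default_rng(8)
        draws = np.empty(30_000)
        for i in range(draws.size):
            model.augment_missing(st, rng)
            draws[i] = st.y_blocks[0][0, 1]
        # conditional of FP given FF=2.0: mean 0.2 + R10/R00*(2.0 - 1.0)
        mean_exact = 0.2 + R[1, 0] / R[0, 0] * (2.0 - 1.0)
        var_exact = R[1, 1] - R[1, 0] ** 2 / R[0, 0]
        assert abs(draws.mean() - mean_exact) < 4 * np.sqrt(var_exact / draws.size)
        assert abs(draws.var() - var_exact) < 0.05 * var_exact


class TestLocationSampling:
    def test_founders_only_shrinkage_closed_form(self):
        # one animal, one record: conditional of a is the textbook shrinkage
        ids = ["f0"]
        ped = ch.Pedigree(ids, [""], [""], is_sorted=True)
        pheno = pd.DataFrame(
            {"animal": ids, "group": "SA", "year_class": "y", "tank": "t",
             "sex": "F", "FF": [2.4]}
        )
        spec = ModelSpec(blocks=[CrossSectionalBlock("SA", "SA", ["FF"])],
                         longitudinal=None, fullsib=False)
        model = CensoredGibbsModel(ped, pheno, None, spec=spec)
        st = model.init_state()
        va, ve, b = 0.5, 1.5, 1.0
        st.comps.G0 = np.array([[va]])
        st.comps.R_blocks = [np.array([[ve]])]
        st.b_blocks[0][:] = b
        rng = np.random.default_rng(1)
        draws = np.empty(40_000)
        for i in range(draws.size):
            model.sample_breeding_values(st, rng)
            draws[i] = st.a[0, 0]
        shrink = va / (va + ve)
        assert abs(draws.mean() - shrink * (2.4 - b)) < 4 * draws.std() / np.sqrt(draws.size)
        var_exact = 1.0 / (1.0 / va + 1.0 / ve)
        assert abs(draws.var() - var_exact) < 0.05 * var_exact

    def test_zero_data_zero_effects_symmetric_conditionals(self):
        ids = [f"f{i}" for i in range(4)]
        ped = ch.Pedigree(ids, [""] * 4, [""] * 4, is_sorted=True)
        pheno = pd.DataFrame(
            {"animal": ids, "group": "SA", "year_class": "y", "tank": "t",
             "sex": "F", "FF": 0.0}
        )
        spec = ModelSpec(blocks=[CrossSectionalBlock("SA", "SA", ["FF"])],
                         longitudinal=None, fullsib=False)
        model = CensoredGibbsModel(ped, pheno, None, spec=spec)
        st = model.init_state()
        st.b_blocks[0][:] = 0.0
        va, ve = 0.5, 1.5
        st.comps.G0 = np.array([[va]])
        st.comps.R_blocks = [np.array([[ve]])]
        rng = np.random.default_rng(2)
        acc = []
        for _ in range(5000):
            model.sample_breeding_values(st, rng)
            acc.append(st.a[:, 0].copy())
        acc = np.array(acc)
        # conditional variance (1/va + 1/ve)^-1 around zero mean
        var_exact = 1.0 / (1.0 / va + 1.0 / ve)
        assert abs(acc.mean()) < 4 * acc.std() / np.sqrt(acc.size)
        assert abs(acc.var() - var_exact) < 0.05 * var_exact

    def test_fixed_effect_posterior_matches_gls_oracle(self):
        # single-trait dataset, variances frozen at truth: the long-run mean
        # of the fixed-effect levels equals the dense GLS (BLUE) solution
        rng = np.random.default_rng(55)
        design = ch.SimulationDesign(n_sires=15, n_dams=30, offspring_per_family_sa=6,
                                     offspring_per_family_sw=1, seed=19)
        sp = ch.simulate_pedigree(design)
        va, vc, ve = 0.4, 0.15, 0.6
        comps = ch.VarianceComponents(G0=np.array([[va]]), C0=np.array([[vc]]),
                                      R_blocks=[np.array([[ve]])])
        eff = ch.simulate_genetic_effects(sp, comps, rng)
        pos = {a: i for i, a in enumerate(sp.pedigree.animal)}
        sa = sp.animals[sp.animals.group == "SA"].reset_index(drop=True)
        rows = np.array([pos[a] for a in sa.animal])
        lvl = (np.arange(len(sa)) % 2)  # two artificial levels
        truth_b = np.array([1.0, 2.5])
        y = truth_b[lvl] + eff.a[rows, 0] + eff.c[sa.family, 0] \
            + np.sqrt(ve) * rng.standard_normal(len(sa))
        pheno = pd.DataFrame({"animal": sa.animal, "group": "SA",
                              "year_class": np.where(lvl == 0, "l0", "l1"),
                              "tank": "t", "sex": "F", "FF": y})
        spec = ModelSpec(blocks=[CrossSectionalBlock("SA", "SA", ["FF"])],
                         longitudinal=None)
        model = CensoredGibbsModel(sp.pedigree, pheno, None, spec=spec)
        st = model.init_state()
        st.comps.G0 = np.array([[va]])
        st.comps.C0 = np.array([[vc]])
        st.comps.R_blocks = [np.array([[ve]])]
        g = np.random.default_rng(20)
        n_iter, burn = 4000, 500
        acc = np.zeros(2)
        for it in range(n_iter):
            model.sample_location_effects(st, g)
            if it >= burn:
                acc += st.b_blocks[0][0]
        b_mean = acc / (n_iter - burn)
        A = ch.build_relationship_matrix(sp.pedigree).A
        fam = sa.family.to_numpy()
        V = (va * A[np.ix_(rows, rows)]
             + vc * (fam[:, None] == fam[None, :])
             + ve * np.eye(y.size))
        X = np.zeros((y.size, 2))
        X[np.arange(y.size), lvl] = 1.0
        Vi_X = np.linalg.solve(V, X)
        b_gls = np.linalg.solve(X.T @ Vi_X, X.T @ np.linalg.solve(V, y))
        post_sd = np.sqrt(np.diag(np.linalg.inv(X.T @ Vi_X)))
        # MC error of a 3,500-draw mean is far below half a posterior SD
        assert np.all(np.abs(b_mean - b_gls) < 0.5 * post_sd)


class TestVarianceSampling:
    def test_inverse_wishart_moment_oracle(self, small_population):
        pop = small_population
        model = CensoredGibbsModel(pop.pedigree, pop.phenotypes, pop.growth)
        st = model.init_state()
        st.a[:] = pop.effects.a
        st.c[:] = pop.effects.c
        rng = np.random.default_rng(9)
        S = st.a.T @ (model.ainv @ st.a)
        df = model.priors.g_df + model.n_animals
        scale = model.priors.g_scale + S
        T = 8
        mean_exact = scale / (df - T - 1)
        acc = np.zeros((T, T))
        n = 3000
        for _ in range(n):
            model.sample_variance_components(st, rng)
            acc += st.comps.G0
        emp = acc / n
        rel = np.abs(emp - mean_exact) / (np.abs(mean_exact) + 1e-2)
        assert rel.max() < 0.1

    def test_prior_dominance_limit(self, small_population):
        pop = small_population
        model = CensoredGibbsModel(pop.pedigree, pop.phenotypes, pop.growth)
        pr = model.priors
        pr.g_df = 1e8
        pr.g_scale = np.eye(8) * 0.25 * 1e8
        st = model.init_state()
        rng = np.random.default_rng(10)
        for _ in range(5):
            model.sample_variance_components(st, rng)
        # with overwhelming prior df, G0 concentrates at scale/df
        assert np.allclose(st.comps.G0, np.eye(8) * 0.25, atol=0.01)

    def test_c2_concentrates_near_zero_without_fullsib_variance(self):
        # data generated with (essentially) no common-fullsib variance
        rng = np.random.default_rng(77)
        design = ch.SimulationDesign(n_sires=100, n_dams=200, offspring_per_family_sa=6,
                                     offspring_per_family_sw=1, seed=31)
        sp = ch.simulate_pedigree(design)
        va, ve = 0.4, 0.6
        comps = ch.VarianceComponents(
            G0=np.array([[va]]), C0=np.array([[1e-8]]), R_blocks=[np.array([[ve]])]
        )
        eff = ch.simulate_genetic_effects(sp, comps, rng)
        pos = {a: i for i, a in enumerate(sp.pedigree.animal)}
        sa = sp.animals[sp.animals.group == "SA"].reset_index(drop=True)
        rows = np.array([pos[a] for a in sa.animal])
        y = 1.0 + eff.a[rows, 0] + np.sqrt(ve) * rng.standard_normal(len(sa))
        pheno = pd.DataFrame({"animal": sa.animal, "group": "SA", "year_class": "y",
                              "tank": "t", "sex": "F", "FF": y})
        spec = ModelSpec(blocks=[CrossSectionalBlock("SA", "SA", ["FF"])], longitudinal=None)
        model = CensoredGibbsModel(sp.pedigree, pheno, None, spec=spec)
        chain = model.run_chain(ChainConfig(n_iterations=4000, burn_in_iterations=1000,
                                            thinning_interval=3, seed=6))
        c2 = chain.C0[:, 0, 0] / (chain.G0[:, 0, 0] + chain.C0[:, 0, 0] + chain.R_blocks[0][:, 0, 0])
        assert np.median(c2) < 0.05


class TestRunChain:
    def test_retained_count_and_determinism(self, small_population):
        pop = small_population
        model = CensoredGibbsModel(pop.pedigree, pop.phenotypes, pop.growth)
        cfg = ChainConfig(n_iterations=60, burn_in_iterations=20, thinning_interval=4, seed=5)
        chain1 = model.run_chain(cfg)
        assert len(chain1) == plan_chain(60, 20, 4)
        chain2 = model.run_chain(cfg)
        assert np.array_equal(chain1.G0, chain2.G0)
        assert np.array_equal(chain1.sigma_e_long, chain2.sigma_e_long)
        assert np.array_equal(chain1.event_mean_draws, chain2.event_mean_draws)
        chain3 = model.run_chain(ChainConfig(n_iterations=60, burn_in_iterations=20,
                                             thinning_interval=4, seed=6))
        assert not np.array_equal(chain1.G0, chain3.G0)

    def test_censoring_consistency_during_sampling(self, small_population):
        pop = small_population
        model = CensoredGibbsModel(pop.pedigree, pop.phenotypes, pop.growth)
        st = model.init_state()
        rng = np.random.default_rng(11)
        gd = model.growth
        for _ in range(30):
            model.sweep(st, rng)
            assert np.all(st.y_long[gd.cens] <= gd.bound[gd.cens] + 1e-12)

    def test_reduction_to_standard_model_matches_reml_oracle(self):
        # single trait, no fullsib, no censoring: posterior means of the two
        # variances agree with a dense REML oracle within 3 posterior SDs
        rng = np.random.default_rng(13)
        n_found = 100
        design = ch.SimulationDesign(n_sires=n_found // 2, n_dams=n_found // 2,
                                     offspring_per_family_sa=8, offspring_per_family_sw=1,
                                     seed=14)
        sp = ch.simulate_pedigree(design)
        va_t, ve_t = 0.4, 0.6
        comps = ch.VarianceComponents(G0=np.array([[va_t]]), C0=None,
                                      R_blocks=[np.array([[ve_t]])])
        eff = ch.simulate_genetic_effects(sp, comps, rng)
        pos = {a: i for i, a in enumerate(sp.pedigree.animal)}
        sa = sp.animals[sp.animals.group == "SA"].reset_index(drop=True)
        rows = np.array([pos[a] for a in sa.animal])
        y = 2.0 + eff.a[rows, 0] + np.sqrt(ve_t) * rng.standard_normal(len(sa))
        pheno = pd.DataFrame({"animal": sa.animal, "group": "SA", "year_class": "y",
                              "tank": "t", "sex": "F", "FF": y})
        spec = ModelSpec(blocks=[CrossSectionalBlock("SA", "SA", ["FF"])],
                         longitudinal=None, fullsib=False)
        model = CensoredGibbsModel(sp.pedigree, pheno, None, spec=spec)
        chain = model.run_chain(ChainConfig(n_iterations=6000, burn_in_iterations=2000,
                                            thinning_interval=4, seed=15))
        va_post = chain.G0[:, 0, 0]
        ve_post = chain.R_blocks[0][:, 0, 0]

        A = ch.build_relationship_matrix(sp.pedigree).A
        Arr = A[np.ix_(rows, rows)]
        X = np.ones((y.size, 1))

        def negll(theta):
            va, ve = np.exp(theta)
            V = va * Arr + ve * np.eye(y.size)
            L = np.linalg.cholesky(V)
            Vi_y = np.linalg.solve(V, y)
            Vi_X = np.linalg.solve(V, X)
            XVX = X.T @ Vi_X
            b = np.linalg.solve(XVX, X.T @ Vi_y)
            r = y - X @ b
            return float(
                2 * np.log(np.diag(L)).sum() + r @ np.linalg.solve(V, r)
                + np.linalg.slogdet(XVX)[1]
            ) / 2

        res = minimize(negll, np.log([0.3, 0.7]), method="Nelder-Mead",
                       options={"xatol": 1e-5, "fatol": 1e-7})
        va_reml, ve_reml = np.exp(res.x)
        assert abs(va_post.mean() - va_reml) < 3 * va_post.std()
        assert abs(ve_post.mean() - ve_reml) < 3 * ve_post.std()


class TestEventMeans:
    def test_no_censoring_estimated_equals_observed(self):
        sched = ch.SlaughterSchedule(
            events=tuple(ch.SlaughterEvent(i + 1, 800.0 + 30 * i, 1e9 if i < 2 else None)
                         for i in range(3)),
            baseline_age_days=700.0,
        )
        design = ch.SimulationDesign(n_sires=6, n_dams=12, offspring_per_family_sa=2,
                                     offspring_per_family_sw=4, schedule=sched,
                                     below_threshold_fraction=1.0, below_threshold_band=1.0,
                                     mortality_rate=0.0, seed=16)
        pop = ch.simulate_population(design)
        assert (pop.growth["status"] != "censored_alive").all()
        model = CensoredGibbsModel(pop.pedigree, pop.phenotypes, pop.growth)
        chain = model.run_chain(ChainConfig(n_iterations=100, burn_in_iterations=20,
                                            thinning_interval=2, seed=17))
        em = ch.estimate_event_means(chain, pop.growth)
        assert np.allclose(em["estimated_mean"], em["observed_mean"])
        assert np.allclose(em["estimated_sd"], 0.0)

    def test_estimated_mean_below_observed_under_selection(self, small_population):
        pop = small_population
        model = CensoredGibbsModel(pop.pedigree, pop.phenotypes, pop.growth)
        chain = model.run_chain(ChainConfig(n_iterations=400, burn_in_iterations=100,
                                            thinning_interval=3, seed=18))
        em = ch.estimate_event_means(chain, pop.growth)
        sel = em[em["n_observed"] < em["n_rows"]]
        assert (sel["estimated_mean"] <= sel["observed_mean"]).all()
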