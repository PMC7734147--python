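import numpy as np
import pandas as pd
import pytest

import censherit as ch
from censherit.errors import DesignError


def _tiny_design(**kw):
    base = dict(
        n_sires=2,
        n_dams=4,
        offspring_per_family_sa=1,
        offspring_per_family_sw=1,
        n_year_classes=1,
        sa_age_days=(896.0,),
        seed=1,
    )
    base.update(kw)
    return ch.SimulationDesign(**base)


class TestSimulatePedigree:
    def test_counts_2x4x2(self):
        sp = ch.simulate_pedigree(_tiny_design())
        assert len(sp.pedigree) == 2 + 4 + 4 * 2
        assert len(sp.families) == 4
        assert sp.animals.groupby("family").size().eq(2).all()

    def test_equal_sires_and_dams_gives_monogamy(self):
        sp = ch.simulate_pedigree(_tiny_design(n_sires=4, n_dams=4))
        per_sire = sp.families.groupby("sire").size()
        assert (per_sire == 1).all()

    def test_nested_design_dams_per_sire_in_one_or_two(self):
        design = ch.SimulationDesign(n_sires=120, n_dams=206, seed=3)
        sp = ch.simulate_pedigree(design)
        per_sire = sp.families.groupby("sire").size()
        assert set(per_sire.unique()) <= {1, 2}
        assert len(sp.families) == 206

    def test_infeasible_design_rejected(self):
        with pytest.raises(DesignError, match="infeasible"):
            _tiny_design(n_sires=2, n_dams=5)
        with pytest.raises(DesignError, match="n_dams >= n_sires"):
            _tiny_design(n_sires=5, n_dams=4)

    def test_group_split_sizes_per_family(self, small_population):
        sizes = small_population.animals.groupby(["family", "group"]).size().unstack()
        assert (sizes["SA"] == small_population.design.offspring_per_family_sa).all()
        assert (sizes["SW"] == small_population.design.offspring_per_family_sw).all()


class TestGeneticEffects:
    def test_zero_variance_components_give_zero_effects(self):
        design = _tiny_design()
        sp = ch.simulate_pedigree(design)
        eps = 1e-12  # components must stay PD; tiny variance stands in for zero
        comps = ch.VarianceComponents(
            G0=np.eye(8) * eps,
            C0=np.eye(8) * eps,
            R_blocks=[np.eye(4), np.eye(3)],
            sigma_e_long=1.0,
            sigma_r=eps,
        )
        eff = ch.simulate_genetic_effects(sp, comps, np.random.default_rng(0))
        assert np.abs(eff.a).max() < 1e-5
        assert np.abs(eff.c).max() < 1e-5
        assert np.abs(eff.r).max() < 1e-5

    def test_founder_variance_matches_target(self):
        design = ch.SimulationDesign(n_sires=5000, n_dams=5000, offspring_per_family_sa=1,
                                     offspring_per_family_sw=1, seed=2)
        sp = ch.simulate_pedigree(design)
        comps = ch.paper_like_components()
        eff = ch.simulate_genetic_effects(sp, comps, np.random.default_rng(3))
        founders = eff.a[: 10_000]
        emp = founders.var(axis=0)
        target = np.diag(comps.G0)
        assert np.all(np.abs(emp - target) < 0.05 * target + 1e-3)

    def test_fullsib_breeding_value_covariance_is_half_G0(self):
        # many replicate families; non-inbred fullsib pairs have cov 0.5*G0
        design = ch.SimulationDesign(n_sires=2500, n_dams=5000, offspring_per_family_sa=1,
                                     offspring_per_family_sw=1, seed=4)
        sp = ch.simulate_pedigree(design)
        comps = ch.paper_like_components()
        eff = ch.simulate_genetic_effects(sp, comps, np.random.default_rng(5))
        n_found = 7500
        a_off = eff.a[n_found:]
        fam = sp.animals["family"].to_numpy()
        order = np.argsort(fam, kind="stable")
        pairs = a_off[order].reshape(-1, 2, 8)
        cross = np.einsum("nt,nu->tu", pairs[:, 0], pairs[:, 1]) / pairs.shape[0]
        target = 0.5 * comps.G0
        scale = np.sqrt(np.outer(np.diag(comps.G0), np.diag(comps.G0)))
        assert np.all(np.abs(cross - target) < 0.08 * scale + 5e-3)

    def test_non_pd_components_rejected(self):
        design = _tiny_design()
        sp = ch.simulate_pedigree(design)
        bad = ch.VarianceComponents(
            G0=np.array([[1.0, 2.0], [2.0, 1.0]]),  # indefinite
            C0=np.eye(2),
            R_blocks=[np.eye(2)],
        )
        with pytest.raises(ch.ValidationError, match="G0"):
            ch.simulate_genetic_effects(sp, bad, np.random.default_rng(0))


class TestSlaughterProtocol:
    def test_unreachable_thresholds_defer_everyone_to_final_event(self):
        sched = ch.SlaughterSchedule(
            events=tuple(
                ch.SlaughterEvent(i + 1, 800.0 + 30 * i, 1e9 if i < 5 else None)
                for i in range(6)
            ),
            baseline_age_days=700.0,
        )
        design = ch.SimulationDesign(
            n_sires=4, n_dams=8, offspring_per_family_sa=2, offspring_per_family_sw=5,
            schedule=sched, mortality_rate=0.0, below_threshold_fraction=0.0, seed=9,
        )
        pop = ch.simulate_population(design)
        sw_fish = 8 * 5
        slaughtered = pop.growth[pop.growth["status"] == "observed_slaughtered"]
        assert (slaughtered["event_index"] == 6).all()
        assert len(slaughtered) == sw_fish
        cens = pop.growth[pop.growth["status"] == "censored_alive"]
        assert len(cens) == sw_fish * 5  # every fish censored at events 1..5

    def test_threshold_boundary_counts(self):
        # three latent weights around a 4.2 kg threshold: ties slaughter
        assert (4500.0 >= 4200.0) and (4300.0 >= 4200.0) and not (4100.0 >= 4200.0)
        # realized in simulation: every observed_slaughtered row is at/above threshold
        design = ch.SimulationDesign(n_sires=10, n_dams=20, offspring_per_family_sa=2,
                                     offspring_per_family_sw=10, seed=10)
        pop = ch.simulate_population(design)
        sl = pop.growth[(pop.growth["status"] == "observed_slaughtered")
                        & pop.growth["threshold_g"].notna()]
        assert (sl["body_weight_g"] >= sl["threshold_g"]).all()
        cens = pop.growth[pop.growth["status"] == "censored_alive"]
        assert cens["growth_rate"].isna().all()
        assert (cens["upper_bound"] == cens["threshold_g"] / cens["age_days"]).all()

    def test_conservation_every_fish_slaughtered_once_or_dead(self, small_population):
        g = small_population.growth
        ends = g[g["status"].isin(["observed_slaughtered", "dead"])]
        sw = small_population.animals.query("group == 'SW'")["animal"]
        assert ends.groupby("animal").size().eq(1).all()
        assert set(ends["animal"]) == set(sw)

    def test_record_counts_within_two_to_ten_for_slaughtered_fish(self, small_population):
        g = small_population.growth
        dead = set(g.loc[g["status"] == "dead", "animal"])
        live = g[~g["animal"].isin(dead)]
        per_fish = live.groupby("animal").size()
        assert per_fish.between(2, 10).all()

    def test_observed_mean_growth_declines_over_slaughter_events(self):
        # the decline is a property of the paper-scale design; small samples
        # can reorder adjacent event means by chance
        design = ch.SimulationDesign(n_sires=60, n_dams=120, offspring_per_family_sa=2,
                                     offspring_per_family_sw=14, seed=21)
        g = ch.simulate_population(design).growth
        obs = g[g["status"].str.startswith("observed") & (g["event_index"] >= 1)]
        for yc in ("yc1", "yc2"):
            m = (
                obs[obs["sampling_group"].str.startswith(yc)]
                .groupby("event_index")["growth_rate"]
                .mean()
            )
            assert (m.diff().dropna() < 0).all(), f"means not decreasing in {yc}: {m.values}"

    def test_observed_rows_satisfy_growth_identity(self, small_population):
        g = small_population.growth
        obs = g[g["status"].str.startswith("observed")]
        assert np.allclose(obs["growth_rate"], obs["body_weight_g"] / obs["age_days"])

    def test_selection_gap_observed_exceeds_truth_at_threshold_events(self, small_population):
        g = small_population.growth
        truth = small_population.truth
        obs = (
            g[g["status"].str.startswith("observed")]
            .assign(year_class=lambda d: d["sampling_group"].str.split(":").str[0])
            .groupby(["year_class", "event_index"])["growth_rate"]
            .mean()
            .rename("observed")
            .reset_index()
        )
        m = obs.merge(truth, on=["year_class", "event_index"])
        sel = m[(m["event_index"] >= 1) & (m["event_index"] <= 5)]
        gap = sel["observed"] - sel["true_mean_gr"]
        assert (gap > 0).all()

    def test_no_selection_means_match_fixed_effects(self):
        # thresholds removed: phenotype means equal the fixed-effect values within MC error
        sched = ch.SlaughterSchedule(
            events=tuple(
                ch.SlaughterEvent(i + 1, 800.0 + 30 * i, 1e9 if i < 5 else None)
                for i in range(6)
            ),
            baseline_age_days=700.0,
        )
        design = ch.SimulationDesign(
            n_sires=60, n_dams=120, offspring_per_family_sa=8, offspring_per_family_sw=8,
            n_year_classes=1, sa_age_days=(896.0,), schedule=sched,
            mortality_rate=0.0, missing_rate=0.0, seed=12,
        )
        pop = ch.simulate_population(design)
        fe = design.fixed_effects
        sa = pop.phenotypes.query("group == 'SA'")
        for col, t in (("FF", 0), ("FP", 1), ("VF", 2), ("GR", 3)):
            target = fe.trait_means[t, 0] + 0.5 * fe.sex_effects[t]
            tol = 4 * np.sqrt(ch.model.VP_TRUE[t] / len(sa)) + 0.1 * abs(fe.sex_effects[t])
            assert abs(sa[col].mean() - target) < tol

    def test_dead_fish_have_no_rows_after_death(self, small_population):
        g = small_population.growth
        dead = g[g["status"] == "dead"]
        for animal, ev in zip(dead["animal"], dead["event_index"]):
            rows = g[g["animal"] == animal]
            assert rows["event_index"].max() == ev


class TestCountRecords:
    def test_single_fish_histogram(self):
        g = pd.DataFrame(
            {
                "animal": ["f"] * 3,
                "status": ["observed_below_threshold", "censored_alive", "observed_slaughtered"],
            }
        )
        h = ch.count_records(g)
        assert h["observed_and_censored"] == {3: 1}
        assert h["observed"] == {2: 1}

    def test_empty_table(self):
        h = ch.count_records(pd.DataFrame(columns=["animal", "status"]))
        assert h == {"observed": {}, "observed_and_censored": {}}

    def test_bookkeeping_identity_on_simulation(self, small_population):
        g = small_population.growth
        h = ch.count_records(g)
        n_rows = sum(k * v for k, v in h["observed_and_censored"].items())
        assert n_rows == (g["status"] != "dead").sum()
        n_fish = sum(h["observed_and_censored"].values())
        assert n_fish == g.loc[g["status"] != "dead", "animal"].nunique()


class TestScheduleValidation:
    def test_ages_must_increase(self):
        with pytest.raises(DesignError, match="increasing"):
            ch.SlaughterSchedule(
                events=(
                    ch.SlaughterEvent(1, 900.0, 4200.0),
                    ch.SlaughterEvent(2, 800.0, None),
                ),
            )

    def test_final_event_has_no_threshold(self):
        with pytest.raises(DesignError, match="final"):
            ch.SlaughterSchedule(
                events=(
                    ch.SlaughterEvent(1, 800.0, 4200.0),
                    ch.SlaughterEvent(2, 900.0, 4400.0),
                ),
            )

    def test_missing_intermediate_threshold_rejected(self):
        with pytest.raises(DesignError, match="threshold"):
            ch.SlaughterSchedule(
                events=(
                    ch.SlaughterEvent(1, 800.0, None),
                    ch.SlaughterEvent(2, 900.0, None),
                ),
            )
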