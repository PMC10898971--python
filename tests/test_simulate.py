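import pandas as pd
import pytest

import flukemr as fm
from flukemr.errors import ValidationError


def tiny_config(**kwargs):
    defaults = dict(
        start_year=2004,
        end_year=2007,
        initial_abundance={"Hawaii": 400, "MexMld": 200},
        fidelity={"Hawaii": {"SEAKNBC": 1.0}, "MexMld": {"CAOR": 1.0}},
        capture_prob={"Hawaii": 0.3, "MexMld": 0.3, "SEAKNBC": 0.3, "CAOR": 0.3},
        effort_ramp=(1.0, 1.0),
        seed=5,
    )
    defaults.update(kwargs)
    return fm.SimConfig(**defaults)


class TestSimulate:
    def test_reproducible_under_seed(self):
        a = fm.simulate(tiny_config())
        b = fm.simulate(tiny_config())
        pd.testing.assert_frame_equal(a.encounters, b.encounters)
        pd.testing.assert_series_equal(a.truth.n_true, b.truth.n_true)

    def test_conservation_of_individuals(self):
        out = fm.simulate(tiny_config(end_year=2012))
        demo = out.truth.demography.set_index("year")
        for year in demo.index:
            assert (
                out.truth.n_true.at[year + 1]
                == demo.at[year, "survivors"] + demo.at[year, "recruits"]
            )

    def test_zero_detection_probability_yields_no_encounters(self):
        out = fm.simulate(
            tiny_config(capture_prob={k: 0.0 for k in ("Hawaii", "MexMld", "SEAKNBC", "CAOR")})
        )
        assert out.encounters.empty
        assert (out.truth.n_true > 0).all()
        assert (out.truth.cell_counts["detected"] == 0).all()

    def test_census_limit_recovers_truth_exactly(self, strata):
        """s=1, b=0, p=1: everyone is seen every season, so the two-occasion
        estimate equals the true (constant) population size exactly."""
        config = tiny_config(
            initial_abundance={"Hawaii": 300},
            fidelity={"Hawaii": {"SEAKNBC": 1.0}},
            capture_prob={"Hawaii": 1.0, "SEAKNBC": 1.0},
            survival=1.0,
            growth_rate=0.0,
            decline_rate=0.0,
            pivot_year=2006,
        )
        # survival 1 + zero growth target => recruitment 0
        assert config.recruitment_rate(2005) == 0.0
        out = fm.simulate(config)
        captures, report = fm.condense(out.encounters, strata)
        assert report.n_unassigned == 0 and report.n_class_mismatch == 0
        c = fm.count_two_samples(captures, fm.EstimationWindow(2005))
        assert c.n1 == c.n2 == c.m == 300
        assert fm.chapman_estimate(c.n1, c.n2, c.m) == 300.0

    def test_detected_counts_consistent_with_histories(self):
        out = fm.simulate(tiny_config())
        per_cell = (
            out.truth.histories.groupby(["stratum", "season", "season_year"])
            .size()
            .rename("n")
            .reset_index()
        )
        merged = out.truth.cell_counts.merge(
            per_cell, on=["stratum", "season", "season_year"], how="left"
        )
        merged["n"] = merged["n"].fillna(0).astype(int)
        assert (merged["detected"] == merged["n"]).all()
        assert (merged["detected"] <= merged["present"]).all()
        assert (
            merged.groupby("season_year")["present"].max()
            <= out.truth.n_true.max()
        ).all()

    def test_encounters_fall_within_their_stratum_and_season(self, strata):
        out = fm.simulate(tiny_config())
        captures, report = fm.condense(out.encounters, strata)
        assert report.n_unassigned == 0
        assert report.n_class_mismatch == 0
        # detected individuals and condensed captures agree one-to-one
        hist = out.truth.histories
        assert len(captures) == len(hist)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValidationError):
            fm.simulate(tiny_config(capture_prob={"Hawaii": 1.5}))
        with pytest.raises(ValidationError):
            fm.simulate(
                tiny_config(fidelity={"Hawaii": {"SEAKNBC": 0.6}, "MexMld": {"CAOR": 1.0}})
            )
        with pytest.raises(ValidationError):
            fm.simulate(tiny_config(survival=1.2))

    def test_growth_then_decline_default_trajectory(self, small_sim):
        """The default demographic schedule grows ~6%/yr before the pivot."""
        n = small_sim.truth.n_true
        rates = n.pct_change().dropna()
        assert (rates > 0.03).all()  # growth phase at quarter scale, pre-pivot
        assert rates.mean() == pytest.approx(0.06, abs=0.02)


def test_jackknife_interval_covers_truth():
    """±2 s.e. intervals from the jackknifed corrected estimator cover the
    simulated truth in 85-99% of replicates (a wide band: the delete-d
    jackknife is an approximation, not an exact interval)."""
    import warnings

    import numpy as np

    strata = fm.default_strata()
    window = fm.EstimationWindow(2006)
    cover, reps = 0, 100
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(reps):
            cfg = fm.SimConfig(
                start_year=2004, end_year=2008,
                initial_abundance={"Hawaii": 900, "MexMld": 600},
                fidelity={
                    "Hawaii": {"SEAKNBC": 0.9, "CAOR": 0.1},
                    "MexMld": {"CAOR": 0.9, "SEAKNBC": 0.1},
                },
                capture_prob={
                    "Hawaii": 0.2, "MexMld": 0.15, "SEAKNBC": 0.2, "CAOR": 0.15,
                },
                effort_ramp=(1.0, 1.0), growth_rate=0.0, decline_rate=0.0,
                pivot_year=2006, seed=50_000 + i,
            )
            out = fm.simulate(cfg)
            caps, _ = fm.condense(out.encounters, strata)
            ref = fm.splash_like_reference(out, strata, mid_year=2005)
            truth = out.truth.n_true.at[2006]
            rng = np.random.default_rng(i)
            est = fm.correction_factor(
                ref, caps, window, n_replicates=3, rng=rng
            ).n_t

            def corrected(sub, _r=rng, _ref=ref):
                return fm.correction_factor(
                    _ref, sub, window, n_replicates=3, rng=_r
                ).n_t

            jk = fm.jackknife_se(corrected, caps, n_replicates=10, rng=rng)
            cover += (est - 2 * jk.se) <= truth <= (est + 2 * jk.se)
    assert 0.85 <= cover / reps <= 0.99


class TestHeatwaveScenario:
    def test_zero_penalties_return_config_unchanged(self):
        config = tiny_config()
        assert fm.heatwave_scenario(config, (2005,), 0.0, 0.0) is config

    def test_pulse_outside_range_rejected(self):
        with pytest.raises(ValidationError):
            fm.heatwave_scenario(tiny_config(), (1999,), 0.05, 0.5)

    def test_survival_pulse_produces_decline(self):
        config = tiny_config(
            end_year=2012,
            growth_rate=0.0,
            decline_rate=0.0,
            pivot_year=2013,
            initial_abundance={"Hawaii": 2000, "MexMld": 1000},
        )
        pulsed = fm.heatwave_scenario(
            config, pulse_years=(2007, 2008, 2009),
            survival_penalty=0.05, recruitment_penalty=1.0,
        )
        out = fm.simulate(pulsed)
        n = out.truth.n_true
        assert n.at[2010] < n.at[2007]
        assert n.at[2012] < n.at[2007]


class TestSplashLikeReference:
    def test_reference_matches_truth_and_window(self, small_sim, small_reference):
        assert small_reference.n_ref == small_sim.truth.n_true.at[2005]
        assert small_reference.window.mid_year == 2005
        winters = small_reference.captures[
            small_reference.captures["season"] == "winter"
        ]["season_year"].unique()
        assert set(winters) == {2004, 2005, 2006}

    def test_uncovered_window_rejected(self, small_sim):
        with pytest.raises(ValidationError):
            fm.splash_like_reference(small_sim, mid_year=2020)
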