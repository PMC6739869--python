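"""The agent-based generator: determinism, schedule statistics, phenotype structure."""

import numpy as np
import pytest

from pavca.io import score_trials, trials_to_event_log
from pavca.metrics import summarize_session
from pavca.scoring import pavca_index
from pavca.synth import (
    CohortDesign,
    TrialConfig,
    expected_session_duration_min,
    make_agent,
    simulate_cohort,
    simulate_dialysis_series,
    simulate_pavca_session,
    theta_at_session,
)


class TestMakeAgent:
    def test_phenotype_signs_forced(self):
        assert make_agent("ST", 1).theta_asym > 0
        assert make_agent("GT", 1).theta_asym < 0
        assert make_agent("IN", 1).theta_asym == 0

    def test_deterministic_for_fixed_seed(self):
        assert make_agent("ST", 1) == make_agent("ST", 1)
        assert make_agent("ST", 1) != make_agent("ST", 2)

    def test_unknown_phenotype_rejected(self):
        with pytest.raises(ValueError, match="phenotype"):
            make_agent("XX", 1)

    def test_theta_stays_clamped(self):
        agent = make_agent("ST", 3, treat_shift=2.0)
        for s in range(1, 20):
            assert -1.0 <= theta_at_session(agent, s, treated=True) <= 1.0


class TestSimulateSession:
    def test_theta_plus_one_always_lever(self, rng):
        agent = make_agent("ST", 1, theta0=1.0, theta_asym=1.0, respond_prob=1.0)
        trials = simulate_pavca_session(agent, 1, rng=rng)
        assert len(trials) == 25
        assert all(t.lever_events for t in trials)
        assert all(not t.mag_events_cs for t in trials)

    def test_theta_minus_one_always_magazine(self, rng):
        agent = make_agent("GT", 1, theta0=-1.0, theta_asym=-1.0, respond_prob=1.0)
        trials = simulate_pavca_session(agent, 1, rng=rng)
        assert all(not t.lever_events for t in trials)
        assert all(t.mag_events_cs for t in trials)

    def test_theta_zero_allocation_is_binomial_half(self, rng):
        """Lever-trial fraction over 10^4 trials within 3 SE of 0.5."""
        agent = make_agent("IN", 1, theta0=0.0, learn_rate=0.0, respond_prob=1.0)
        n_lever = n_total = 0
        for _ in range(400):
            for t in simulate_pavca_session(agent, 1, rng=rng):
                n_total += 1
                n_lever += bool(t.lever_events)
        se = 0.5 / np.sqrt(n_total)
        assert abs(n_lever / n_total - 0.5) < 3 * se

    def test_iti_mean_within_one_percent(self, rng):
        """Mean simulated ITI over >= 10^4 trials within 1% of the schedule mean."""
        agent = make_agent("IN", 1)
        itis = []
        for _ in range(400):
            trials = simulate_pavca_session(agent, 1, rng=rng)
            prev_off = 0.0
            for t in trials:
                itis.append(t.cs_on_s - prev_off)
                prev_off = t.cs_off_s
        assert len(itis) >= 10_000
        assert abs(np.mean(itis) - 90.0) / 90.0 < 0.01
        assert min(itis) >= 30.0 - 1e-3 and max(itis) <= 150.0 + 1e-3

    def test_extreme_agents_measured_index_converges_to_extremes(self, rng):
        for pheno, sign in (("ST", 1.0), ("GT", -1.0)):
            agent = make_agent(
                pheno, 1, theta0=sign, theta_asym=sign, respond_prob=1.0,
                lat_scale_s=1e-6,
            )
            trials = simulate_pavca_session(agent, 1, rng=rng)
            sc = pavca_index(summarize_session(trials))
            assert sc.index == pytest.approx(sign, abs=1e-3)

    def test_pellet_after_every_cs(self, rng):
        trials = simulate_pavca_session(make_agent("ST", 1), 1, rng=rng)
        assert all(t.pellet_retrieved for t in trials)


class TestSimulateCohort:
    def test_byte_identical_for_fixed_seed(self):
        design = CohortDesign(n_per_cell=3, seed=7)
        log1 = trials_to_event_log(simulate_cohort(design)[0]).to_csv(index=False)
        log2 = trials_to_event_log(simulate_cohort(design)[0]).to_csv(index=False)
        assert log1 == log2

    def test_adding_rats_preserves_existing_ones(self):
        """Per-rat substreams: a larger cohort reproduces the smaller one's rats."""
        small = CohortDesign(n_per_cell=2, seed=5)
        big = CohortDesign(n_per_cell=4, seed=5)
        t_small, _ = simulate_cohort(small)
        t_big, _ = simulate_cohort(big)
        small_ids = {t.rat_id for t in t_small}
        big_subset = [t for t in t_big if t.rat_id in small_ids]
        assert big_subset == t_small

    def test_treatment_shift_applies_only_from_onset(self):
        design = CohortDesign(
            n_per_cell=2, seed=3, treat_shifts={"ST": -0.5, "GT": -0.5}
        )
        _, truth = simulate_cohort(design)
        treated = truth[truth["treatment"] == "CNO"]
        assert not treated.loc[treated["session"] < 11, "treated_session"].any()
        assert treated.loc[treated["session"] >= 11, "treated_session"].all()

    def test_negative_shift_lowers_test_phase_index(self):
        """Across replicate cohorts, treated STs drop from rescreen to test."""
        drops = []
        for seed in range(20):
            design = CohortDesign(
                n_per_cell=2,
                seed=seed,
                sessions_acquisition=(1, 2),
                sessions_rescreen=(3, 4),
                sessions_test=(5, 6),
                treatment_onset_session=5,
                phenotypes=("ST",),
                treat_shifts={"ST": -0.6},
            )
            trials, truth = simulate_cohort(design)
            _, scores = score_trials(trials)
            arm = truth[["rat_id", "treatment"]].drop_duplicates().set_index("rat_id")[
                "treatment"
            ]
            scores["arm"] = scores["rat_id"].map(arm)
            treated = scores[scores["arm"] == "CNO"]
            drops.append(
                treated.loc[treated["phase"] == "test", "index"].mean()
                - treated.loc[treated["phase"] == "rescreen", "index"].mean()
            )
        assert np.mean(drops) < 0

    def test_overlapping_session_ranges_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            CohortDesign(n_per_cell=2, sessions_acquisition=(1, 6), sessions_rescreen=(6, 10))


class TestDialysisGenerator:
    def test_noise_free_coupling_is_exact(self):
        agent = make_agent("ST", 1, da_noise_sd=0.0, da_coupling=50.0)
        series = simulate_dialysis_series(agent, 1.0, rng=np.random.default_rng(0))
        da = series[series["analyte"] == "DA"]
        base = da.loc[da["phase"] == "baseline", "conc_nM"]
        sess = da.loc[da["phase"] == "session", "conc_nM"]
        assert np.allclose(100 * (sess / base.mean() - 1), 50.0)

    def test_zero_index_zero_change(self):
        agent = make_agent("ST", 1, da_noise_sd=0.0)
        series = simulate_dialysis_series(agent, 0.0, rng=np.random.default_rng(0))
        da = series[series["analyte"] == "DA"]
        assert np.allclose(da["conc_nM"], da["conc_nM"].iloc[0])

    def test_schedule_counts(self):
        series = simulate_dialysis_series(make_agent("GT", 2), -0.5)
        counts = series[series["analyte"] == "DA"]["phase"].value_counts()
        assert counts["baseline"] == 6 and counts["pre"] == 5 and counts["session"] == 7
        assert set(series["analyte"]) == {"DA", "ACh", "GABA", "Glu", "5-HT"}

    def test_non_da_analytes_uncoupled(self):
        agent = make_agent("ST", 1, da_noise_sd=0.0, da_coupling=50.0)
        series = simulate_dialysis_series(agent, 1.0, rng=np.random.default_rng(0))
        for analyte in ("ACh", "GABA", "Glu", "5-HT"):
            sub = series[series["analyte"] == analyte]["conc_nM"]
            assert np.allclose(sub, sub.iloc[0])

    def test_out_of_range_index_rejected(self):
        with pytest.raises(ValueError):
            simulate_dialysis_series(make_agent("ST", 1), 1.5)


class TestScheduleClosedForm:
    def test_pretraining_duration(self):
        # 25 pellet deliveries on VT-30 s, no CS period
        assert expected_session_duration_min(25, 30.0, 0.0) == pytest.approx(12.5)

    def test_training_duration_about_forty_minutes(self):
        assert expected_session_duration_min(25, 90.0, 8.0) == pytest.approx(40.83, abs=0.01)

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            expected_session_duration_min(0, 30.0, 0.0)


def test_trial_config_validation():
    with pytest.raises(ValueError):
        TrialConfig(iti_mean_s=200.0)  # outside the range
    with pytest.raises(ValueError):
        TrialConfig(n_trials=0)
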