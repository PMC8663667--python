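"""The synthetic cohort generator: determinism, measurement round-trips,
and trajectory construction."""

import numpy as np
import pandas as pd
import pytest

from smglyc import dsmq as dsmq_mod
from smglyc import glycemic, mediation, sm_metrics
from smglyc.errors import ValidationError
from smglyc.pipeline import analyze_cohort
from smglyc.synthetic import (
    SMMonthsDist,
    SyntheticConfig,
    generate_cohort,
    generate_messages,
    trajectory_from_target_tic,
)
from .conftest import brute_force_tic


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(n_patients=0), "n_patients"),
            (dict(p_rural=1.2), "p_rural"),
            (dict(sigma_m=0.0), "sigma_m"),
            (dict(sigma_y=-1.0), "sigma_y"),
        ],
    )
    def test_invalid_fields_named(self, kwargs, field):
        with pytest.raises(ValidationError, match=field):
            SyntheticConfig(**kwargs)

    def test_sm_months_dist_moments(self):
        d = SMMonthsDist()
        x = d.sample(np.random.default_rng(0), 200_000)
        assert set(np.unique(x)) <= set(range(13))
        assert np.mean(x) == pytest.approx(6.7, abs=0.05)
        assert np.std(x) == pytest.approx(3.1, abs=0.05)

    def test_pmf_dist_validation(self):
        with pytest.raises(ValidationError, match="pmf"):
            SMMonthsDist(kind="pmf", pmf=tuple([0.5] * 13))
        d = SMMonthsDist(kind="pmf", pmf=tuple([1.0] + [0.0] * 12))
        assert (d.sample(np.random.default_rng(0), 50) == 0).all()


class TestTrajectory:
    def test_target_100_all_below_threshold(self):
        s = trajectory_from_target_tic(100.0, 2018, 4, seed=3)
        assert all(v < 8.0 for _, v in s.measurements)
        tic = glycemic.percent_time_in_control(glycemic.interpolate_daily(s, 2018))
        assert tic == 100.0

    def test_target_0_all_at_or_above_threshold(self):
        s = trajectory_from_target_tic(0.0, 2018, 4, seed=3)
        assert all(v >= 8.0 for _, v in s.measurements)
        tic = glycemic.percent_time_in_control(glycemic.interpolate_daily(s, 2018))
        assert tic == 0.0

    def test_target_50_round_trip_against_oracle(self):
        s = trajectory_from_target_tic(50.0, 2018, 6, seed=7)
        tic = glycemic.percent_time_in_control(glycemic.interpolate_daily(s, 2018))
        assert abs(tic - 50.0) <= 2.0
        assert tic == pytest.approx(brute_force_tic(s.measurements, 2018), abs=1e-9)

    @pytest.mark.parametrize("target", [3.0, 25.0, 61.8, 88.0, 99.0])
    def test_tolerance_across_targets(self, target):
        for seed in range(5):
            s = trajectory_from_target_tic(target, 2018, 5, seed=seed)
            tic = glycemic.percent_time_in_control(glycemic.interpolate_daily(s, 2018))
            assert abs(tic - target) <= 2.0

    def test_dates_increasing_and_values_in_assay_range(self):
        s = trajectory_from_target_tic(30.0, 2018, 8, seed=1)
        dates = [d for d, _ in s.measurements]
        assert dates == sorted(dates) and len(set(dates)) == len(dates)
        assert all(4.0 <= v <= 15.0 for _, v in s.measurements)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError, match="target_tic"):
            trajectory_from_target_tic(120.0, 2018, 4)
        with pytest.raises(ValidationError, match="n_measurements"):
            trajectory_from_target_tic(50.0, 2018, 1)


class TestGenerateMessages:
    def test_empty_active_months_yields_no_rows(self):
        assert generate_messages("p", 2017, set(), {}, seed=0) == []

    def test_full_year_recovers_twelve_months(self):
        rows = pd.DataFrame(generate_messages("p", 2017, set(range(1, 13)), {}, seed=0))
        assert sm_metrics.months_with_message(rows, "p", 2017) == 12

    def test_active_months_exact_and_threads_contiguous(self):
        rows = generate_messages("p", 2017, {1, 3}, {"diabetes": 0.5}, seed=5)
        df = pd.DataFrame(rows)
        assert sm_metrics.months_with_message(df, "p", 2017) == 2
        months = pd.to_datetime(df["timestamp"]).dt.month
        assert set(months[df["sender"] == "patient"]) == {1, 3}
        # rows of one thread are adjacent in the output
        tid = df["thread_id"].to_numpy()
        changes = (tid[1:] != tid[:-1]).sum()
        assert changes == df["thread_id"].nunique() - 1

    def test_bad_month_rejected(self):
        with pytest.raises(ValidationError, match="active_months"):
            generate_messages("p", 2017, {0, 3}, {}, seed=0)


class TestCohortRoundTrips:
    def test_seeded_determinism_byte_identical(self):
        cfg = SyntheticConfig(n_patients=40, seed=123)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        for ta, tb in zip(
            (a.patients, a.labs, a.messages, a.dsmq), (b.patients, b.labs, b.messages, b.dsmq)
        ):
            assert ta.to_csv(index=False) == tb.to_csv(index=False)
        assert a.truth == b.truth

    def test_different_seeds_differ(self):
        a = generate_cohort(SyntheticConfig(n_patients=40, seed=1))
        b = generate_cohort(SyntheticConfig(n_patients=40, seed=2))
        assert a.labs.to_csv() != b.labs.to_csv()

    def test_referential_integrity_and_ranges(self, cohort):
        ids = set(cohort.patients["patient_id"])
        for table in (cohort.labs, cohort.messages, cohort.dsmq):
            assert set(table["patient_id"]) <= ids
        assert set(cohort.patients["rurality_code"]) <= {0, 1}
        items = cohort.dsmq[dsmq_mod.ITEM_COLUMNS].to_numpy()
        assert ((items >= 0) & (items <= 3)).all()

    def test_months_metric_recovers_x_exactly(self, cohort):
        sm = sm_metrics.summarize_all(cohort.messages, cohort.patients["patient_id"], 2017)
        assert (
            sm["months_with_message"].to_numpy() == np.array(cohort.truth["x_months"])
        ).all()

    def test_dsmq_composite_recovers_latent_m(self, cohort):
        scores = dsmq_mod.score_all(cohort.dsmq)
        err = np.abs(scores["composite"].to_numpy() - np.array(cohort.truth["latent_m"]))
        assert err.max() <= 0.25

    def test_tic_recovers_latent_outcome(self, cohort):
        labs = cohort.labs.copy()
        labs["date"] = pd.to_datetime(labs["date"])
        glyc = glycemic.summarize_all(labs, 2018).set_index("patient_id")
        truth = pd.Series(cohort.truth["latent_tic"], index=cohort.patients["patient_id"])
        assert (glyc["a1c_tic_percent"] - truth).abs().max() <= 2.0


class TestStructuralRecovery:
    def test_null_structure_gives_near_zero_indirect_effects(self):
        cfg = SyntheticConfig(n_patients=1500, a1=0.0, a3=0.0, b=0.0, c_prime=0.0, seed=9)
        report = analyze_cohort(cfg_to_cohort(cfg), mediation.ModelSpec(n_boot=200, seed=9))
        fit = report.fit
        b_se = fit.outcome_model.loc["dsmq_composite", "se"]
        assert abs(fit.b) < 3 * b_se
        for v in fit.conditional_indirect.values():
            assert abs(v) < 0.2

    def test_recovers_interaction_and_b_path_at_n2000(self):
        cfg = SyntheticConfig(n_patients=2000, a1=0.04, a3=-0.08, b=10.0, seed=1)
        report = analyze_cohort(cfg_to_cohort(cfg), mediation.ModelSpec(n_boot=1, seed=1))
        med, out = report.fit.mediator_model, report.fit.outcome_model
        assert med.loc["x_w", "ci_low"] <= -0.08 <= med.loc["x_w", "ci_high"]
        assert out.loc["dsmq_composite", "ci_low"] <= 10.0 <= out.loc["dsmq_composite", "ci_high"]

    def test_index_sign_matches_truth_across_replicates(self):
        """With a nonzero interaction and b-path the fitted index keeps the
        true (negative) sign in nearly all replicates at n = 2000."""
        signs = []
        for seed in range(30):
            cfg = SyntheticConfig(n_patients=2000, seed=seed)
            report = analyze_cohort(cfg_to_cohort(cfg), mediation.ModelSpec(n_boot=1, seed=seed))
            signs.append(report.fit.index_mm < 0)
        assert np.mean(signs) >= 0.95


def cfg_to_cohort(cfg):
    return generate_cohort(cfg)
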