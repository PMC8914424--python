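import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from biledrain_econ.trial_cost_comparison import (
    PatientCostRecord,
    aggregate_costs,
    bc_bootstrap_diff,
    bc_levels,
    bootstrap_report,
    mann_whitney_p,
    read_records_csv,
    summarize_arms,
    write_records_csv,
)
from conftest import make_record
from oracles import exact_mann_whitney_p


class TestPatientCostRecord:
    def test_derived_totals(self):
        r = make_record(hospital=3000.0, primary=1029.15, reint=0.0)
        assert r.total_bd_cost == 1029.15
        assert r.total_cost == 4029.15

    def test_rearrangement_identity(self):
        r = make_record(hospital=2500.0, primary=900.0, reint=450.0, n_reint=2)
        assert r.total_cost - r.hospital_other_cost == r.total_bd_cost

    def test_cost_without_event_rejected(self):
        with pytest.raises(ValueError, match="without any re-intervention"):
            make_record(reint=100.0, n_reint=0)

    def test_event_without_cost_needs_flag(self):
        with pytest.raises(ValueError, match="zero"):
            make_record(reint=0.0, n_reint=1)
        ok = PatientCostRecord(
            patient_id="p",
            arm="EUS-BD",
            hospital_other_cost=1.0,
            primary_bd_cost=1.0,
            n_reinterventions=1,
            allow_zero_cost_reintervention=True,
        )
        assert ok.reintervention_cost == 0.0

    def test_negative_cost_rejected(self):
        with pytest.raises(ValueError):
            make_record(hospital=-1.0)

    def test_csv_round_trip(self, tmp_path):
        records = [
            make_record("a1", "EUS-BD", 3000.0, 1029.15),
            make_record("b1", "PTBD", 3600.0, 1177.21, 340.62, 1, 2),
        ]
        path = tmp_path / "records.csv"
        write_records_csv(records, path)
        reread = read_records_csv(path)
        assert reread == records


class TestSummarizeArms:
    def test_single_patient_arm_median_equals_value(self):
        records = [
            make_record("a", "EUS-BD", 3000.0, 1000.0),
            make_record("b", "PTBD", 4000.0, 1200.0),
        ]
        comp = summarize_arms(records)
        row = comp.summary.query("category == 'total_cost' and arm == 'EUS-BD'").iloc[0]
        assert row["median"] == row["min"] == row["max"] == 4000.0

    def test_summary_permutation_invariant(self, trial_structure_records):
        forward = summarize_arms(trial_structure_records)
        rng = np.random.default_rng(0)
        shuffled = list(trial_structure_records)
        rng.shuffle(shuffled)
        backward = summarize_arms(shuffled, arms=("EUS-BD", "PTBD"))
        assert forward.summary.sort_values(["category", "arm"]).reset_index(
            drop=True
        ).equals(
            backward.summary.sort_values(["category", "arm"]).reset_index(drop=True)
        )
        assert forward.p_values == backward.p_values

    def test_trial_reintervention_structure_recovered(self, trial_structure_records):
        comp = summarize_arms(trial_structure_records, arms=("EUS-BD", "PTBD"))
        assert comp.reintervention_rate["EUS-BD"] == pytest.approx(0.25, abs=0.005)
        assert comp.reintervention_rate["PTBD"] == pytest.approx(0.548, abs=0.005)
        assert comp.mean_reintervention_frequency["EUS-BD"] == pytest.approx(
            0.34, abs=0.01
        )
        assert comp.mean_reintervention_frequency["PTBD"] == pytest.approx(
            0.93, abs=0.01
        )

    def test_empty_arm_rejected(self):
        records = [make_record("a", "EUS-BD", 1.0, 1.0)]
        with pytest.raises(ValueError):
            summarize_arms(records, arms=("EUS-BD", "PTBD"))

    def test_totals_are_per_patient_sums(self, trial_structure_records):
        frame = aggregate_costs(trial_structure_records)
        np.testing.assert_allclose(
            frame["total_cost"],
            frame["hospital_other_cost"]
            + frame["primary_bd_cost"]
            + frame["reintervention_cost"],
        )


class TestMannWhitney:
    def test_textbook_example(self):
        res = mann_whitney_p([1, 2], [3, 4])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 3)

    def test_identical_samples_p_one(self):
        assert mann_whitney_p([1, 2], [1, 2]).p_value == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_p([], [1.0])

    @given(
        n_a=st.integers(2, 5),
        n_b=st.integers(2, 5),
        data=st.data(),
    )
    @settings(max_examples=60, deadline=None)
    def test_exact_path_matches_enumeration(self, n_a, n_b, data):
        pool = data.draw(
            st.lists(
                st.integers(0, 10**6),
                min_size=n_a + n_b,
                max_size=n_a + n_b,
                unique=True,
            )
        )
        a, b = pool[:n_a], pool[n_a:]
        res = mann_whitney_p(a, b)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(exact_mann_whitney_p(a, b), abs=1e-12)

    def test_asymptotic_close_to_exact_at_n8(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            vals = rng.permutation(1000)[:16].astype(float)
            a, b = vals[:8], vals[8:]
            p_exact = mann_whitney_p(a, b).p_value
            p_approx = stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic"
            ).pvalue
            assert abs(p_exact - p_approx) < 0.02

    def test_type_one_error_near_nominal_under_null(self):
        rng = np.random.default_rng(314)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            if mann_whitney_p(x, y).p_value < 0.05:
                rejections += 1
        rate = rejections / n_rep
        # binomial 99% envelope around 0.05 at 400 replicates
        assert 0.02 < rate < 0.09


class TestBcBootstrap:
    def test_constant_arms_degenerate_interval(self):
        records = [
            make_record(f"a{i}", "A", hospital=10.0, primary=0.0) for i in range(4)
        ] + [make_record(f"b{i}", "B", hospital=14.0, primary=0.0) for i in range(4)]
        ci = bc_bootstrap_diff(records, "hospital_other_cost", seed=0, arms=("A", "B"))
        assert ci.degenerate
        assert ci.point_difference == -4.0
        assert (ci.lower, ci.upper) == (-4.0, -4.0)

    def test_bias_correction_reduces_to_percentile_at_z0_zero(self):
        assert bc_levels(0.0, 0.95) == (
            pytest.approx(0.025, abs=1e-12),
            pytest.approx(0.975, abs=1e-12),
        )

    def test_endpoints_are_within_bootstrap_sample_range(self, trial_structure_records):
        ci = bc_bootstrap_diff(trial_structure_records, "total_cost", seed=1)
        boot = ci.bootstrap_statistics
        assert boot.min() <= ci.lower <= ci.upper <= boot.max()
        # endpoints agree with the BC quantile construction on the stored sample
        lo_level, hi_level = bc_levels(ci.z0, 0.95)
        np.testing.assert_allclose(
            [ci.lower, ci.upper], np.quantile(boot, [lo_level, hi_level])
        )

    def test_same_seed_same_interval(self, trial_structure_records):
        a = bc_bootstrap_diff(trial_structure_records, "total_cost", seed=9)
        b = bc_bootstrap_diff(trial_structure_records, "total_cost", seed=9)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_report_covers_all_categories(self, trial_structure_records):
        table = bootstrap_report(trial_structure_records, n_boot=200, seed=0)
        assert len(table) == 5
        assert (table["ci_lower"] <= table["ci_upper"]).all()

    def test_too_small_arm_rejected(self):
        records = [
            make_record("a", "A", 1.0, 1.0),
            make_record("b1", "B", 1.0, 1.0),
            make_record("b2", "B", 2.0, 1.0),
        ]
        with pytest.raises(ValueError, match="at least 2"):
            bc_bootstrap_diff(records, "total_cost", arms=("A", "B"))

    def test_unknown_category_rejected(self, trial_structure_records):
        with pytest.raises(KeyError):
            bc_bootstrap_diff(trial_structure_records, "stent_cost")
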