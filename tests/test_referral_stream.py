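"""Referral-stream generator: rates, Poisson structure, backlog, CSV round-trip."""

import numpy as np
import pytest
from scipy import stats

from edtsim.referral_stream import (
    GroupParams,
    PatientRecord,
    default_group_params,
    generate_backlog,
    generate_referrals,
    read_patients,
    write_patients,
)


class TestDefaultGroupParams:
    def test_weekly_rates_reproduce_observed_quarter(self, group_by_label):
        assert group_by_label["A"].weekly_rate == pytest.approx(77 / 13)
        assert group_by_label["B"].weekly_rate == pytest.approx(14 / 13)
        assert group_by_label["C"].weekly_rate == pytest.approx(40 / 13)
        assert group_by_label["D"].weekly_rate == pytest.approx(64 / 13)

    def test_total_rate_and_yearly_referrals(self, group_params):
        total = sum(gp.weekly_rate for gp in group_params)
        assert total == pytest.approx(195 / 13)  # 15 per week
        assert total * 52 == pytest.approx(780)

    def test_abnormality_probabilities(self, group_by_label):
        assert group_by_label["A"].p_abnormal == pytest.approx(23 / 77)
        assert group_by_label["B"].p_abnormal == pytest.approx(4 / 14)
        assert group_by_label["C"].p_abnormal == pytest.approx(0.125)
        assert group_by_label["D"].p_abnormal is None

    def test_group_d_not_screenable(self, group_by_label):
        assert not group_by_label["D"].screenable
        assert all(group_by_label[g].screenable for g in "ABC")

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="weekly_rate"):
            GroupParams("A", -1.0, 0.5)
        with pytest.raises(ValueError, match="p_abnormal"):
            GroupParams("A", 1.0, 1.5)
        with pytest.raises(ValueError, match="not screenable"):
            GroupParams("D", 1.0, None, screenable=True)


class TestGenerateReferrals:
    def test_rejects_bad_horizon_and_scale(self, group_params):
        with pytest.raises(ValueError, match="horizon_weeks"):
            generate_referrals(group_params, 0.0)
        with pytest.raises(ValueError, match="horizon_weeks"):
            generate_referrals(group_params, -5.0)
        with pytest.raises(ValueError, match="demand_scale"):
            generate_referrals(group_params, 52.0, demand_scale=0.0)

    def test_tiny_horizon_near_empty(self, group_params):
        recs = generate_referrals(group_params, 1e-9, rng_seed=3)
        assert len(recs) <= 1

    def test_sorted_ids_and_fields(self, group_params):
        recs = generate_referrals(group_params, 52.0, rng_seed=5, id_start=100)
        arrivals = [r.arrival_week for r in recs]
        assert arrivals == sorted(arrivals)
        assert [r.id for r in recs] == list(range(100, 100 + len(recs)))
        assert all(r.source == "referral" for r in recs)
        assert all(0 <= r.arrival_week < 52 for r in recs)
        assert all((r.true_abnormal is None) == (r.group == "D") for r in recs)
        assert all(r.edt_week is None and r.wait_weeks is None for r in recs)

    def test_mean_count_matches_rate(self, group_params):
        # 15/week over 260 weeks -> expected 3900 per replication.
        n_seeds = 200
        counts = [
            len(generate_referrals(group_params, 260.0, rng_seed=s))
            for s in range(n_seeds)
        ]
        se = np.sqrt(3900 / n_seeds)
        assert abs(np.mean(counts) - 3900) < 3 * se

    def test_demand_scale_scales_mean(self, group_params):
        counts = [
            len(generate_referrals(group_params, 260.0, demand_scale=1.25, rng_seed=s))
            for s in range(100)
        ]
        se = np.sqrt(4875 / 100)
        assert abs(np.mean(counts) - 4875) < 3 * se

    def test_group_mix_matches_observed_proportions(self, group_params):
        # Pooled over seeds the A:B:C:D mix should fit 77:14:40:64.
        observed = {g: 0 for g in "ABCD"}
        for s in range(40):
            for r in generate_referrals(group_params, 52.0, rng_seed=s):
                observed[r.group] += 1
        total = sum(observed.values())
        expected = np.array([77, 14, 40, 64], dtype=float) / 195 * total
        chi2 = stats.chisquare([observed[g] for g in "ABCD"], expected)
        assert chi2.pvalue > 0.001

    def test_weekly_counts_poisson_dispersion(self, group_params):
        # Weekly bin counts are iid Poisson(15); dispersion index ~ chi2.
        counts = []
        for s in range(5):
            recs = generate_referrals(group_params, 104.0, rng_seed=1000 + s)
            hist, _ = np.histogram(
                [r.arrival_week for r in recs], bins=104, range=(0, 104)
            )
            counts.extend(hist.tolist())
        counts = np.asarray(counts, dtype=float)
        n = len(counts)
        disp = (n - 1) * counts.var(ddof=1) / counts.mean()
        lo, hi = stats.chi2.ppf([0.005, 0.995], df=n - 1)
        assert lo < disp < hi

    def test_abnormality_independent_of_arrival_time(self, group_params):
        recs = generate_referrals(group_params, 520.0, rng_seed=11)
        a = [(r.arrival_week, float(r.true_abnormal)) for r in recs if r.group == "A"]
        t, status = np.array(a).T
        r = np.corrcoef(t, status)[0, 1]
        assert abs(r) < 4 / np.sqrt(len(a))

    def test_seed_determinism(self, group_params):
        r1 = generate_referrals(group_params, 52.0, rng_seed=42)
        r2 = generate_referrals(group_params, 52.0, rng_seed=42)
        assert r1 == r2
        r3 = generate_referrals(group_params, 52.0, rng_seed=43)
        assert r1 != r3


class TestGenerateBacklog:
    def test_empty_and_negative(self, group_params):
        assert generate_backlog(0, group_params) == []
        with pytest.raises(ValueError, match=">= 0"):
            generate_backlog(-1, group_params)

    def test_full_backlog_structure(self, group_params):
        recs = generate_backlog(228, group_params, rng_seed=2)
        assert len(recs) == 228
        assert all(r.arrival_week == 0.0 and r.source == "backlog" for r in recs)
        assert all(r.edt_week is None for r in recs)
        assert all((r.true_abnormal is None) == (r.group == "D") for r in recs)
        # Group mix drawn from the arrival mix: A should dominate, D second.
        from collections import Counter

        mix = Counter(r.group for r in recs)
        assert mix["A"] > mix["B"] and mix["D"] > mix["C"] > mix["B"]


class TestPatientCsv:
    def test_empty_round_trip(self, tmp_path):
        path = tmp_path / "patients.csv"
        write_patients(path, [])
        assert path.read_text().strip().count("\n") == 0  # header only
        assert read_patients(path) == []

    def test_round_trip_preserves_fields(self, group_params, tmp_path):
        recs = generate_backlog(28, group_params, rng_seed=1) + generate_referrals(
            group_params, 10.0, rng_seed=1, id_start=28
        )
        recs[0].screen_flagged = True
        recs[1].edt_week = 3.0
        recs[1].wait_weeks = 3.0
        path = tmp_path / "patients.csv"
        write_patients(path, recs)
        back = read_patients(path)
        assert back == recs
        # Re-serialisation is byte-identical (idempotent formatting).
        path2 = tmp_path / "again.csv"
        write_patients(path2, back)
        assert path.read_bytes() == path2.read_bytes()

    def test_backlog_row_count(self, group_params, tmp_path):
        path = tmp_path / "backlog.csv"
        write_patients(path, generate_backlog(228, group_params, rng_seed=0))
        assert len(path.read_text().strip().splitlines()) == 229

    def test_malformed_rows_report_line_numbers(self, tmp_path):
        path = tmp_path / "bad.csv"
        header = "id,source,arrival_week,group,true_abnormal,screen_flagged,edt_week,wait_weeks"
        path.write_text(header + "\n1,referral,0.5,A,True,,,\n2,referral,oops,A,,,,\n")
        with pytest.raises(ValueError, match="line 3"):
            read_patients(path)
        path.write_text(header + "\n1,referral,0.5\n")
        with pytest.raises(ValueError, match="line 2"):
            read_patients(path)
        path.write_text("not,a,patient,header\n")
        with pytest.raises(ValueError, match="line 1"):
            read_patients(path)

    def test_identical_seed_identical_bytes(self, group_params, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_patients(p1, generate_referrals(group_params, 26.0, rng_seed=9))
        write_patients(p2, generate_referrals(group_params, 26.0, rng_seed=9))
        assert p1.read_bytes() == p2.read_bytes()


class TestPatientRecordInvariants:
    def test_backlog_must_arrive_at_zero(self):
        with pytest.raises(ValueError, match="arrival_week = 0"):
            PatientRecord(id=0, source="backlog", arrival_week=1.0, group="A")

    def test_bad_source_and_group(self):
        with pytest.raises(ValueError, match="source"):
            PatientRecord(id=0, source="walk-in", arrival_week=0.0, group="A")
        with pytest.raises(ValueError, match="group"):
            PatientRecord(id=0, source="referral", arrival_week=0.0, group="E")
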