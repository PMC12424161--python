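"""Success rates, bootstrap CIs, Welch tests, Top-N/hybrid selection, failure modes."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pfaseval.evaluation_stats import (EvaluationTable, FailureModes,
                                       bootstrap_ci, classify_failure,
                                       compare_splits, failure_mode_shares,
                                       hybrid_success, significance_stars,
                                       success_rate, topn_success, welch_test,
                                       aggregate_report)
from pfaseval.pose_metrics import PoseMetrics
from pfaseval.synthetic_data import CohortSpec, make_evaluation_table


class TestSuccessRate:
    def test_half(self):
        assert success_rate([0.1, 0.3]) == 50.0

    def test_boundary_inclusive(self):
        assert success_rate([0.2]) == 100.0
        assert success_rate([0.2000001]) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            success_rate([])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50),
           st.floats(0.05, 0.5), st.floats(0.05, 0.5))
    @settings(deadline=None, derandomize=True)
    def test_monotone_in_threshold(self, values, t1, t2):
        lo, hi = sorted((t1, t2))
        assert success_rate(values, lo) <= success_rate(values, hi)


class TestBootstrap:
    def test_degenerate_all_ones(self):
        assert bootstrap_ci(np.ones(20)) == (100.0, 100.0)

    def test_same_seed_reproduces(self):
        v = np.random.default_rng(0).integers(0, 2, size=50)
        assert bootstrap_ci(v, seed=7) == bootstrap_ci(v, seed=7)

    def test_interval_brackets_point_estimate(self):
        v = np.r_[np.ones(70), np.zeros(30)]
        low, high = bootstrap_ci(v, seed=1)
        assert low <= 70.0 <= high
        assert 55 < low and high < 85

    def test_coverage_for_bernoulli(self):
        """95% percentile CIs cover a true rate of 0.7 in 93-97% of 500
        replicate experiments (n = 200 each)."""
        rng = np.random.default_rng(1234)
        covered = 0
        for rep in range(500):
            sample = (rng.random(200) < 0.7).astype(float)
            low, high = bootstrap_ci(sample, seed=int(rng.integers(2**31)))
            covered += low <= 70.0 <= high
        assert 0.93 <= covered / 500 <= 0.97


class TestWelch:
    def test_identical_samples(self):
        t, p, stars = welch_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert t == 0.0 and p == 1.0 and stars == ""

    def test_matches_closed_form(self):
        """Hand-computed Welch statistic for {1,2,3,4} vs {2,3,4,5,6,7}."""
        a, b = [1, 2, 3, 4], [2, 3, 4, 5, 6, 7]
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        se = math.sqrt(va / len(a) + vb / len(b))
        t_expected = (ma - mb) / se
        dof = (va / len(a) + vb / len(b)) ** 2 / (
            (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
        )
        from scipy.stats import t as t_dist

        p_expected = 2 * t_dist.sf(abs(t_expected), dof)
        t_got, p_got, _ = welch_test(a, b)
        assert t_got == pytest.approx(t_expected, abs=1e-12)
        assert p_got == pytest.approx(p_expected, abs=1e-12)

    def test_star_thresholds(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(0.0004) == "***"
        assert significance_stars(0.2) == ""

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            welch_test([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            welch_test([1.0], [1.0, 2.0])


def _table(rows):
    return EvaluationTable(pd.DataFrame(rows))


def _rows(entry, method, pals, split="Before", **extra):
    return [
        {
            "entry_id": entry, "method_label": method, "rank": i + 1,
            "rmsd_backbone": 0.05, "rmsd_pocket": extra.get("pocket", 0.05),
            "rmsd_ligand": extra.get("ligand", 0.05),
            "rmsd_pocket_aligned_ligand": v, "split": split,
        }
        for i, v in enumerate(pals)
    ]


class TestTopN:
    def test_rank_window(self):
        table = _table(_rows("E1", "AF3", [0.5, 0.15]))
        assert topn_success(table, 1).rate == 0.0
        assert topn_success(table, 2).rate == 100.0

    def test_n_larger_than_available_clamps(self):
        table = _table(_rows("E1", "AF3", [0.5, 0.15]))
        assert topn_success(table, 10).rate == 100.0

    def test_matches_direct_enumeration(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(40):
            rows += _rows(f"E{i}", "AF3", rng.uniform(0.05, 0.6, size=5).tolist())
        table = _table(rows)
        for n in (1, 3, 5):
            got = topn_success(table, n).rate
            df = table.frame
            exp = np.mean(
                [
                    df[(df.entry_id == f"E{i}") & (df["rank"] <= n)]
                    .rmsd_pocket_aligned_ligand.min()
                    <= 0.2
                    for i in range(40)
                ]
            )
            assert got == pytest.approx(100 * exp)

    def test_duplicate_rank_rejected(self):
        rows = _rows("E1", "AF3", [0.1]) + _rows("E1", "AF3", [0.2])
        with pytest.raises(ValueError):
            _table(rows)


class TestHybrid:
    def test_union_rescues_entry(self):
        rows = _rows("E1", "AF3", [0.3]) + _rows("E1", "Vina", [0.1])
        table = _table(rows)
        assert hybrid_success(table, ["AF3", "Vina"], n=1).rate == 100.0

    def test_dominates_each_constituent(self):
        rng = np.random.default_rng(6)
        rows = []
        for i in range(50):
            rows += _rows(f"E{i}", "AF3", rng.uniform(0.05, 0.7, 5).tolist())
            rows += _rows(f"E{i}", "Vina", rng.uniform(0.05, 0.7, 5).tolist())
        table = _table(rows)
        hybrid = hybrid_success(table, ["AF3", "Vina"], n=5).rate
        for method in ("AF3", "Vina"):
            assert hybrid >= topn_success(table, 5, method=method).rate

    def test_missing_method_excludes_entry(self):
        rows = (_rows("E1", "AF3", [0.1]) + _rows("E1", "Vina", [0.5])
                + _rows("E2", "AF3", [0.5]))
        table = _table(rows)
        with pytest.warns(UserWarning, match="lack poses"):
            s = hybrid_success(table, ["AF3", "Vina"], n=1)
        assert s.n == 1  # E2 dropped


class TestFailureModes:
    def test_success_returns_none(self):
        m = PoseMetrics(0.05, 0.05, 0.05, 0.15)
        assert classify_failure(m) is None

    @pytest.mark.parametrize(
        "ligand,pocket,expected",
        [
            (0.05, 0.05, FailureModes(True, False, False, False)),
            (0.35, 0.05, FailureModes(False, True, False, False)),
            (0.05, 0.35, FailureModes(False, False, True, False)),
            (0.30, 0.30, FailureModes(False, True, True, True)),
        ],
    )
    def test_mode_rules(self, ligand, pocket, expected):
        m = PoseMetrics(0.05, pocket, ligand, 0.5)
        assert classify_failure(m) == expected

    def test_every_failure_has_a_mode(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            m = PoseMetrics(0.05, rng.uniform(0, 0.5), rng.uniform(0, 0.5),
                            rng.uniform(0.21, 1.0))
            fm = classify_failure(m)
            assert fm.orientation or fm.ligand_structure or fm.pocket_structure
            if fm.orientation:
                assert not (fm.ligand_structure or fm.pocket_structure)

    def test_shares_can_exceed_100(self):
        rows = _rows("E1", "AF3", [0.5], ligand=0.3, pocket=0.3)
        shares = failure_mode_shares(_table(rows))
        by_mode = dict(zip(shares["mode"], shares["share"]))
        assert by_mode["ligand_structure"] == 100.0
        assert by_mode["pocket_structure"] == 100.0


class TestAggregateAndRecovery:
    def test_single_record_rates_are_0_or_100(self):
        table = _table(_rows("E1", "AF3", [0.1]))
        report = aggregate_report(table, group_by=(),
                                  references=("pocket_aligned_ligand",))
        assert set(report["rate"]) <= {0.0, 100.0}

    def test_parameter_recovery_with_welch_significance(self):
        """Synthetic cohorts at rates 0.75/0.55 (n=400/split): recovered rates
        lie inside the bootstrap CI of the truth and the split difference is
        highly significant."""
        spec = CohortSpec(n_systems=400,
                          success_probs={"Before": 0.75, "After": 0.55},
                          seed=11)
        table = make_evaluation_table(spec)
        report = aggregate_report(table, group_by=("split",),
                                  references=("pocket_aligned_ligand",),
                                  strategies=(1,), seed=3)
        for row in report.itertuples():
            truth = 75.0 if row.split == "Before" else 55.0
            assert row.ci_low <= truth <= row.ci_high or abs(row.rate - truth) < 5
        cmp = compare_splits(table)
        assert cmp["p"].iloc[0] < 0.001

    def test_charge_groups_partition_the_table(self):
        table = make_evaluation_table(CohortSpec(n_systems=100, seed=4))
        report = aggregate_report(table, group_by=("charge_category",),
                                  references=("pocket_aligned_ligand",),
                                  strategies=(1,))
        per_group = report[report["strategy"] == "top1"]["n"]
        assert per_group.sum() == 200  # 100 systems x 2 splits


class TestMonotonicityProperties:
    def test_topn_and_hybrid_monotonicity_on_random_tables(self):
        """Across 100 random tables: Top-(n+1) >= Top-n, hybrid >= each
        constituent, and success rate non-decreasing in threshold."""
        rng = np.random.default_rng(99)
        for rep in range(100):
            rows = []
            n_entries = int(rng.integers(3, 12))
            for i in range(n_entries):
                rows += _rows(f"E{i}", "AF3", rng.uniform(0.02, 0.8, 5).tolist())
                rows += _rows(f"E{i}", "Vina", rng.uniform(0.02, 0.8, 5).tolist())
            table = _table(rows)
            rates = [topn_success(table, n, method="AF3").rate for n in (1, 2, 3, 4, 5)]
            assert all(a <= b + 1e-12 for a, b in zip(rates, rates[1:]))
            hybrid = hybrid_success(table, ["AF3", "Vina"], n=5).rate
            assert hybrid + 1e-12 >= max(
                topn_success(table, 5, method=m).rate for m in ("AF3", "Vina")
            )
            values = table.frame["rmsd_pocket_aligned_ligand"]
            assert success_rate(values, 0.1) <= success_rate(values, 0.2) <= \
                success_rate(values, 0.4)
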