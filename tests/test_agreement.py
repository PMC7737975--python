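import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lvstrain.agreement import (
    bland_altman,
    bonferroni_threshold,
    build_tables,
    duplicate_single_run,
    format_threshold,
    group_summary,
    paired_comparison,
    sd_percent_of_mean,
)
from lvstrain.errors import ConfigurationError, DataError
from lvstrain.metrics import METRIC_NAMES
from lvstrain.phantom import PhantomConfig, generate_study, render_session
from lvstrain import pipeline


def synthetic_metrics_table(rng, n_readers=7, shift=None):
    """Wide metrics table for 2 software x 2 repetitions without the phantom."""
    shift = shift or {}
    base = {"ACS": -12.0, "MCS": -20.0, "BCS": -30.0, "GCS": -20.7, "EDV": 160.0, "ESV": 97.0, "LVEF": 40.0}
    rows = []
    for software in ("osirix", "scanip"):
        for rep in (1, 2):
            for reader in range(1, n_readers + 1):
                row = {"reader": reader, "software": software, "repetition": rep, "kind": "manual"}
                for m, mu in base.items():
                    offset = shift.get(m, 0.0) if software == "scanip" else 0.0
                    row[m] = mu + offset + rng.normal(0, abs(mu) * 0.03)
                rows.append(row)
    return pd.DataFrame(rows)


class TestGroupSummary:
    def test_sd_percent_of_mean_table_convention(self):
        assert round(sd_percent_of_mean(-11.9, 4.1), 1) == 34.5
        assert round(sd_percent_of_mean(123.8, 7.8), 1) == 6.3

    def test_summary_against_t_interval(self):
        rng = np.random.default_rng(0)
        x = rng.normal(-11.9, 4.1, 7)
        s = group_summary(x)
        assert s.mean == pytest.approx(x.mean())
        assert s.sd == pytest.approx(x.std(ddof=1))
        lo, hi = stats.t.interval(0.95, 6, loc=x.mean(), scale=stats.sem(x))
        assert (s.ci_low, s.ci_high) == pytest.approx((lo, hi))

    def test_constant_vector_collapses(self):
        s = group_summary([5.0] * 7)
        assert s.sd == 0.0 and s.sd_pct == 0.0
        assert s.ci_low == s.ci_high == 5.0

    def test_too_small_group(self):
        with pytest.raises(DataError):
            group_summary([1.0])


class TestPairedComparison:
    def test_reference_t_oracle(self):
        """Frozen worked example, cross-checked against scipy's paired t."""
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 5.0]
        c = paired_comparison(a, b)
        assert c.mean_difference == pytest.approx(-4.0 / 3.0)
        assert c.sd_difference == pytest.approx(0.5774, abs=1e-4)
        assert c.p == pytest.approx(0.0572, abs=1e-3)
        assert c.p == pytest.approx(stats.ttest_rel(a, b).pvalue)
        assert c.mean_of_attempts == pytest.approx(np.mean([1.5, 2.5, 4.0]))

    def test_identical_groups_flagged_degenerate(self):
        c = paired_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert c.mean_difference == 0.0 and c.degenerate and np.isnan(c.p)

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            paired_comparison([1.0, 2.0], [1.0, 2.0, 3.0])

    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=9),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=40, deadline=None)
    def test_pairing_identity_and_antisymmetry(self, a, seed):
        rng = np.random.default_rng(seed)
        a = np.asarray(a)
        b = a + rng.normal(0, 1.0, a.size)
        fwd = paired_comparison(a, b)
        rev = paired_comparison(b, a)
        assert fwd.mean_difference == pytest.approx(a.mean() - b.mean(), abs=1e-9)
        assert rev.mean_difference == pytest.approx(-fwd.mean_difference, abs=1e-12)
        if not fwd.degenerate:
            assert rev.p == pytest.approx(fwd.p, rel=1e-12)


class TestBonferroni:
    def test_seven_metric_threshold(self):
        t = bonferroni_threshold(0.05, 7)
        assert t == pytest.approx(0.05 / 7)
        assert format_threshold(t) == 0.007

    def test_single_comparison(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    @pytest.mark.parametrize("m", [1, 3, 7, 28])
    def test_algebraic_identity(self, m):
        assert bonferroni_threshold(0.05, m) * m == pytest.approx(0.05)

    def test_invalid_inputs(self):
        with pytest.raises(ConfigurationError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ConfigurationError):
            bonferroni_threshold(1.5, 7)


class TestBlandAltman:
    def test_identical_series(self):
        x = np.arange(10.0)
        res = bland_altman(x, x)
        assert res.bias == res.loa_low == res.loa_high == 0.0

    def test_constant_offset(self):
        """A constant -1.9 cm offset is recovered as the bias with zero-width
        limits of agreement."""
        x = np.linspace(9.0, 18.0, 25)
        res = bland_altman(x, x - 1.9)
        assert res.bias == pytest.approx(-1.9)
        assert res.loa_low == pytest.approx(-1.9)
        assert res.loa_high == pytest.approx(-1.9)

    def test_monte_carlo_normal_model(self):
        rng = np.random.default_rng(12)
        sigma, n = 0.5, 1000
        x = rng.normal(14.0, 1.0, n)
        y = x + rng.normal(0.6, sigma, n)
        res = bland_altman(x, y)
        assert res.bias == pytest.approx(0.6, abs=3 * sigma / np.sqrt(n))
        assert res.loa_high == pytest.approx(0.6 + 1.96 * sigma, abs=4 * sigma * np.sqrt(3 / n))
        assert res.loa_low == pytest.approx(0.6 - 1.96 * sigma, abs=4 * sigma * np.sqrt(3 / n))
        assert len(res.points) == n

    def test_mismatched_inputs(self):
        with pytest.raises(DataError):
            bland_altman([1.0, 2.0], [1.0])
        with pytest.raises(DataError):
            bland_altman([1.0], [1.0])


class TestDuplication:
    def test_automated_run_becomes_two_repetitions(self, small_config):
        sess = render_session(small_config, 0, 1, "cvi42", kind="automated", render_masks=False)
        first, second = duplicate_single_run(sess)
        assert (first.repetition, second.repetition) == (1, 2)
        assert first.duplicated and second.duplicated
        assert first.contours is sess.contours  # shared measurements

    def test_intra_comparison_of_duplicate_is_exactly_zero(self, small_config):
        sess = render_session(small_config, 0, 1, "cvi42", kind="automated", render_masks=False)
        first, second = duplicate_single_run(sess)
        meas = pipeline.measure_study([first, second], method="spline")
        res = pipeline.bland_altman_lengths(meas, "cvi42", "cvi42", repetition=None)
        # repetition 1 vs 2 of the same duplicated data
        a = meas[meas.repetition == 1]["perimeter_cm"].to_numpy()
        b = meas[meas.repetition == 2]["perimeter_cm"].to_numpy()
        assert np.array_equal(a, b)
        assert res is not None

    def test_refuses_double_duplication(self, small_config):
        sess = render_session(small_config, 0, 1, "cvi42", kind="automated", render_masks=False)
        first, _ = duplicate_single_run(sess)
        with pytest.raises(DataError):
            duplicate_single_run(first)


class TestBuildTables:
    def test_table_shapes(self):
        rng = np.random.default_rng(3)
        table1, table2, threshold = build_tables(synthetic_metrics_table(rng))
        assert len(table1) == 7 * 4
        assert len(table2) == 7 * 4
        assert threshold == pytest.approx(0.05 / 7)
        assert set(table2["comparison"]) == {
            "osirix: T1 vs T2",
            "scanip: T1 vs T2",
            "T1: osirix vs scanip",
            "T2: osirix vs scanip",
        }

    def test_injected_volume_bias_is_flagged(self):
        """A 36 mL EDV offset between packages fires the inter-software flag."""
        rng = np.random.default_rng(4)
        df = synthetic_metrics_table(rng, shift={"EDV": -36.0, "ESV": -23.0})
        _, table2, _ = build_tables(df)
        inter_edv = table2[(table2.metric == "EDV") & table2.comparison.str.contains("vs scanip")]
        assert inter_edv["significant"].all()
        intra_gcs = table2[(table2.metric == "GCS") & table2.comparison.str.contains("T1 vs T2")]
        assert not intra_gcs["significant"].any()

    def test_swapping_order_negates_differences(self):
        rng = np.random.default_rng(5)
        df = synthetic_metrics_table(rng, shift={"EDV": -36.0})
        _, fwd, _ = build_tables(df, software_order=["osirix", "scanip"])
        _, rev, _ = build_tables(df, software_order=["scanip", "osirix"])
        f = fwd[fwd.comparison.str.startswith("T1")].set_index("metric")
        r = rev[rev.comparison.str.startswith("T1")].set_index("metric")
        for m in METRIC_NAMES:
            assert r.loc[m, "mean_difference"] == pytest.approx(-f.loc[m, "mean_difference"])
            assert r.loc[m, "p"] == pytest.approx(f.loc[m, "p"], rel=1e-9, nan_ok=True)

    def test_missing_group_or_reader_mismatch(self):
        rng = np.random.default_rng(6)
        df = synthetic_metrics_table(rng)
        with pytest.raises(DataError):
            build_tables(df[df.software == "osirix"])
        bad = df.copy()
        bad.loc[(bad.software == "scanip") & (bad.repetition == 2) & (bad.reader == 3), "reader"] = 9
        with pytest.raises(DataError):
            build_tables(bad)


class TestTypeIControl:
    def test_false_positive_rate_without_bias(self, small_config):
        """With no injected software bias the Bonferroni-flagged fraction over
        replicated studies stays below the family-wise alpha."""
        import dataclasses

        cfg = dataclasses.replace(
            small_config, software_length_bias={"osirix": 0.0, "scanip": 0.0}
        )
        n_studies, flagged, total = 60, 0, 0
        for r in range(n_studies):
            c = dataclasses.replace(cfg, seed=1000 + r)
            sessions, _ = generate_study(c, render_masks=False)
            manual = [s for s in sessions if s.kind == "manual"]
            meas = pipeline.measure_study(manual, method="spline")
            table = pipeline.metrics_table(meas, c.slice_spacing)
            _, table2, _ = build_tables(table)
            flagged += int(table2["significant"].sum())
            total += len(table2)
        assert flagged / total <= 0.05
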