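"""Agreement and group-comparison statistics against independent oracles."""

import numpy as np
import pytest
from scipy import stats as sst

import gaitinit as gi
from gaitinit.errors import UsageError
from gaitinit.stats import Z_LOA, _ba_power


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def icc_a1_anova_oracle(x):
    """ICC(A,1) from an explicitly looped two-way ANOVA decomposition."""
    n, k = x.shape
    grand = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(x[i][j] for j in range(k)) / k for i in range(n)]
    col = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((r - grand) ** 2 for r in row)
    ssc = n * sum((c - grand) ** 2 for c in col)
    sse = sum((x[i][j] - row[i] - col[j] + grand) ** 2
              for i in range(n) for j in range(k))
    msr, msc, mse = ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def spearman_rank_formula(x, y):
    """1 - 6*sum(d^2)/(n(n^2-1)) for tie-free data."""
    n = len(x)
    rx = np.argsort(np.argsort(x))
    ry = np.argsort(np.argsort(y))
    d = rx - ry
    return 1.0 - 6.0 * float(np.sum(d * d)) / (n * (n * n - 1))


def mc_loa_containment_power(n, bias, sd, delta, n_rep, rng):
    """Monte-Carlo probability that both 95% LOA confidence bounds fall
    inside +-delta for samples of n normal differences."""
    d = rng.normal(bias, sd, size=(n_rep, n))
    mean = d.mean(axis=1)
    s = d.std(axis=1, ddof=1)
    tq = sst.t.ppf(0.975, n - 1)
    se = s * np.sqrt(1.0 / n + Z_LOA ** 2 / (2.0 * (n - 1)))
    upper = mean + Z_LOA * s + tq * se
    lower = mean - Z_LOA * s - tq * se
    return float(np.mean((upper <= delta) & (lower >= -delta)))


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

class TestBlandAltman:
    def test_identical_systems(self):
        x = np.array([1.0, 1.2, 0.9, 1.1])
        r = gi.bland_altman(x, x)
        assert r.bias == 0 and r.sd_diff == 0
        assert r.loa_low == r.loa_high == 0 and r.cv_percent == 0

    def test_hand_computed_symmetric_differences(self):
        d = np.array([0.1, -0.1, 0.0, 0.2, -0.2])
        y = np.full(5, 1.0)
        r = gi.bland_altman(y + d, y)
        assert r.bias == pytest.approx(0.0)
        sd = np.sqrt(np.sum(d ** 2) / 4)      # n-1 denominator, zero mean
        assert r.sd_diff == pytest.approx(sd)
        assert r.loa_half_width == pytest.approx(1.96 * sd)

    def test_constant_offset(self):
        y = np.array([0.8, 1.0, 1.2, 1.4])
        r = gi.bland_altman(y + 0.05, y)
        assert r.bias == pytest.approx(0.05) and r.sd_diff == pytest.approx(0)

    def test_loa_half_width_identity_and_cv_scale_invariance(self, rng):
        x = rng.normal(1.0, 0.2, 30)
        y = x + rng.normal(0, 0.05, 30)
        r1 = gi.bland_altman(x, y)
        assert r1.loa_half_width == pytest.approx(1.96 * r1.sd_diff, abs=1e-12)
        r2 = gi.bland_altman(3.0 * x, 3.0 * y)
        assert r2.cv_percent == pytest.approx(r1.cv_percent, rel=1e-9)

    def test_too_few_pairs(self):
        with pytest.raises(UsageError):
            gi.bland_altman(np.ones(2), np.ones(2))


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

class TestICC:
    def test_equals_anova_oracle_on_random_tables(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 20))
            x = rng.normal(1.0, 0.5, size=(n, 2))
            x[:, 1] += rng.normal(0, 0.2, size=n)
            r = gi.icc_two_way_absolute(x)
            assert r.icc == pytest.approx(icc_a1_anova_oracle(x), abs=1e-10)
            assert r.ci_low <= r.icc <= r.ci_high

    def test_perfect_agreement(self, rng):
        col = rng.normal(1.0, 0.3, 10)
        r = gi.icc_two_way_absolute(np.column_stack([col, col]))
        assert r.icc == pytest.approx(1.0)
        assert r.cronbach_alpha == pytest.approx(1.0)
        assert r.fleiss_class == "excellent"

    def test_constant_shift_penalised_by_absolute_agreement(self, rng):
        col = rng.normal(1.0, 0.3, 60)
        shifted = np.column_stack([col, col + 0.3])
        r = gi.icc_two_way_absolute(shifted)
        assert r.icc < 1.0
        assert r.icc == pytest.approx(icc_a1_anova_oracle(shifted), abs=1e-10)
        # consistency-type alpha ignores the shift
        assert r.cronbach_alpha == pytest.approx(1.0, abs=1e-9)

    def test_hand_built_6x2_table(self):
        x = np.array([[9., 2.], [1., 1.], [8., 4.], [2., 1.], [10., 5.],
                      [3., 2.]])
        r = gi.icc_two_way_absolute(x)
        assert r.icc == pytest.approx(icc_a1_anova_oracle(x), abs=1e-10)

    def test_zero_between_subject_variance_flagged(self):
        r = gi.icc_two_way_absolute(np.ones((6, 2)))
        assert r.flagged

    def test_fleiss_classification_bands(self):
        assert gi.classify_icc(0.99) == "excellent"
        assert gi.classify_icc(0.39) == "poor"
        assert gi.classify_icc(0.40) == "fair-to-good"
        assert gi.classify_icc(0.75) == "fair-to-good"
        assert gi.classify_icc(0.751) == "excellent"
        with pytest.raises(UsageError):
            gi.classify_icc(1.5)


# ---------------------------------------------------------------------------
# mean errors, group comparison, correlation
# ---------------------------------------------------------------------------

class TestMeanErrors:
    def test_signed_and_absolute_reported_separately(self):
        me, mae = gi.mean_errors(np.array([0.0, 0.04]), np.array([0.02, 0.02]))
        assert me == pytest.approx(0.0) and mae == pytest.approx(0.02)

    def test_identical_instants(self):
        me, mae = gi.mean_errors(np.ones(4), np.ones(4))
        assert me == 0 and mae == 0

    def test_consistent_negative_differences(self):
        a = np.zeros(3)
        b = np.full(3, 0.01)
        me, mae = gi.mean_errors(a, b)
        assert me == pytest.approx(-0.01) and mae == pytest.approx(0.01)


class TestGroupCompare:
    def test_equal_means_negligible_effect(self, rng):
        a = rng.normal(0, 1, 40)
        b = a.copy()
        r = gi.group_compare(a, b)
        assert r.cohen_d == pytest.approx(0.0, abs=1e-12)
        assert r.d_class == "negligible"

    def test_one_pooled_sd_separation_is_large(self, rng):
        a = rng.normal(0, 1, 2000)
        pooled = np.sqrt(a.var(ddof=1))
        b = a + pooled
        r = gi.group_compare(b, a)
        assert r.cohen_d == pytest.approx(1.0, abs=1e-9)
        assert r.d_class == "large"

    def test_seeded_samples_near_analytic_population_d(self):
        rng = np.random.default_rng(42)
        reps = 300
        ds = []
        for _ in range(reps):
            a = rng.normal(0.81, 0.17, 25)
            b = rng.normal(0.59, 0.09, 8)
            ds.append(gi.group_compare(a, b).cohen_d)
        # population d with df-weighted pooled SD
        pooled = np.sqrt((24 * 0.17 ** 2 + 7 * 0.09 ** 2) / 31)
        pop_d = (0.81 - 0.59) / pooled
        se = np.std(ds, ddof=1) / np.sqrt(reps)
        assert np.mean(ds) == pytest.approx(pop_d, abs=4 * se + 0.05)

    def test_affine_invariance_of_t_and_d(self, rng):
        a = rng.normal(0.8, 0.2, 20)
        b = rng.normal(0.6, 0.1, 12)
        r1 = gi.group_compare(a, b)
        r2 = gi.group_compare(5.0 * a + 2.0, 5.0 * b + 2.0)
        assert r2.t_stat == pytest.approx(r1.t_stat, rel=1e-9)
        assert r2.cohen_d == pytest.approx(r1.cohen_d, rel=1e-9)

    def test_d_classification_bands(self):
        assert gi.classify_cohen_d(0.1) == "negligible"
        assert gi.classify_cohen_d(0.2) == "small"
        assert gi.classify_cohen_d(-0.6) == "moderate"
        assert gi.classify_cohen_d(0.8) == "large"


class TestCorrelate:
    def test_identity_is_very_strong(self):
        x = np.arange(10.0)
        r = gi.correlate(x, x)
        assert r.r == pytest.approx(1.0) and r.magnitude_class == "very strong"

    def test_spearman_rank_invariance_under_monotone_transform(self, rng):
        x = rng.normal(size=20)
        r = gi.correlate(x, np.exp(x), method="spearman")
        assert r.r == pytest.approx(1.0)

    def test_spearman_equals_rank_formula_on_tie_free_tables(self, rng):
        for _ in range(20):
            x = rng.permutation(6).astype(float)
            y = rng.permutation(6).astype(float)
            r = gi.correlate(x, y, method="spearman")
            assert r.r == pytest.approx(spearman_rank_formula(x, y),
                                        abs=1e-12)

    def test_constant_input_flagged(self):
        r = gi.correlate(np.ones(6), np.arange(6.0))
        assert r.flagged and np.isnan(r.r)

    def test_magnitude_bands_boundaries_to_higher_band(self):
        for val, cls in [(0.1, "very slight"), (0.2, "slight"),
                         (0.4, "moderate"), (0.6, "strong"),
                         (0.8, "very strong"), (-0.65, "strong")]:
            assert gi.classify_correlation(val) == cls


# ---------------------------------------------------------------------------
# Bland-Altman sample size
# ---------------------------------------------------------------------------

class TestBaSampleSize:
    def test_monotone_in_max_allowed_diff(self):
        n1 = gi.ba_sample_size(-0.02, 0.13, 0.40)
        n2 = gi.ba_sample_size(-0.02, 0.13, 0.80)
        n3 = gi.ba_sample_size(-0.02, 0.13, 1.60)
        assert n1 >= n2 >= n3

    def test_infinite_allowance_gives_method_minimum(self):
        assert gi.ba_sample_size(-0.02, 0.13, 1e6) == 3

    def test_unattainable_allowance_rejected(self):
        with pytest.raises(UsageError):
            gi.ba_sample_size(-0.02, 0.13, 0.20)

    def test_matches_monte_carlo_power_oracle(self):
        """Exact-power iteration vs simulated LOA-CI containment across a
        12-point parameter grid, within one subject."""
        rng = np.random.default_rng(2024)
        grid = [(b, s, d) for b in (0.0, -0.02) for s in (0.10, 0.13)
                for d in (0.40, 0.45, 0.55)]
        assert len(grid) == 12
        for bias, sd, delta in grid:
            n_star = gi.ba_sample_size(bias, sd, delta, power=0.9)
            # MC bracket: power just reached at n_star, not at n_star - 2
            p_at = mc_loa_containment_power(n_star, bias, sd, delta,
                                            8000, rng)
            assert p_at >= 0.9 - 0.015
            if n_star > 3:
                p_below = mc_loa_containment_power(n_star - 2, bias, sd,
                                                   delta, 8000, rng)
                assert p_below <= 0.9 + 0.015

    def test_internal_power_matches_mc_directly(self):
        rng = np.random.default_rng(7)
        p_exact = _ba_power(20, -0.02, 0.13, 0.45, alpha=0.05)
        p_mc = mc_loa_containment_power(20, -0.02, 0.13, 0.45, 20000, rng)
        assert p_exact == pytest.approx(p_mc, abs=0.012)


# ---------------------------------------------------------------------------
# agreement report
# ---------------------------------------------------------------------------

def _metrics(subject, vals, source):
    return gi.GIMetrics(subject_id=subject, source=source, n_trials=5,
                        time_to_apa=vals[0], time_to_toe_off=vals[1],
                        time_to_heel_strike=vals[2], apa_duration=vals[3],
                        swing_duration=vals[4])


class TestAgreementReport:
    def _tables(self, rng, noise=0.0):
        imu, fp = [], []
        for i in range(12):
            a = rng.uniform(0.3, 0.6)
            d = rng.uniform(0.5, 1.0)
            s = rng.uniform(0.35, 0.6)
            vals = np.array([a, a + d, a + d + s, d, s])
            fp.append(_metrics(f"s{i}", vals, "fp"))
            imu.append(_metrics(f"s{i}", vals + rng.normal(0, noise, 5)
                                if noise else vals, "imu"))
        return imu, fp

    def test_identical_tables_are_in_perfect_agreement(self, rng):
        imu, fp = self._tables(rng)
        rep = gi.agreement_report(imu, fp)
        for m in rep.per_metric.values():
            assert m.bland_altman.bias == pytest.approx(0.0)
            assert m.pearson.r == pytest.approx(1.0)
            assert m.slope == pytest.approx(1.0)
            assert m.icc.icc == pytest.approx(1.0)
        assert rep.summary["pearson_r"]["mean"] == pytest.approx(1.0)

    def test_regression_slope_attenuates_with_noise(self):
        rng = np.random.default_rng(11)
        slopes = []
        for noise in (0.0, 0.05, 0.15):
            imu, fp = self._tables(np.random.default_rng(3), noise=noise)
            rep = gi.agreement_report(imu, fp)
            slopes.append(np.mean([abs(m.slope - 1.0)
                                   for m in rep.per_metric.values()]))
        assert slopes[0] < slopes[1] < slopes[2] + 0.2

    def test_report_schema_complete(self, rng):
        imu, fp = self._tables(rng, noise=0.01)
        d = gi.agreement_report(imu, fp).as_dict()
        assert set(d["per_metric"]) == set(gi.METRIC_NAMES)
        for key in ("loa_half_width_s", "cv_percent", "pearson_r", "slope"):
            assert {"mean", "sd"} <= set(d["summary"][key])

    def test_too_few_matched_subjects(self):
        imu = [_metrics("a", [0.4, 1.0, 1.5, 0.6, 0.5], "imu")]
        with pytest.raises(UsageError):
            gi.agreement_report(imu, imu)
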