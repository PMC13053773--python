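"""Correlation-study engine: Pearson with exact-t p, BH within families,
bootstrap CIs, effect-size bands, power, and the sensitivity variants."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

from runcna.errors import (
    ConfigError,
    InvalidParameterError,
    UndefinedCorrelationError,
)
from runcna.stats import (
    FamilySpec,
    bh_adjust,
    bootstrap_ci,
    correlation_study,
    default_design,
    heatmap_matrices,
    interpret_r,
    min_detectable_r,
    monte_carlo_power,
    normality_report,
    pearson_power,
    pearson_with_p,
    sensitivity_variants,
)
from runcna.synthetic import planted_cohort


def bh_brute_force(p):
    """Step-up definition: adj_(i) = min_{j>=i} min(1, p_(j) * m / j)."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


class TestNormality:
    def test_large_normal_sample_not_rejected(self, rng):
        w, p = normality_report(rng.normal(0.0, 1.0, 500))
        assert p > 0.05

    def test_constant_vector_reported_invalid(self):
        with pytest.raises(UndefinedCorrelationError):
            normality_report(np.full(50, 3.0))

    def test_skewed_sample_rejected_in_most_seeds(self):
        rejections = sum(
            normality_report(np.random.default_rng(s).exponential(1.0, 50))[1] < 0.05
            for s in range(30)
        )
        assert rejections > 27  # > 90% power against exponential at n=50


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p, n = pearson_with_p(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-50
        assert n == 10

    def test_perfect_negative(self):
        x = np.arange(8.0)
        r, _, _ = pearson_with_p(x, -x)
        assert r == pytest.approx(-1.0)

    def test_p_matches_t_transform_oracle(self, rng):
        for _ in range(50):
            x, y = rng.standard_normal((2, 23))
            r, p, n = pearson_with_p(x, y)
            t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
            expected = 2 * sstats.t.sf(abs(t), n - 2)
            assert p == pytest.approx(expected, abs=1e-12)

    def test_headline_effect_size_p_value(self):
        # |r| = 0.60 at n = 23 gives t ≈ 3.44 and two-tailed p ≈ 0.0025
        t = 0.60 * math.sqrt(21) / math.sqrt(1 - 0.36)
        p = 2 * sstats.t.sf(t, 21)
        assert t == pytest.approx(3.44, abs=0.01)
        assert p == pytest.approx(0.0025, abs=0.0002)

    def test_pairwise_complete_filtering(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([2.0, 4.1, 6.0, 8.2, np.nan])
        _, _, n = pearson_with_p(x, y)
        assert n == 3

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_with_p(np.ones(10), np.arange(10.0))


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_three_value_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_equal_p_values_are_identity(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2, 0.2]), 0.2)

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 40))
            p = rng.uniform(1e-6, 1.0, m)
            np.testing.assert_allclose(bh_adjust(p), bh_brute_force(p), atol=1e-12)

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(1e-6, 1.0, 30)
        assert np.all(bh_adjust(p) >= p - 1e-15)

    @pytest.mark.parametrize("bad", [[0.0], [1.5], [-0.1], [np.nan]])
    def test_out_of_range_p_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            bh_adjust(bad)


class TestBootstrap:
    def test_degenerate_perfect_relation_gives_unit_interval(self):
        x = np.arange(10.0)
        lo, hi = bootstrap_ci(x, x, B=200, seed=1)
        assert (lo, hi) == (1.0, 1.0)

    def test_same_seed_bit_identical(self, rng):
        x, y = rng.standard_normal((2, 23))
        assert bootstrap_ci(x, y, seed=9) == bootstrap_ci(x, y, seed=9)

    def test_different_seeds_differ(self, rng):
        x, y = rng.standard_normal((2, 23))
        assert bootstrap_ci(x, y, seed=1) != bootstrap_ci(x, y, seed=2)

    def test_interval_brackets_sample_r(self, rng):
        z = rng.standard_normal((23, 2))
        x = z[:, 0]
        y = 0.6 * z[:, 0] + 0.8 * z[:, 1]
        r, _, _ = pearson_with_p(x, y)
        lo, hi = bootstrap_ci(x, y, seed=4)
        assert lo <= r <= hi


class TestInterpretR:
    @pytest.mark.parametrize("r,label", [
        (0.05, "trivial"), (0.1, "small"), (0.29, "small"), (0.3, "moderate"),
        (0.5, "large"), (-0.60, "large"), (0.7, "very large"),
        (0.95, "nearly perfect"), (1.0, "nearly perfect"),
    ])
    def test_band_boundaries_half_open_on_left(self, r, label):
        assert interpret_r(r) == label

    def test_magnitude_above_one_rejected(self):
        with pytest.raises(InvalidParameterError):
            interpret_r(1.2)


class TestPower:
    def test_size_equals_level_under_the_null(self):
        assert pearson_power(0.0, 23, alpha=0.05) == pytest.approx(0.05, abs=1e-6)

    def test_min_detectable_r_monotone_decreasing_in_n(self):
        values = [min_detectable_r(n) for n in (10, 23, 50, 100)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_min_detectable_r_monotone_increasing_in_power(self):
        assert min_detectable_r(23, power=0.9) > min_detectable_r(23, power=0.8)

    def test_solution_attains_requested_power(self):
        r = min_detectable_r(23)
        assert pearson_power(r, 23) == pytest.approx(0.80, abs=1e-8)

    def test_monte_carlo_agrees_with_exact_power(self):
        power = monte_carlo_power(0.55, 23, n_sim=5000, seed=3)
        assert power == pytest.approx(pearson_power(0.55, 23), abs=0.03)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            min_detectable_r(3)
        with pytest.raises(InvalidParameterError):
            min_detectable_r(23, alpha=1.5)


class TestCorrelationStudy:
    def test_planted_pair_has_smallest_adjusted_p(self):
        table, _ = planted_cohort(n=23, rho=-0.85, seed=2)
        results = correlation_study(table, default_design(), bootstrap_B=0)
        best = results.loc[results["p_adj"].idxmin()]
        assert (best["x"], best["y"]) == ("Kflex_ecc", "BF_cna_12")

    def test_adjusted_p_never_below_raw(self):
        table, _ = planted_cohort(n=23, seed=3)
        results = correlation_study(table, default_design(), bootstrap_B=0)
        assert np.all(results["p_adj"] >= results["p_raw"] - 1e-15)

    def test_bh_family_is_per_declared_family(self):
        table, _ = planted_cohort(n=23, seed=4)
        design = default_design()
        results = correlation_study(table, design, bootstrap_B=0)
        for fam in design:
            grp = results[results["family"] == fam.family_id]
            np.testing.assert_allclose(
                grp["p_adj"], bh_brute_force(grp["p_raw"].to_numpy()), atol=1e-12
            )

    def test_empty_design_gives_empty_output(self):
        table, _ = planted_cohort(n=23, seed=5)
        out = correlation_study(table, (), bootstrap_B=0)
        assert out.empty

    def test_self_pair_rejected(self):
        table, _ = planted_cohort(n=23, seed=5)
        fam = FamilySpec("bad", (("Kflex_ecc", "Kflex_ecc", 12.0),))
        with pytest.raises(ConfigError):
            correlation_study(table, (fam,), bootstrap_B=0)

    def test_missing_column_reported_by_name(self):
        table, _ = planted_cohort(n=23, seed=5)
        fam = FamilySpec("bad", (("no_such_var", "BF_cna_12", 12.0),))
        with pytest.raises(ConfigError, match="no_such_var"):
            correlation_study(table, (fam,), bootstrap_B=0)

    def test_seed_reproducibility_of_full_study(self):
        table, _ = planted_cohort(n=23, seed=6)
        design = default_design(speeds=(12,))
        a = correlation_study(table, design, bootstrap_B=199, seed=5)
        b = correlation_study(table, design, bootstrap_B=199, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_heatmap_matrices_are_per_family_and_speed(self):
        table, _ = planted_cohort(n=23, seed=7)
        results = correlation_study(table, default_design(), bootstrap_B=0)
        mats = heatmap_matrices(results)
        iso = mats[("isokinetic_cna", 12.0)]
        assert iso.loc["Kflex_ecc", "BF_cna_12"] == pytest.approx(
            results.query("x == 'Kflex_ecc' and y == 'BF_cna_12'")["r"].iloc[0]
        )


class TestSensitivityVariants:
    def test_constant_stride_frequency_gives_identical_r(self):
        table, _ = planted_cohort(n=23, seed=8)
        table["stride_freq_spm"] = 180.0
        for col in [c for c in table.columns if "_cna_" in c]:
            table[col.replace("_cna_", "_iemg_")] = table[col] / 180.0
        out = sensitivity_variants(table, default_design(speeds=(12,)))
        variant = out["per_cycle_iemg"].copy()
        variant["y"] = variant["y"].str.replace("_iemg_", "_cna_", regex=False)
        merged = out["main"].merge(variant, on=["x", "y", "speed"],
                                   suffixes=("_m", "_v"))
        assert len(merged) == len(out["main"])
        np.testing.assert_allclose(merged["r_m"], merged["r_v"], atol=1e-12)

    def test_proportional_ffm_gives_identical_r(self):
        table, _ = planted_cohort(n=23, seed=9)
        table["ffm_kg"] = 0.85 * table["body_mass_kg"]
        out = sensitivity_variants(table, default_design(speeds=(12,)))
        np.testing.assert_allclose(
            out["main"]["r"], out["ffm_normalized"]["r"], atol=1e-12
        )

    def test_planted_pair_signs_agree_across_variants(self):
        table, _ = planted_cohort(n=23, rho=-0.7, seed=10)
        out = sensitivity_variants(table, default_design())
        agreement = out["sign_agreement"]
        assert set(agreement["variant"]) == {"per_cycle_iemg", "ffm_normalized"}
        assert (agreement["n_pairs"] == 240).all()


@given(scale=st.floats(0.1, 50.0), shift=st.floats(-100.0, 100.0))
@settings(max_examples=40, derandomize=True)
def test_r_invariant_to_positive_affine_rescaling(scale, shift):
    rng = np.random.default_rng(0)
    x, y = rng.standard_normal((2, 30))
    r0, _, _ = pearson_with_p(x, y)
    r1, _, _ = pearson_with_p(scale * x + shift, y)
    r2, _, _ = pearson_with_p(-scale * x + shift, y)
    assert r1 == pytest.approx(r0, abs=1e-9)
    assert r2 == pytest.approx(-r0, abs=1e-9)
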