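import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st

from colonygrid import (
    FORMAT_384, FORMAT_1536_QUAD, MeasurementTable, PlateKey,
    ExclusionParams, NormalizationConfig, StatConfig,
    bonferroni, exclude_global, exclude_replicates, normalize,
    pvalues_mannwhitney, pvalues_normal, pvalues_welch, review_pipeline,
    shimazaki_bin_width, strain_ratios,
)
from colonygrid.errors import ConfigError, NormalizationError, PairingError
from colonygrid.synthplate import simulate_null_ratios


def table_from_values(values, plate="p1", condition="control"):
    values = np.asarray(values, dtype=float)
    rows, cols = values.shape
    recs = [(plate, condition, r + 1, c + 1, values[r, c])
            for r in range(rows) for c in range(cols)]
    return MeasurementTable(pd.DataFrame(
        recs, columns=["plate", "condition", "row", "col", "value"]))


# ---------------------------------------------------------------------------
# normalization


class TestNormalize:
    def test_plate_median(self):
        t = table_from_values(np.array([[2, 4, 6, 8, 10.0]]))
        out = normalize(t, NormalizationConfig("plate_median"))
        np.testing.assert_allclose(
            out.data["value"], [1 / 3, 2 / 3, 1.0, 4 / 3, 5 / 3], rtol=1e-9)

    def test_none_is_identity(self):
        t = table_from_values(np.arange(12.0).reshape(3, 4))
        out = normalize(t, NormalizationConfig("none"))
        assert out == t

    def test_designated_controls_even_median(self):
        # controls {8,8,10,10}: divisor 9 (mean of the middle two)
        df = pd.DataFrame({
            "plate": "p1", "condition": "c",
            "row": [1] * 5, "col": list(range(1, 6)),
            "value": [8.0, 8.0, 10.0, 10.0, 18.0],
            "control": [True, True, True, True, False],
            "strain": list("abcde"), "orf": list("abcde"),
        })
        out = normalize(MeasurementTable(df),
                        NormalizationConfig("designated_controls"))
        assert out.data["value"].iloc[4] == pytest.approx(2.0)

    def test_zero_median_is_error(self):
        t = table_from_values(np.zeros((2, 3)))
        with pytest.raises(NormalizationError, match="p1"):
            normalize(t, NormalizationConfig("plate_median"))

    def test_normalized_median_is_one(self, rng):
        t = table_from_values(rng.lognormal(0, 0.3, (16, 24)) * 100)
        out = normalize(t, NormalizationConfig("plate_median"))
        assert np.median(out.data["value"]) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# exclusion: brute-force fixed-point oracle (asynchronous, random order)


def oracle_global_exclusion(vals, params=ExclusionParams(), rng=None):
    rows, cols = vals.shape
    low = vals < params.low_growth_fraction
    excl = np.zeros_like(low)
    order = [(i, j) for i in range(rows) for j in range(cols)]
    changed = True
    while changed:
        changed = False
        if rng is not None:
            rng.shuffle(order)
        for i, j in order:
            if excl[i, j] or not low[i, j]:
                continue
            nbs = [(a, b) for a in range(i - 1, i + 2) for b in range(j - 1, j + 2)
                   if (a, b) != (i, j) and 0 <= a < rows and 0 <= b < cols]
            k = len(nbs)
            n_low = sum(low[a, b] for a, b in nbs)
            n_exc = sum(excl[a, b] for a, b in nbs)
            if (n_low >= math.ceil(params.neighbor_low_count * k / 8)
                    or n_exc >= math.ceil(params.neighbor_excluded_count * k / 8)):
                excl[i, j] = True
                changed = True
    return excl


class TestGlobalExclusion:
    def test_dead_block_fully_excluded_far_cells_untouched(self):
        g = np.ones((16, 24))
        g[:4, :6] = 0.0
        mask = exclude_global(g)
        assert mask[:4, :6].all()
        assert not mask[4:, :].any() and not mask[:, 6:].any()

    def test_uniform_plate_nothing_excluded(self):
        assert not exclude_global(np.ones((16, 24))).any()

    def test_isolated_zero_not_excluded(self):
        g = np.ones((16, 24))
        g[8, 12] = 0.0
        assert not exclude_global(g).any()

    def test_matches_bruteforce_oracle_on_random_grids(self, rng):
        for _ in range(30):
            g = rng.choice([0.0, 0.1, 0.5, 1.0, 1.5],
                           size=(16, 24), p=[0.2, 0.1, 0.1, 0.4, 0.2])
            np.testing.assert_array_equal(
                exclude_global(g), oracle_global_exclusion(g, rng=rng))

    def test_fixed_point_order_independent(self, rng):
        g = rng.choice([0.0, 1.0], size=(16, 24), p=[0.3, 0.7])
        a = oracle_global_exclusion(g, rng=None)
        b = oracle_global_exclusion(g, rng=rng)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(exclude_global(g), a)


class TestReplicateExclusion:
    def grid_with_block(self, block):
        g = np.ones((32, 48))
        g[0:2, 0:2] = np.asarray(block).reshape(2, 2)
        return g

    def test_single_outlier_excluded(self):
        m = exclude_replicates(self.grid_with_block([1.0, 1.0, 1.0, 0.2]),
                               FORMAT_1536_QUAD)
        assert m[0:2, 0:2].sum() == 1
        assert m[np.unravel_index(np.argmax(m[0:2, 0:2]), (2, 2))]
        assert m.sum() == 1

    def test_concordant_block_kept(self):
        m = exclude_replicates(self.grid_with_block([1.0, 1.0, 1.0, 1.0]),
                               FORMAT_1536_QUAD)
        assert not m.any()

    def test_non_quad_layout_warns_and_skips(self):
        with pytest.warns(UserWarning, match="quad"):
            m = exclude_replicates(np.ones((16, 24)), FORMAT_384)
        assert not m.any()

    def test_literal_reading_flips_selection(self):
        g = self.grid_with_block([1.0, 1.0, 1.0, 0.2])
        m = exclude_replicates(g, FORMAT_1536_QUAD,
                               ExclusionParams(literal_within_band=True))
        # literal mode excludes the concordant replicates instead
        assert m[0:2, 0:2].sum() == 3


# ---------------------------------------------------------------------------
# ratios and statistics


class TestStrainRatios:
    def annotated(self, values, excluded=None, plate="p1", condition="c"):
        n = len(values)
        df = pd.DataFrame({
            "plate": plate, "condition": condition,
            "row": np.arange(1, n + 1), "col": 1,
            "value": values,
            "strain": [f"s{i // 4}" for i in range(n)],   # 4 reps per strain
            "orf": [f"O{i // 4}" for i in range(n)],
            "excluded": excluded if excluded is not None else [False] * n,
        })
        return df

    def test_basic_ratio_and_log(self):
        c = self.annotated([1.0] * 4)
        e = self.annotated([0.5] * 4)
        out = strain_ratios(c, e)
        assert out["growth_ratio"].iloc[0] == pytest.approx(0.5)
        assert out["log_ratio"].iloc[0] == pytest.approx(math.log(2))

    def test_equal_means_log_zero(self):
        c = self.annotated([1.0, 1.2, 0.8, 1.0])
        e = self.annotated([1.0, 1.2, 0.8, 1.0])
        assert strain_ratios(c, e)["log_ratio"].iloc[0] == pytest.approx(0.0)

    def test_excluded_replicate_omitted(self):
        c = self.annotated([1.0] * 4)
        e = self.annotated([0.3, 0.3, 0.3, 9.9], excluded=[False] * 3 + [True])
        out = strain_ratios(c, e)
        assert out["experimental_mean"].iloc[0] == pytest.approx(0.3)
        assert out["n_experimental"].iloc[0] == 3
        assert out["excluded_count"].iloc[0] == 1

    def test_dead_on_experimental_sentinel(self):
        c = self.annotated([1.0] * 4)
        e = self.annotated([0.0] * 4)
        out = strain_ratios(c, e)
        assert out["log_ratio"].iloc[0] == np.inf
        assert out["growth_ratio"].iloc[0] == 0.0


class TestNormalMethod:
    def test_population_mean_scores_zero(self):
        x = np.array([-1.0, 0.0, 1.0, 2.0, -2.0])
        z, p = pvalues_normal(x)
        assert z[1] == pytest.approx(0.0)
        assert p[1] == pytest.approx(1.0)

    def test_population_sd_convention(self):
        z, _ = pvalues_normal(np.array([-1.0, 0.0, 1.0]))
        assert z[2] == pytest.approx(1.224744871, abs=1e-6)

    def test_z_to_p_via_erfc_oracle(self):
        # |z| = 1.959964 -> p ~ 0.05 (complementary error function)
        x = np.array([0.0, 0.0, 1.0, -1.0, 1.959964 * np.sqrt(0.5 + 1.959964 ** 2 / 4)])
        z, p = pvalues_normal(x)
        zq = z[-1]
        assert p[-1] == pytest.approx(math.erfc(abs(zq) / math.sqrt(2)), rel=1e-9)

    def test_nonfinite_ratios_dropped(self):
        x = np.array([-1.0, 0.0, 1.0, np.inf, np.nan])
        z, p = pvalues_normal(x)
        assert np.isnan(z[3]) and np.isnan(z[4])
        assert z[2] == pytest.approx(1.224744871, abs=1e-6)

    def test_degenerate_sd_raises(self):
        with pytest.raises(ValueError):
            pvalues_normal(np.array([1.0, 1.0, 1.0]))


class TestWelch:
    def test_identical_samples(self):
        t, df, p = pvalues_welch(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_longhand_formula_oracle(self):
        a = np.array([10.0, 11, 9, 10])
        b = np.array([5.0, 6, 4, 5])
        t, df, p = pvalues_welch(a, b)
        # long-hand: means 10 and 5, s^2 = 2/3 each, n = 4
        se2 = (2 / 3) / 4 + (2 / 3) / 4
        t_hand = 5 / math.sqrt(se2)
        df_hand = se2 ** 2 / (((2 / 3) / 4) ** 2 / 3 + ((2 / 3) / 4) ** 2 / 3)
        assert t == pytest.approx(t_hand, abs=1e-10)
        assert df == pytest.approx(df_hand, abs=1e-10)
        assert p == pytest.approx(2 * sps.t.sf(t_hand, df_hand), abs=1e-12)

    def test_matches_scipy_on_random_data(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(2, 8))
            b = rng.normal(0.5, 2, rng.integers(2, 8))
            t, df, p = pvalues_welch(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_variance_free_equal_samples(self):
        t, df, p = pvalues_welch(np.array([2.0, 2.0]), np.array([2.0, 2.0]))
        assert p == 1.0

    def test_variance_free_unequal_means_sentinel(self):
        with pytest.warns(UserWarning):
            _, _, p = pvalues_welch(np.array([2.0, 2.0]), np.array([3.0, 3.0]))
        assert p == 0.0


class TestMannWhitney:
    def test_disjoint_samples_exact(self):
        u, p = pvalues_mannwhitney(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert u == 0.0
        assert p == pytest.approx(0.1)      # 2/C(6,3) = 0.1

    def test_symmetric_interleaved_p_one(self):
        u, p = pvalues_mannwhitney(np.array([1.0, 4, 5, 8]),
                                   np.array([2.0, 3, 6, 7]))
        assert p == pytest.approx(1.0)

    def test_exact_matches_scipy_enumeration(self, rng):
        for _ in range(40):
            n1, n2 = rng.integers(1, 9, 2)
            a = rng.normal(0, 1, n1)
            b = rng.normal(0.3, 1, n2)
            _, p = pvalues_mannwhitney(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="exact").pvalue
            assert p == pytest.approx(ref, abs=1e-12)

    def test_approximation_close_to_exact_at_switch(self, rng):
        # n1 = n2 = 12 crosses the 20-sample switch to the approximation
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.8, 1, 12)
        _, p_approx = pvalues_mannwhitney(a, b)            # n = 24 > 20
        ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="exact").pvalue
        assert p_approx == pytest.approx(ref, abs=0.02)

    def test_ties_handled_in_exact_branch(self):
        a = np.array([1.0, 2.0, 2.0])
        b = np.array([2.0, 3.0, 4.0])
        _, p = pvalues_mannwhitney(a, b)
        assert 0.0 < p <= 1.0


class TestBonferroni:
    def test_simple_product(self):
        assert bonferroni(0.001, 10) == pytest.approx(0.01)

    def test_clamped_at_one(self):
        assert bonferroni(0.01, 384) == 1.0

    def test_zero_stays_zero(self):
        assert bonferroni(0.0, 10 ** 6) == 0.0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(p=st.floats(0, 1), m1=st.integers(1, 1000), m2=st.integers(1, 1000))
    def test_never_decreases_and_monotone_in_m(self, p, m1, m2):
        lo, hi = sorted([m1, m2])
        assert bonferroni(p, lo) >= p
        assert bonferroni(p, hi) >= bonferroni(p, lo)


class TestShimazaki:
    def oracle_best_width(self, data, widths):
        """Independent cost computation using np.digitize binning."""
        x = np.sort(np.asarray(data, float))
        best, best_c = None, np.inf
        for w in widths:
            nbins = int(np.ceil((x[-1] - x[0]) / w))
            edges = x[0] + w * np.arange(nbins + 1)
            counts = np.array([((x >= lo) & (x < hi)).sum()
                               for lo, hi in zip(edges[:-1], edges[1:])])
            counts[-1] += (x == edges[-1]).sum()    # close the last bin
            c = (2 * counts.mean() - counts.var()) / w ** 2
            if c < best_c:
                best, best_c = w, c
        return best

    def test_matches_grid_search_oracle(self, rng):
        data = rng.normal(10, 2, 200)
        span = data.max() - data.min()
        widths = np.geomspace(span / 200, span / 2, 64)
        assert shimazaki_bin_width(data) == pytest.approx(
            self.oracle_best_width(data, widths))

    def test_scale_equivariance(self, rng):
        data = rng.normal(0, 1, 300)
        w1 = shimazaki_bin_width(data)
        w10 = shimazaki_bin_width(data * 10)
        assert w10 == pytest.approx(10 * w1, rel=0.05)

    def test_two_distinct_values(self):
        w = shimazaki_bin_width(np.array([0.0, 1.0, 0.0, 1.0]))
        assert w > 0 and np.isfinite(w)

    def test_identical_values_raise(self):
        with pytest.raises(ValueError):
            shimazaki_bin_width(np.ones(10))


# ---------------------------------------------------------------------------
# calibration and pipeline


class TestCalibration:
    def test_normal_method_null_rate(self):
        ctrl, exp = simulate_null_ratios(2000, 4, seed=42)
        logr = np.log(ctrl.mean(axis=1) / exp.mean(axis=1))
        _, p = pvalues_normal(logr)
        assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.02)

    def test_welch_null_rate(self):
        ctrl, exp = simulate_null_ratios(1000, 4, seed=7)
        p = np.array([pvalues_welch(c, e)[2] for c, e in zip(ctrl, exp)])
        assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.025)

    def test_mannwhitney_null_rate(self):
        # exact p-values at n=4+4 are discrete: count rejections at the
        # achievable level closest to 0.05 (2*1/70 ~ 0.0286 per tail)
        ctrl, exp = simulate_null_ratios(800, 4, seed=9)
        p = np.array([pvalues_mannwhitney(c, e)[1] for c, e in zip(ctrl, exp)])
        rate = (p <= 0.05).mean()
        assert rate == pytest.approx(2 / 70, abs=0.02)


def build_screen_tables(n_strains=96, hits=(), seed=0, ratio=0.3):
    """Numbers-only paired-plate screen (no images) for pipeline tests."""
    rng = np.random.default_rng(seed)
    rows, cols = 8, 12
    fmt = None
    recs, keyrecs = [], []
    base = rng.lognormal(0, 0.05, n_strains) * 200
    k = 0
    for r in range(1, rows + 1):
        for c in range(1, cols + 1):
            sid = f"s{k:03d}"
            mult = ratio if sid in hits else 1.0
            recs.append(("p1", "control", r, c, base[k]))
            recs.append(("p1", "treated", r, c, base[k] * mult
                         * rng.lognormal(0, 0.05)))
            keyrecs.append(("p1", r, c, sid, f"O{k}", 0))
            k += 1
    table = MeasurementTable(pd.DataFrame(
        recs, columns=["plate", "condition", "row", "col", "value"]))
    key = PlateKey(pd.DataFrame(
        keyrecs, columns=["plate", "row", "col", "strain", "orf", "control"]))
    from colonygrid import GridFormat
    return table, key, GridFormat(96, 8, 12)


class TestReviewPipeline:
    def test_planted_hits_recovered(self):
        hits = {f"s{i:03d}" for i in (3, 17, 42, 55, 80)}
        table, key, fmt = build_screen_tables(hits=hits, seed=1)
        rev = review_pipeline(table, key, fmt)
        flagged = set(rev.stats.loc[rev.stats["growth_ratio"] <= 0.5, "strain"])
        assert flagged == hits

    def test_manual_exclusion_masks_position(self):
        table, key, fmt = build_screen_tables(seed=2)
        manual = pd.DataFrame([("p1", "treated", 1, 1, 1)],
                              columns=["plate", "condition", "row", "col", "flag"])
        rev = review_pipeline(table, key, fmt, manual_exclusions=manual)
        s0 = rev.stats[rev.stats["strain"] == "s000"].iloc[0]
        assert s0["n_experimental"] == 0
        assert s0["excluded_count"] == 1

    def test_empty_manual_equals_automatic(self):
        table, key, fmt = build_screen_tables(seed=3)
        rev_a = review_pipeline(table, key, fmt)
        rev_b = review_pipeline(table, key, fmt,
                                manual_exclusions=pd.DataFrame(
                                    columns=["plate", "condition", "row",
                                             "col", "flag"]))
        pd.testing.assert_frame_equal(rev_a.stats, rev_b.stats)

    def test_unpaired_condition_raises(self):
        table, key, fmt = build_screen_tables(seed=4)
        t2 = MeasurementTable(
            table.data[table.data["condition"] == "treated"].reset_index(drop=True))
        with pytest.raises(PairingError):
            review_pipeline(t2, key, fmt)

    def test_bonferroni_rejected_for_normal_method(self):
        with pytest.raises(ConfigError):
            StatConfig(test="normal_distribution", bonferroni=True)

    def test_welch_pipeline_on_quad_plate(self):
        # quad layout: 4 replicates per strain on an 8x12 grid -> 24 strains
        from colonygrid import GridFormat
        fmt = GridFormat(96, 8, 12, replicate_layout="quad_2x2")
        rng = np.random.default_rng(5)
        recs, keyrecs = [], []
        for r in range(1, 9):
            for c in range(1, 13):
                sid = f"s{(r - 1) // 2}_{(c - 1) // 2}"
                mult = 0.3 if sid == "s0_0" else 1.0
                recs.append(("p1", "control", r, c, 200 * rng.lognormal(0, 0.05)))
                recs.append(("p1", "treated", r, c,
                             200 * mult * rng.lognormal(0, 0.05)))
                keyrecs.append(("p1", r, c, sid, sid.upper(), 0))
        table = MeasurementTable(pd.DataFrame(
            recs, columns=["plate", "condition", "row", "col", "value"]))
        key = PlateKey(pd.DataFrame(
            keyrecs, columns=["plate", "row", "col", "strain", "orf", "control"]))
        rev = review_pipeline(table, key, fmt,
                              stat_config=StatConfig(test="welch_t",
                                                     bonferroni=True))
        hit = rev.stats[rev.stats["strain"] == "s0_0"].iloc[0]
        others = rev.stats[rev.stats["strain"] != "s0_0"]
        assert hit["p_adjusted"] < 0.05
        assert hit["growth_ratio"] <= 0.5
        assert (others["growth_ratio"] > 0.5).all()
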