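import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from lfcnet.montage import CHANNELS, all_pairs
from lfcnet.stats import (
    all_band_statistics,
    bh_fdr,
    build_stat_matrix,
    compute_band_statistics,
    group_delta,
    matrix_to_frame,
    pooled_ttest,
    select_lying_connections,
)


def divisional_frame(values: dict, band="theta", period="3#"):
    """Long-format table from {pair: (guilty values, innocent values)}."""
    rows = []
    trial = 0
    for pair, (g, i) in values.items():
        for v in g:
            rows.append(dict(trial=trial, subject="g1", group="guilty",
                             stim="P", pair=pair, band=band, period=period,
                             wc=v, n_valid=10))
            trial += 1
        for v in i:
            rows.append(dict(trial=trial, subject="i1", group="innocent",
                             stim="P", pair=pair, band=band, period=period,
                             wc=v, n_valid=10))
            trial += 1
    return pd.DataFrame(rows)


class TestPooledTTest:
    def test_df_is_3118_for_the_full_cohort_sizes(self, rng):
        a = rng.random(1560)
        b = rng.random(1560)
        _, _, df = pooled_ttest(a, b)
        assert df == 3118

    def test_identical_samples_give_t0_p1(self):
        a = np.array([0.2, 0.4, 0.6])
        t, p, _ = pooled_ttest(a, a.copy())
        assert t == 0.0 and p == 1.0

    def test_matches_closed_form_pooled_variance_formula(self):
        # hand oracle: means 2 and 3, both variances 1, pooled var 1,
        # se = sqrt(1/3 + 1/3), t = -1/se = -sqrt(3/2)
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 3.0, 4.0])
        t, p, df = pooled_ttest(a, b)
        assert np.isclose(t, -np.sqrt(1.5), rtol=1e-12)
        assert df == 4
        assert np.isclose(p, 2 * sp_stats.t.sf(np.sqrt(1.5), 4), rtol=1e-10)

    def test_zero_variance_with_unequal_means_yields_p0(self):
        t, p, _ = pooled_ttest(np.ones(5), np.full(5, 2.0))
        assert p == 0.0 and np.isinf(t)

    def test_undersized_samples_rejected(self):
        with pytest.raises(ValueError):
            pooled_ttest(np.array([1.0]), np.array([1.0, 2.0]))


class TestBHFDR:
    def test_canonical_step_up_example_rejects_four(self):
        p = np.array([0.001, 0.01, 0.02, 0.04, 0.9])
        corrected, reject = bh_fdr(p, q=0.05)
        assert reject.sum() == 4
        assert not reject[-1]
        # corrected p monotone in the raw ordering
        order = np.argsort(p)
        assert np.all(np.diff(corrected[order]) >= -1e-12)

    def test_all_ones_reject_nothing(self):
        _, reject = bh_fdr(np.ones(10))
        assert reject.sum() == 0

    def test_all_zeros_reject_everything(self):
        _, reject = bh_fdr(np.zeros(10))
        assert reject.all()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))


class TestStatMatrices:
    def test_huge_group_difference_forces_the_pairs_element(self, rng):
        values = {}
        for a, b in all_pairs():
            pair = f"{a}-{b}"
            g = 0.3 + 0.02 * rng.standard_normal(30)
            i = 0.3 + 0.02 * rng.standard_normal(30)
            if pair == "Fz-C4":  # canonical (index-ordered) label
                g = g + 0.5
            values[pair] = (g, i)
        M, tests = build_stat_matrix(divisional_frame(values), "theta", "3#")
        i, j = CHANNELS.index("C4"), CHANNELS.index("Fz")
        assert M[i, j] == 1 and M[j, i] == 1
        assert np.all(np.diag(M) == 0)
        np.testing.assert_array_equal(M, M.T)

    def test_labelled_export_has_channel_headers(self):
        M = np.zeros((12, 12), dtype=int)
        frame = matrix_to_frame(M)
        assert list(frame.columns) == list(CHANNELS)
        assert list(frame.index) == list(CHANNELS)


class TestSelection:
    @pytest.mark.parametrize(
        "m1,m3,expected", [(0, 1, 1), (1, 1, 0), (0, 0, 0), (1, 0, 0)]
    )
    def test_selection_rule_truth_table(self, m1, m3, expected):
        M1 = np.zeros((12, 12), dtype=int)
        M3 = np.zeros((12, 12), dtype=int)
        M1[0, 1] = M1[1, 0] = m1
        M3[0, 1] = M3[1, 0] = m3
        L, pairs = select_lying_connections(M1, M3)
        assert L[0, 1] == expected
        assert (len(pairs) == 1) == bool(expected)

    def test_empty_m3_gives_empty_selection(self):
        L, pairs = select_lying_connections(np.ones((12, 12), int), np.zeros((12, 12), int))
        assert L.sum() == 0 and pairs == []

    def test_random_matrices_match_elementwise_boolean_oracle(self, rng):
        for _ in range(20):
            M1 = rng.integers(0, 2, (12, 12))
            M1 = (M1 | M1.T)
            M3 = rng.integers(0, 2, (12, 12))
            M3 = (M3 | M3.T)
            L, _ = select_lying_connections(M1, M3)
            # brute-force truth table, element by element
            for i in range(12):
                for j in range(12):
                    expected = int((not M1[i, j]) and M3[i, j]) if i != j else 0
                    assert L[i, j] == expected


class TestGroupDelta:
    def test_hand_arithmetic(self):
        table = divisional_frame({"C4-Fz": ([0.7, 0.8], [0.6, 0.6])})
        assert np.isclose(group_delta(table, "C4-Fz", "theta", "3#"), 0.15)

    def test_equal_means_give_zero(self):
        table = divisional_frame({"C4-Fz": ([0.5, 0.7], [0.6, 0.6])})
        assert np.isclose(group_delta(table, "C4-Fz", "theta", "3#"), 0.0)

    def test_sign_flips_when_groups_swap(self):
        base = divisional_frame({"C4-Fz": ([0.7, 0.8], [0.5, 0.5])})
        swapped = base.copy()
        swapped["group"] = swapped["group"].map(
            {"guilty": "innocent", "innocent": "guilty"}
        )
        d1 = group_delta(base, "C4-Fz", "theta", "3#")
        d2 = group_delta(swapped, "C4-Fz", "theta", "3#")
        assert np.isclose(d1, -d2)

    def test_missing_group_rejected(self):
        table = divisional_frame({"C4-Fz": ([0.7], [])})
        with pytest.raises(ValueError):
            group_delta(table, "C4-Fz", "theta", "3#")


class TestFDRFamilies:
    def test_global_family_is_no_more_permissive_than_per_area(self, rng):
        from lfcnet.stats import all_band_statistics

        values = {}
        for a, b in all_pairs():
            pair = f"{a}-{b}"
            g = 0.3 + 0.05 * rng.standard_normal(25)
            i = 0.3 + 0.05 * rng.standard_normal(25)
            if pair in ("Fz-C4", "F3-P3"):
                g = g + 0.12  # concentrated effects in one band's 3# area
            values[pair] = (g, i)
        table = pd.concat(
            [divisional_frame(values, period=p) for p in ("1#", "3#")],
            ignore_index=True,
        )
        per_area = all_band_statistics(table, family="per-area")
        global_ = all_band_statistics(table, family="global")
        n_pa = sum(sm.M3.sum() for sm, _ in per_area.values())
        n_gl = sum(sm.M3.sum() for sm, _ in global_.values())
        assert n_gl <= n_pa
        with pytest.raises(ValueError, match="family"):
            all_band_statistics(table, family="bonferroni")


class TestBandStatistics:
    def test_full_band_computation_is_deterministic(self, rng):
        values = {
            f"{a}-{b}": (0.3 + 0.05 * rng.standard_normal(20),
                         0.3 + 0.05 * rng.standard_normal(20))
            for a, b in all_pairs()
        }
        table = pd.concat(
            [divisional_frame(values, period=p) for p in ("1#", "3#")],
            ignore_index=True,
        )
        sm1, dt1 = compute_band_statistics(table, "theta")
        sm2, dt2 = compute_band_statistics(table, "theta")
        np.testing.assert_array_equal(sm1.L, sm2.L)
        assert dt1.table.equals(dt2.table)
        # L = (NOT M1) AND M3, verifiable by recomputation
        np.testing.assert_array_equal(sm1.L, (1 - sm1.M1) & sm1.M3)
        # delta values bounded by construction of WC in [0, 1]
        assert dt1.table["delta3"].abs().max() <= 1.0
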