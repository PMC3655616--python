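import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import eegbico as eb
from eegbico.stats import DegenerateDataError

from oracles import exact_ranksum_p


class TestPairedT:
    def test_identical_samples(self):
        cmp = eb.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert cmp.statistic == 0.0 and cmp.p_value == 1.0

    def test_constant_nonzero_difference_degenerate(self):
        with pytest.raises(DegenerateDataError):
            eb.paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_hand_computed_statistic(self):
        # diffs [-1,-2,-3]: mean -2, sd 1, n 3 -> t = -2/(1/sqrt(3)) = -3.46
        cmp = eb.paired_t([1, 2, 3], [2, 4, 6])
        assert cmp.statistic == pytest.approx(-3.464, abs=5e-4)


class TestUnpairedT:
    def test_identical_groups(self):
        cmp = eb.unpaired_t([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert cmp.statistic == 0.0 and cmp.p_value == pytest.approx(1.0)

    def test_separated_groups_tiny_p(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 0.1, size=10)
        cmp = eb.unpaired_t(y + 100, y[::-1])
        assert cmp.p_value < 1e-6

    def test_agrees_with_permutation_oracle_small_n(self):
        """Welch p on n=4+4 within the coarse resolution of the exhaustive
        permutation distribution of the t statistic."""
        from itertools import combinations
        from scipy import stats as sps

        x = np.array([3.1, 4.5, 2.8, 5.0])
        y = np.array([1.2, 2.0, 0.8, 1.5])
        t_obs = eb.unpaired_t(x, y).statistic
        pooled = np.concatenate([x, y])
        count = total = 0
        for idx in combinations(range(8), 4):
            xa = pooled[list(idx)]
            yb = pooled[[i for i in range(8) if i not in idx]]
            t = sps.ttest_ind(xa, yb, equal_var=False).statistic
            total += 1
            count += abs(t) >= abs(t_obs) - 1e-12
        p_perm = count / total
        p_welch = eb.unpaired_t(x, y).p_value
        # with complete separation the permutation p bottoms out at 2/70
        assert p_welch < 0.05 and abs(p_perm - 2 / 70) < 1e-12

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            eb.unpaired_t([1.0], [1.0, 2.0])


class TestWilcoxonRanksum:
    def test_most_extreme_assignment_two_vs_two(self):
        # one-tailed p = 1/6 (most extreme of C(4,2) rank assignments);
        # two-sided doubles it
        cmp = eb.wilcoxon_ranksum([1, 2], [3, 4])
        assert cmp.p_value == pytest.approx(2 / 6)
        assert cmp.method == "exact"

    def test_identical_multisets_give_p_one_with_ties_handled(self):
        cmp = eb.wilcoxon_ranksum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert cmp.p_value == pytest.approx(1.0)

    def test_rank_invariance_under_monotone_transform(self):
        x = np.array([0.3, 1.7, 2.2, 5.0])
        y = np.array([0.9, 2.5, 3.1])
        a = eb.wilcoxon_ranksum(x, y)
        b = eb.wilcoxon_ranksum(np.exp(x), np.exp(y))
        assert a.statistic == b.statistic and a.p_value == b.p_value

    def test_all_identical_degenerate(self):
        with pytest.raises(DegenerateDataError):
            eb.wilcoxon_ranksum([2.0, 2.0], [2.0, 2.0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=2, max_value=6),
        st.integers(min_value=2, max_value=6),
        st.randoms(use_true_random=False),
    )
    def test_exact_p_equals_enumeration(self, n1, n2, rnd):
        """Exact two-sided p matches brute-force rank enumeration for
        combined n <= 12 without ties."""
        vals = rnd.sample(range(1000), n1 + n2)
        x = np.array(vals[:n1], dtype=float)
        y = np.array(vals[n1:], dtype=float)
        cmp = eb.wilcoxon_ranksum(x, y)
        assert cmp.p_value == pytest.approx(exact_ranksum_p(x, y), abs=1e-9)


class TestTypeIError:
    def test_paired_t_calibrated_on_gaussian_null(self):
        """Rejection rate at alpha=0.05 within [0.03, 0.07] over 2000
        Gaussian-null replicates."""
        from scipy import stats as sps

        rng = np.random.default_rng(2024)
        n_rep, n = 2000, 12
        x = rng.normal(size=(n_rep, n))
        y = rng.normal(size=(n_rep, n))
        p = sps.ttest_rel(x, y, axis=1).pvalue
        rate = float(np.mean(p < 0.05))
        assert 0.03 <= rate <= 0.07


class TestPerChannelScreen:
    def _tables(self, n_units=10, n_channels=14, effect=None, seed=0):
        rng = np.random.default_rng(seed)
        bands = ["delta", "theta", "alpha", "beta", "gamma"]
        channels = [f"C{i}" for i in range(n_channels)]
        rows_a, rows_b = [], []
        for u in range(n_units):
            for ch in channels:
                for band in bands:
                    base = rng.normal(10, 1)
                    shift = 0.0
                    if effect and (ch, band) == effect[:2]:
                        shift = effect[2]
                    rows_b.append({"unit": u, "channel": ch, "band": band,
                                   "value": base})
                    rows_a.append({"unit": u, "channel": ch, "band": band,
                                   "value": base + rng.normal(shift, 1)})
        return pd.DataFrame(rows_a), pd.DataFrame(rows_b)

    def test_null_false_positive_rate_matches_alpha(self):
        """14 channels x 5 bands at alpha=0.05: pooled false positives over
        the replicates stay inside the binomial 95% band (3.5/replicate
        expected)."""
        total = 0
        n_rep = 900
        for rep in range(n_rep):
            after, before = self._tables(seed=rep)
            out = eb.per_channel_screen(after, before)
            total += int(out["significant"].sum())
        from scipy import stats as sps

        n_cells = 70 * n_rep
        lo, hi = sps.binom.interval(0.95, n_cells, 0.05)
        assert lo <= total <= hi

    def test_injected_effect_flagged_in_right_cell(self):
        after, before = self._tables(effect=("C3", "beta", 5.0), seed=1)
        out = eb.per_channel_screen(after, before)
        hit = out[(out.channel == "C3") & (out.band == "beta")]
        assert bool(hit["significant"].iloc[0])

    def test_alpha_zero_empty_mask(self):
        after, before = self._tables(seed=2)
        out = eb.per_channel_screen(after, before, alpha=1e-300)
        assert not out["significant"].any()

    def test_mismatched_cells_rejected(self):
        after, before = self._tables(n_channels=3)
        with pytest.raises(ValueError):
            eb.per_channel_screen(after[after.channel != "C0"], before)

    def test_fdr_mode_recorded_and_no_less_conservative(self):
        after, before = self._tables(seed=3)
        raw = eb.per_channel_screen(after, before)
        fdr = eb.per_channel_screen(after, before, fdr=True)
        assert (fdr["correction"] == "fdr_bh").all()
        assert fdr["significant"].sum() <= raw["significant"].sum()
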