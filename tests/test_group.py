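import numpy as np
import pytest

import evreg as ev
from evreg.firstlevel import FirstLevelResult


def _result(coef, pid=0):
    coef = np.asarray(coef, dtype=float)
    n_reg, n_chan, n_time = coef.shape
    return FirstLevelResult(
        pid, coef, [f"r{i}" for i in range(n_reg)],
        [f"c{i}" for i in range(n_chan)],
        np.arange(n_time) * 10, np.full(n_time, 100))


class TestSecondLevel:
    def test_identical_betas_degenerate_variance(self):
        coef = np.full((1, 2, 3), 0.5)
        grp = ev.second_level([_result(coef, 0), _result(coef, 1),
                               _result(coef, 2)])
        assert np.all(np.isposinf(grp.t))
        assert np.all(grp.p == 0.0)

    def test_zero_mean_zero_variance(self):
        coef = np.zeros((1, 2, 2))
        grp = ev.second_level([_result(coef, 0), _result(coef, 1)])
        assert np.all(grp.t == 0.0)
        assert np.all(grp.p == 1.0)

    def test_matches_scipy_ttest(self):
        rng = np.random.default_rng(0)
        coefs = rng.normal(size=(6, 2, 3, 4))
        grp = ev.second_level([_result(c, i) for i, c in enumerate(coefs)])
        from scipy import stats

        t, p = stats.ttest_1samp(coefs, 0.0, axis=0)
        assert np.allclose(grp.t, t)
        assert np.allclose(grp.p, p)

    def test_misaligned_grids_rejected(self):
        a = _result(np.zeros((1, 2, 3)), 0)
        b = _result(np.zeros((1, 2, 4)), 1)
        with pytest.raises(ValueError, match="aligned"):
            ev.second_level([a, b])

    def test_false_positive_rate_near_alpha(self):
        """Null cohorts produce uncorrected p < 0.05 at about the nominal
        rate."""
        rng = np.random.default_rng(1)
        rates = []
        for _ in range(50):
            coefs = rng.normal(size=(10, 1, 4, 10))
            grp = ev.second_level([_result(c, i)
                                   for i, c in enumerate(coefs)])
            rates.append((grp.p < 0.05).mean())
        assert abs(np.mean(rates) - 0.05) < 0.02


class TestFDR:
    def test_default_source_grid_size(self):
        par = ev.load_parcellation()
        p = np.random.default_rng(2).uniform(size=(ev.DOT_ALIGNED_TIMES.size,
                                                   len(par)))
        assert p.size == 25340
        mask = ev.fdr_correct(p, 0.05)
        assert mask.shape == p.shape

    def test_all_ones_empty_mask(self):
        assert not ev.fdr_correct(np.ones((5, 5)), 0.05).any()

    def test_agrees_with_stepup_oracle(self):
        """BH mask matches a literal step-up implementation on random
        p-vectors of assorted lengths."""
        rng = np.random.default_rng(3)
        for _ in range(200):
            m = int(rng.integers(1, 400))
            p = rng.uniform(size=m) ** rng.uniform(0.5, 3.0)
            mask = ev.fdr_correct(p, 0.05)
            order = np.argsort(p)
            thresh = 0.05 * (np.arange(1, m + 1)) / m
            below = np.nonzero(p[order] <= thresh)[0]
            oracle = np.zeros(m, dtype=bool)
            if below.size:
                oracle[order[: below[-1] + 1]] = True
            assert np.array_equal(mask, oracle)

    def test_monotone_in_alpha(self):
        p = np.random.default_rng(4).uniform(size=300) ** 2
        strict = ev.fdr_correct(p, 0.01)
        lax = ev.fdr_correct(p, 0.05)
        assert np.all(lax[strict])

    def test_nan_cells_never_significant(self):
        p = np.array([1e-6, np.nan, 0.5])
        mask = ev.fdr_correct(p, 0.05)
        assert mask[0] and not mask[1]


class TestGrandAverage:
    def test_single_channel_single_participant(self):
        coef = np.arange(6, dtype=float).reshape(1, 1, 6) - 3
        gam = ev.grand_average_magnitude([_result(coef)], "r0")
        assert np.allclose(gam["magnitude"], np.abs(coef[0, 0]))

    def test_rectification_order_inequality(self):
        """Mean-over-channels of |grand average| is bounded by the mean of
        per-channel magnitudes (triangle inequality), strictly when signs
        mix across participants."""
        rng = np.random.default_rng(5)
        coefs = rng.normal(size=(5, 1, 6, 8))
        results = [_result(c, i) for i, c in enumerate(coefs)]
        gam = ev.grand_average_magnitude(results, "r0")
        rectify_first = np.abs(coefs[:, 0]).mean(axis=(0, 1))
        assert np.all(gam["magnitude"] <= rectify_first + 1e-12)
        assert gam["magnitude"].sum() < rectify_first.sum()

    def test_channel_subset(self):
        coef = np.zeros((1, 3, 2))
        coef[0, 0] = 4.0
        gam = ev.grand_average_magnitude([_result(coef)], "r0",
                                         channels=["c0"])
        assert np.allclose(gam["magnitude"], 4.0)


class TestSignificantWindows:
    def test_empty_mask(self):
        wins = ev.significant_windows(np.zeros((3, 10), dtype=bool),
                                      np.zeros((3, 10)), np.arange(10) * 10,
                                      ["a", "b", "c"])
        assert wins == []

    def test_two_disjoint_windows_from_embedded_lags(self):
        times = np.arange(0, 700, 10)
        mask = np.zeros((4, times.size), dtype=bool)
        t = np.zeros((4, times.size))
        for lag, loc in [(120, 1), (400, 3)]:
            j = np.nonzero(times == lag)[0][0]
            mask[loc, j - 1: j + 2] = True
            t[loc, j - 1: j + 2] = 6.0
        wins = ev.significant_windows(mask, t, times, list("abcd"))
        assert len(wins) == 2
        assert wins[0]["t_start_ms"] <= 120 <= wins[0]["t_end_ms"]
        assert wins[1]["t_start_ms"] <= 400 <= wins[1]["t_end_ms"]
        assert wins[0]["top"][0] == "b"
        assert wins[1]["top"][0] == "d"

    def test_ranking_by_time_averaged_t(self):
        times = np.arange(5) * 10
        mask = np.zeros((2, 5), dtype=bool)
        mask[:, 1:4] = True
        t = np.zeros((2, 5))
        t[0, 1:4] = [2, 2, 2]
        t[1, 1:4] = [5, 1, 1]
        wins = ev.significant_windows(mask, t, times, ["lo", "hi"])
        assert wins[0]["top"] == ["hi", "lo"]
        assert wins[0]["mean_abs_t"]["hi"] == pytest.approx(7 / 3)

    def test_detects_embedded_cell_on_full_grid(self):
        """A strong localized effect across 34 simulated participants
        survives FDR on the full 70 x 362 grid and lands in one window."""
        rng = np.random.default_rng(6)
        n_loc, times = 362, ev.DOT_ALIGNED_TIMES
        coefs = rng.normal(0, 0.05, size=(34, 1, n_loc, times.size))
        j = np.nonzero(times == 120)[0][0]
        coefs[:, 0, 40, j] += 0.08  # standardized effect d = 1.6
        grp = ev.second_level([_result(c, i) for i, c in enumerate(coefs)])
        mask = grp.significance(0.01, "r0")
        assert mask[40, j]
        wins = ev.significant_windows(mask, grp.t[0], times,
                                      grp.location_ids)
        assert any(w["t_start_ms"] <= 120 <= w["t_end_ms"] for w in wins)
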