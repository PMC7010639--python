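import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import evreg as ev
from evreg.design import DesignConfig
from evreg.observer import TrialOutcome


def _outcome(rt, trial_id=0, choice=1):
    return TrialOutcome(trial_id, choice, rt, False, True)


class TestRowSelection:
    def test_worked_example_rt_880(self):
        """RT 880 ms at latency 120 ms: 9 dots shown, 8 candidate samples,
        6 rows after the 200 ms pre-response exclusion."""
        counts = ev.expanded_row_counts(880, 120)
        assert counts == {"n_dots_shown": 9, "n_candidates": 8,
                          "n_retained": 6}
        rows = ev.build_expanded_rows([_outcome(880)], 120)
        assert len(rows) == 6
        assert rows["dot_index"].tolist() == [1, 2, 3, 4, 5, 6]
        assert rows["sample_time_ms"].tolist() == [120, 220, 320, 420,
                                                   520, 620]

    def test_timeout_trials_excluded(self):
        o = TrialOutcome(0, 0, 2500, True, False)
        assert len(ev.build_expanded_rows([o], 120)) == 0

    def test_negative_latency_rejected(self):
        with pytest.raises(ValueError):
            ev.build_expanded_rows([_outcome(880)], -10)

    @given(rt=st.integers(30, 2500), t=st.sampled_from(range(0, 700, 10)))
    def test_row_count_matches_brute_force(self, rt, t):
        """The selection rule agrees with literal enumeration of every
        (dot onset, sample time) pair for arbitrary RTs and latencies."""
        cfg = DesignConfig()
        expected = sum(
            1
            for k in range(cfg.max_dots)
            if k * 100 < rt and k * 100 + t < rt and k * 100 + t < rt - 200
        )
        assert len(ev.build_expanded_rows([_outcome(rt)], t, cfg)) == expected


class TestExpandedDesign:
    def test_momentary_columns(self, small_stimuli, small_outcomes):
        rows = ev.build_expanded_rows(small_outcomes, 120)
        dsg = ev.build_expanded_design(small_stimuli, rows)
        assert dsg.names == ["x", "y", "abs_x", "abs_y", "update_x",
                             "update_y", "accum_prev_x", "accum_prev_y",
                             "intercept"]
        interest = dsg.X[:, :-1]
        assert np.allclose(interest.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(interest.std(axis=0), 1.0, atol=1e-12)

    def test_accumulated_variant_values(self, small_stimuli, small_outcomes):
        cfg = DesignConfig(variant="accumulated")
        rows = ev.build_expanded_rows(small_outcomes, 120, cfg)
        dsg = ev.build_expanded_design(small_stimuli, rows, cfg)
        assert "accum_x" in dsg.names and "x" not in dsg.names
        assert "accum_prev_x" not in dsg.names
        # un-z-scored value at a dot-4 row must equal the 4-dot prefix sum
        sel = rows["dot_index"] == 4
        if sel.any():
            i = int(np.nonzero(sel.to_numpy())[0][0])
            ti = int(rows["trial_index"].iloc[i])
            raw = small_stimuli.coordinate_matrix("x")[ti, :4].sum()
            col = dsg.X[:, dsg.names.index("accum_x")]
            x = np.array([
                small_stimuli.coordinate_matrix("x")[int(r.trial_index),
                                                     :int(r.dot_index)].sum()
                for r in rows.itertuples()
            ])
            assert col[i] == pytest.approx((raw - x.mean()) / x.std())

    def test_dot1_only_rows_have_constant_prev_sum(self, small_stimuli,
                                                   small_outcomes):
        rows = ev.build_expanded_rows(small_outcomes, 120)
        dot1 = rows[rows["dot_index"] == 1]
        with pytest.raises(ValueError, match="accum_prev_x"):
            ev.build_expanded_design(small_stimuli, dot1)
        cfg = DesignConfig(drop_constant_columns=True)
        dsg = ev.build_expanded_design(small_stimuli, dot1, cfg)
        assert "accum_prev_x" not in dsg.names

    def test_variants_agree_on_dot1_rows(self, small_stimuli, small_outcomes):
        """At dot 1 the running sum equals the momentary x-coordinate, so
        the two design variants share their evidence column."""
        rows = ev.build_expanded_rows(small_outcomes, 120)
        dot1 = rows[rows["dot_index"] == 1]
        cfg_m = DesignConfig(drop_constant_columns=True)
        cfg_a = DesignConfig(variant="accumulated",
                             drop_constant_columns=True)
        m = ev.build_expanded_design(small_stimuli, dot1, cfg_m)
        a = ev.build_expanded_design(small_stimuli, dot1, cfg_a)
        assert np.allclose(m.X[:, m.names.index("x")],
                           a.X[:, a.names.index("accum_x")])

    @staticmethod
    def _gs_agreement(stimuli, seed):
        """corr(prev-sum regressor, Gram-Schmidt residual of the full sum
        w.r.t. the current x) plus the exact span check."""
        out = ev.simulate_outcomes(stimuli, rng=seed)
        rows = ev.build_expanded_rows(out, 120)
        dsg = ev.build_expanded_design(stimuli, rows)
        x = dsg.X[:, dsg.names.index("x")]
        prev = dsg.X[:, dsg.names.index("accum_prev_x")]
        x_mat = stimuli.coordinate_matrix("x")
        full = np.array([
            x_mat[int(r.trial_index), :int(r.dot_index)].sum()
            for r in rows.itertuples()
        ])
        full = (full - full.mean()) / full.std()
        resid = full - ((full @ x) / (x @ x)) * x
        # prev is an exact linear combination of the full sum and x
        basis, _, _, _ = np.linalg.lstsq(np.column_stack([full, x]), prev,
                                         rcond=None)
        span_err = np.linalg.norm(np.column_stack([full, x]) @ basis - prev)
        return np.corrcoef(prev, resid)[0, 1], span_err, len(rows)

    def test_gram_schmidt_exact_for_driftless_stimuli(self):
        """With no target drift (mean 0), x and the previous sum are
        uncorrelated and the previous-sum regressor matches the
        Gram-Schmidt residual of the full sum almost exactly."""
        stim = ev.build_stimulus_set(rng=33, mean_px=0.0)
        r, span_err, n = self._gs_agreement(stim, 34)
        assert n >= 2000
        assert span_err < 1e-8
        assert r > 0.999

    def test_gram_schmidt_approximate_under_task_drift(self, full_stimuli):
        """Under the task's +/-25 px target drift, x and the previous sum
        share a small common component, so the identity holds up to the
        drift-induced correlation (~0.98 agreement)."""
        r, span_err, n = self._gs_agreement(full_stimuli, 3)
        assert n >= 2000
        assert span_err < 1e-8
        assert r > 0.95


class TestStandardDesign:
    def test_twelve_interest_columns(self, small_stimuli, small_outcomes):
        df = ev.build_standard_design(small_stimuli, small_outcomes)
        interest = [c for c in df.columns if c.startswith(("x_", "y_"))]
        assert len(interest) == 12
        assert {"response", "trial_count", "intercept"} <= set(df.columns)

    def test_normalization_contract(self, small_stimuli, small_outcomes):
        df = ev.build_standard_design(small_stimuli, small_outcomes)
        for c in df.columns:
            if c in ("trial_index", "intercept"):
                continue
            assert df[c].std(ddof=0) == pytest.approx(1.0)
            assert df[c].mean() == pytest.approx(0.0, abs=1e-12)


class TestResponseDesign:
    def test_columns_and_scaling(self, small_outcomes):
        df = ev.build_response_design(small_outcomes)
        assert df["choice"].mean() == pytest.approx(0.0, abs=1e-12)
        assert df["choice"].std(ddof=0) == pytest.approx(1.0)
        assert df["trial_time"].std(ddof=0) == pytest.approx(1.0)
        assert df["trial_time"].mean() != pytest.approx(0.0, abs=0.1)

    def test_timeouts_excluded(self, small_outcomes):
        df = ev.build_response_design(small_outcomes)
        timeouts = {o.trial_id for o in small_outcomes if o.timed_out}
        assert not (set(df["trial_index"]) & timeouts) or all(
            not small_outcomes[i].timed_out for i in df["trial_index"])

    def test_all_timeout_rejected(self):
        outs = [TrialOutcome(i, 0, 2500, True, False) for i in range(5)]
        with pytest.raises(ValueError):
            ev.build_response_design(outs)


class TestZscoreSignal:
    def test_slices_standardized(self, small_session):
        z = ev.zscore_signal(small_session)
        assert np.allclose(z.data.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(z.data.std(axis=0), 1.0, atol=1e-10)

    def test_pooled_rows_need_not_have_unit_sd(self, small_stimuli,
                                               small_outcomes, small_session):
        """Rows pooled from different z-scored slices are close to, but not
        exactly at, unit SD."""
        z = ev.zscore_signal(small_session)
        rows = ev.build_expanded_rows(small_outcomes, 120)
        ti = rows["trial_index"].to_numpy()
        si = ((rows["sample_time_ms"].to_numpy() + 300) // 10).astype(int)
        pooled = z.data[ti, 0, si]
        assert 0.8 < pooled.std() < 1.2
        assert pooled.std() != pytest.approx(1.0, abs=1e-6)

    def test_commutes_with_trial_permutation(self, small_session):
        rng = np.random.default_rng(0)
        perm = ev.permute_trials(small_session, rng)
        a = ev.zscore_signal(perm).data
        b = ev.permute_trials(ev.zscore_signal(small_session),
                              np.random.default_rng(0)).data
        assert np.allclose(a, b)

    def test_zero_variance_cell_identified(self, small_session):
        broken = ev.SignalTensor(
            0, small_session.data.copy(), small_session.times_ms,
            small_session.channel_ids)
        broken.data[:, 2, 5] = 7.0
        with pytest.raises(ValueError, match="time"):
            ev.zscore_signal(broken)


class TestCorrelationEquivalence:
    def test_single_regressor_coefficient_is_pearson_r(self):
        """With both sides z-scored, the OLS slope of a single-regressor
        (plus intercept) model equals the Pearson correlation to 1e-10."""
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = int(rng.integers(20, 200))
            x = rng.normal(size=n)
            y = 0.4 * x + rng.normal(size=n)
            xz = (x - x.mean()) / x.std()
            yz = (y - y.mean()) / y.std()
            X = np.column_stack([xz, np.ones(n)])
            beta = ev.fit_ols(X, yz)
            r = np.corrcoef(x, y)[0, 1]
            assert abs(beta[0] - r) < 1e-10
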