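"""RT filtering, Gumbel psychometrics, and BP/CV extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tremortime import psychometrics as psy

from conftest import gumbel_bp_cv

DURATIONS = np.array([1000, 1260, 1580, 2000, 2520, 3170, 4000], dtype=float)


def _trials_from_rts(rts, subject="s1"):
    n = len(rts)
    return pd.DataFrame(
        {
            "subject": subject,
            "duration_ms": np.resize(DURATIONS, n),
            "choice": "long",
            "rt_ms": rts,
        }
    )


class TestFilterRts:
    def test_absolute_window(self):
        kept, log = psy.filter_rts(_trials_from_rts([150, 250, 400, 2500, 600]))
        assert len(kept) == 3
        row = log.iloc[0]
        assert row["n_excluded_window"] == 2
        assert row["n_excluded_sd"] == 0

    def test_equal_rts_sd_rule_removes_none(self):
        kept, log = psy.filter_rts(_trials_from_rts([500.0] * 20))
        assert len(kept) == 20

    def test_log_sd_rule_removes_inlier_window_outlier(self, rng):
        # 19 log-normal RTs around 500 ms plus one at 1,900 ms: inside the
        # absolute window but beyond 3 SD of the log-RT distribution
        rts = np.append(500 * np.exp(rng.normal(0, 0.1, 19)), 1900.0)
        # independent oracle: explicit mean/SD of the 20 log RTs
        lr = np.log(rts)
        oracle_keep = np.abs(lr - lr.mean()) <= 3 * lr.std(ddof=1)
        assert not oracle_keep[-1], "construction should place 1900 ms beyond 3 SD"
        kept, log = psy.filter_rts(_trials_from_rts(rts))
        assert 1900.0 not in kept["rt_ms"].to_numpy()
        assert log.iloc[0]["n_excluded_sd"] >= 1

    def test_filtering_idempotent_at_window_stage(self, rng):
        rts = np.concatenate([rng.uniform(300, 900, 50), [150, 2500]])
        kept, _ = psy.filter_rts(_trials_from_rts(rts))
        kept2, log2 = psy.filter_rts(kept)
        assert log2.iloc[0]["n_excluded_window"] == 0

    def test_tiny_subject_flagged(self):
        with pytest.warns(UserWarning, match="only"):
            _, log = psy.filter_rts(_trials_from_rts([150.0, 160.0, 500.0]))
        assert bool(log.iloc[0]["flagged"])

    def test_nonpositive_rt_rejected(self):
        with pytest.raises(ValueError):
            psy.filter_rts(_trials_from_rts([0.0, 500.0]))


class TestGumbelCurve:
    def test_location_definition(self):
        # at x = 10**m the cumulative Gumbel passes 1 - 1/e
        assert psy.gumbel_cdf(2000.0, np.log10(2000), 0.1) == pytest.approx(
            1 - np.exp(-1)
        )

    def test_quantile_inverse_closed_form(self):
        # F^-1(0.5) = 2000 * 10**(0.1 * ln(ln 2)) = 1838.14 ms
        bp = psy.gumbel_quantile(0.5, np.log10(2000), 0.1)
        assert bp == pytest.approx(1838.14, abs=0.01)

    def test_degenerate_scale_approaches_step(self):
        lo = psy.gumbel_cdf(1999.0, np.log10(2000), 1e-6)
        hi = psy.gumbel_cdf(2001.0, np.log10(2000), 1e-6)
        assert lo < 1e-6 and hi > 1 - 1e-6

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            psy.gumbel_cdf(2000, 3.3, 0.0)
        for p in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                psy.gumbel_quantile(p, 3.3, 0.1)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(min_value=2.5, max_value=4.0),
        st.floats(min_value=0.01, max_value=0.5),
        st.floats(min_value=0.01, max_value=0.99),
    )
    def test_cdf_quantile_roundtrip(self, m, s, p):
        x = psy.gumbel_quantile(p, m, s)
        assert psy.gumbel_cdf(x, m, s) == pytest.approx(p, abs=1e-9)


class TestFitPsychometric:
    def test_recovers_generating_curve_at_large_n(self, rng):
        m, s = np.log10(2000), 0.1
        n_per = 2000
        probs = psy.gumbel_cdf(DURATIONS, m, s)
        k = rng.binomial(n_per, probs)
        fit = psy.fit_psychometric_counts(DURATIONS, k, np.full(7, n_per))
        bp_true, cv_true = gumbel_bp_cv(m, s)
        assert fit.bp_ms == pytest.approx(bp_true, rel=0.02)
        assert fit.cv == pytest.approx(cv_true, rel=0.02)

    def test_perfect_separation_bracketed_and_flagged(self):
        durs = [1000, 1260, 1580, 2520, 3170, 4000]
        k = [0, 0, 0, 6, 6, 6]
        # regularised fit: BP bracketed by the step location
        fit = psy.fit_psychometric_counts(durs, k, [6] * 6)
        assert 1580 <= fit.bp_ms <= 2520
        # pure MLE: degenerate step curve, flagged as separated
        mle = psy.fit_psychometric_counts(durs, k, [6] * 6, prior_weight=0.0)
        assert 1580 <= mle.bp_ms <= 2520
        assert "perfect_separation" in mle.flags

    def test_nonmonotone_proportions_flagged(self):
        fit = psy.fit_psychometric_counts(
            DURATIONS, [0, 4, 1, 3, 5, 6, 6], [6] * 7
        )
        assert "nonmonotone_proportions" in fit.flags

    def test_degenerate_responses_rejected(self):
        with pytest.raises(ValueError):
            psy.fit_psychometric_counts(DURATIONS, [0] * 7, [6] * 7)
        with pytest.raises(ValueError):
            psy.fit_psychometric_counts([2000.0], [3], [6])

    @pytest.mark.parametrize("scale", [0.5, 2.0, 10.0])
    def test_cv_invariant_to_duration_rescaling(self, rng, scale):
        # CV is a ratio of durations: rescaling all stimuli leaves it fixed
        m, s = np.log10(2000), 0.12
        k = rng.binomial(50, psy.gumbel_cdf(DURATIONS, m, s))
        fit = psy.fit_psychometric_counts(DURATIONS, k, np.full(7, 50))
        fit_scaled = psy.fit_psychometric_counts(
            DURATIONS * scale, k, np.full(7, 50)
        )
        assert fit_scaled.cv == pytest.approx(fit.cv, rel=1e-3)
        assert fit_scaled.bp_ms == pytest.approx(fit.bp_ms * scale, rel=1e-3)

    def test_trial_table_interface_matches_counts(self, rng):
        rows = []
        for d in DURATIONS:
            p = psy.gumbel_cdf(d, np.log10(1900), 0.12)
            for _ in range(30):
                rows.append(
                    {
                        "duration_ms": d,
                        "choice": "long" if rng.random() < p else "short",
                        "rt_ms": 500.0,
                    }
                )
        df = pd.DataFrame(rows)
        fit_df = psy.fit_psychometric(df)
        counts = df.groupby("duration_ms")["choice"].apply(lambda c: (c == "long").sum())
        fit_counts = psy.fit_psychometric_counts(
            counts.index.to_numpy(), counts.to_numpy(), np.full(7, 30)
        )
        assert fit_df.bp_ms == pytest.approx(fit_counts.bp_ms)
        assert fit_df.cv == pytest.approx(fit_counts.cv)


class TestCurvesByCondition:
    def test_full_session_grouping(self, small_session):
        fits = psy.curves_by_condition(small_session)
        assert len(fits) == 9  # 3 amplitudes x 3 frequencies
        assert (fits["n"] == 42).all()

    def test_collapsed_over_amplitude(self, small_session):
        fits = psy.curves_by_condition(small_session, collapse=("amplitude_N",))
        assert len(fits) == 3
        assert (fits["n"] == 126).all()

    def test_small_cells_flagged(self, small_session):
        sub = small_session.head(60)
        fits = psy.curves_by_condition(sub)
        assert fits["flags"].str.contains("too_few_trials").any()
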