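"""Repeated-measures ANOVA, contrasts, direction bins, Mann-Whitney."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tremortime import stats_analysis as sa


def _one_way_table(values_by_subject):
    rows = []
    for subj, vals in values_by_subject.items():
        for lvl, y in enumerate(vals, start=1):
            rows.append({"subject": subj, "lvl": lvl, "y": y})
    return pd.DataFrame(rows)


def _random_two_way(rng, n_s, n_a, n_b):
    rows = []
    for s in range(n_s):
        for a in range(n_a):
            for b in range(n_b):
                rows.append(
                    {"subject": f"s{s}", "A": a, "B": b, "y": rng.normal()}
                )
    return pd.DataFrame(rows)


def _brute_force_two_way(df):
    """Naive nested-loop sums-of-squares decomposition (oracle)."""
    y = df.pivot_table(index="subject", columns=["A", "B"], values="y")
    n_s = y.shape[0]
    n_a = df["A"].nunique()
    n_b = df["B"].nunique()
    cube = y.to_numpy().reshape(n_s, n_a, n_b)
    grand = cube.mean()
    ss = dict(A=0.0, B=0.0, AB=0.0, AS=0.0, BS=0.0, ABS=0.0)
    for i in range(n_a):
        ss["A"] += n_s * n_b * (cube[:, i, :].mean() - grand) ** 2
    for j in range(n_b):
        ss["B"] += n_s * n_a * (cube[:, :, j].mean() - grand) ** 2
    for i in range(n_a):
        for j in range(n_b):
            ss["AB"] += n_s * (
                cube[:, i, j].mean()
                - cube[:, i, :].mean()
                - cube[:, :, j].mean()
                + grand
            ) ** 2
    for s in range(n_s):
        for i in range(n_a):
            ss["AS"] += n_b * (
                cube[s, i, :].mean()
                - cube[:, i, :].mean()
                - cube[s].mean()
                + grand
            ) ** 2
        for j in range(n_b):
            ss["BS"] += n_a * (
                cube[s, :, j].mean()
                - cube[:, :, j].mean()
                - cube[s].mean()
                + grand
            ) ** 2
    ss_total = ((cube - grand) ** 2).sum()
    ss_subj = sum(
        n_a * n_b * (cube[s].mean() - grand) ** 2 for s in range(n_s)
    )
    ss["ABS"] = ss_total - ss_subj - sum(
        ss[k] for k in ("A", "B", "AB", "AS", "BS")
    )
    f_a = (ss["A"] / (n_a - 1)) / (ss["AS"] / ((n_a - 1) * (n_s - 1)))
    f_b = (ss["B"] / (n_b - 1)) / (ss["BS"] / ((n_b - 1) * (n_s - 1)))
    f_ab = (ss["AB"] / ((n_a - 1) * (n_b - 1))) / (
        ss["ABS"] / ((n_a - 1) * (n_b - 1) * (n_s - 1))
    )
    pes = {
        "A": ss["A"] / (ss["A"] + ss["AS"]),
        "B": ss["B"] / (ss["B"] + ss["BS"]),
        "AB": ss["AB"] / (ss["AB"] + ss["ABS"]),
    }
    return (f_a, f_b, f_ab), pes


class TestRmAnova:
    def test_worked_one_way_example(self):
        # subjects {[1,2,3],[2,3,5]} across 3 levels -> F(2,2) = 19.0
        table = _one_way_table({"s1": [1, 2, 3], "s2": [2, 3, 5]})
        res = sa.rm_anova_one_way(table, "y", "subject", "lvl")
        assert res.F == pytest.approx(19.0, abs=1e-9)
        assert (res.df_effect, res.df_error) == (2, 2)

    def test_constant_cells_give_zero_f(self):
        table = _one_way_table({"s1": [2, 2, 2], "s2": [2, 2, 2], "s3": [2, 2, 2]})
        res = sa.rm_anova_one_way(table, "y", "subject", "lvl")
        assert res.F == 0.0

    def test_shift_invariance(self, rng):
        df = _random_two_way(rng, 4, 3, 3)
        base = sa.rm_anova(df, "y", "subject", ["A", "B"])
        shifted = df.assign(y=df["y"] + 100.0)
        after = sa.rm_anova(shifted, "y", "subject", ["A", "B"])
        for r0, r1 in zip(base, after):
            assert r1.F == pytest.approx(r0.F, rel=1e-9)

    @pytest.mark.parametrize("shape", [(3, 2, 2), (4, 3, 2), (5, 3, 3), (2, 2, 3)])
    def test_matches_brute_force_oracle(self, rng, shape):
        df = _random_two_way(rng, *shape)
        res = sa.rm_anova(df, "y", "subject", ["A", "B"])
        (f_a, f_b, f_ab), pes = _brute_force_two_way(df)
        assert res[0].F == pytest.approx(f_a, abs=1e-8)
        assert res[1].F == pytest.approx(f_b, abs=1e-8)
        assert res[2].F == pytest.approx(f_ab, abs=1e-8)
        assert res[0].partial_eta_sq == pytest.approx(pes["A"], abs=1e-8)
        assert res[2].partial_eta_sq == pytest.approx(pes["AB"], abs=1e-8)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.anova import AnovaRM

        df = _random_two_way(rng, 6, 3, 3)
        ours = sa.rm_anova(df, "y", "subject", ["A", "B"])
        ref = AnovaRM(df, "y", "subject", within=["A", "B"]).fit().anova_table
        for row, name in zip(ours, ["A", "B", "A:B"]):
            assert row.F == pytest.approx(ref.loc[name, "F Value"], abs=1e-8)
            assert row.p == pytest.approx(ref.loc[name, "Pr > F"], abs=1e-8)

    def test_missing_cell_rejected(self, rng):
        df = _random_two_way(rng, 3, 3, 3).iloc[:-1]
        with pytest.raises(ValueError, match="missing"):
            sa.rm_anova(df, "y", "subject", ["A", "B"])

    def test_duplicate_cell_rejected(self, rng):
        df = _random_two_way(rng, 3, 3, 3)
        df = pd.concat([df, df.head(1)])
        with pytest.raises(ValueError):
            sa.rm_anova(df, "y", "subject", ["A", "B"])

    def test_type_i_error_calibrated(self, rng):
        # null Gaussian data: nominal-0.05 rejection rate within [0.03, 0.07]
        n_rep, n_s = 1000, 24
        hits = np.zeros(3)
        idx = pd.MultiIndex.from_product(
            [range(n_s), range(3), range(3)], names=["subject", "A", "B"]
        )
        for _ in range(n_rep):
            df = pd.DataFrame(
                {"y": rng.normal(size=n_s * 9)}, index=idx
            ).reset_index()
            res = sa.rm_anova(df, "y", "subject", ["A", "B"])
            hits += [r.p < 0.05 for r in res]
        for rate in hits / n_rep:
            assert 0.03 <= rate <= 0.07


class TestLinearContrast:
    def test_hand_computed_scores(self):
        # per-subject contrast scores (0.5, 1.0, 1.5): t = 3.464, d = 2.0
        table = _one_way_table(
            {"s1": [0.0, 9.0, 0.5], "s2": [0.0, 4.0, 1.0], "s3": [0.0, 7.0, 1.5]}
        )
        res = sa.linear_contrast(table, "y", "subject", "lvl")
        assert res.t == pytest.approx(np.sqrt(12), abs=1e-3)
        assert res.cohen_d == pytest.approx(2.0, abs=1e-9)

    def test_symmetric_scores_give_zero_t(self):
        table = _one_way_table({"s1": [0, 5, 1], "s2": [1, 3, 0]})
        res = sa.linear_contrast(table, "y", "subject", "lvl")
        assert res.t == pytest.approx(0.0, abs=1e-12)

    def test_reversed_levels_flip_sign(self, rng):
        vals = {f"s{i}": rng.normal(size=3).tolist() for i in range(5)}
        table = _one_way_table(vals)
        fwd = sa.linear_contrast(table, "y", "subject", "lvl")
        rev = sa.linear_contrast(table, "y", "subject", "lvl", weights=[1, 0, -1])
        assert rev.t == pytest.approx(-fwd.t, rel=1e-9)

    def test_zero_variance_rejected(self):
        table = _one_way_table({"s1": [0, 0, 1], "s2": [2, 5, 3]})
        with pytest.raises(ValueError, match="zero-variance"):
            sa.linear_contrast(table, "y", "subject", "lvl")


class TestSimpleMainEffects:
    def test_one_result_per_moderator_level(self, rng):
        df = _random_two_way(rng, 5, 3, 3)
        out = sa.simple_main_effects(df, "y", "subject", "A", "B")
        assert len(out) == 3

    def test_planted_moderated_effect_localised(self, rng):
        # frequency effect planted only at the highest amplitude: the
        # smallest simple-main-effect p should land there almost always
        n_rep, n_s = 200, 24
        hits = 0
        for _ in range(n_rep):
            rows = []
            for s in range(n_s):
                for amp in (1, 2, 3):
                    for fi, f in enumerate((4, 8, 12)):
                        eff = 0.03 * fi if amp == 3 else 0.0
                        rows.append(
                            {
                                "subject": s,
                                "amplitude_N": amp,
                                "frequency_Hz": f,
                                "cv": 0.2 + eff + rng.normal(0, 0.03),
                            }
                        )
            df = pd.DataFrame(rows)
            out = sa.simple_main_effects(
                df, "cv", "subject", "frequency_Hz", "amplitude_N"
            )
            hits += out.loc[out["amplitude_N"] == 3, "p"].iloc[0] == out["p"].min()
        assert hits / n_rep >= 0.9

    def test_null_type_i_rate(self, rng):
        n_rep, n_s = 1000, 24
        hits = 0
        idx = pd.MultiIndex.from_product(
            [range(n_s), range(3), range(3)], names=["subject", "A", "B"]
        )
        for _ in range(n_rep):
            df = pd.DataFrame(
                {"y": rng.normal(size=n_s * 9)}, index=idx
            ).reset_index()
            out = sa.simple_main_effects(df, "y", "subject", "A", "B")
            hits += int(out["p"].iloc[0] < 0.05)
        assert 0.03 <= hits / n_rep <= 0.07


class TestDirectionBins:
    @pytest.mark.parametrize(
        "deg, expected",
        [(0.0, 1), (60.0, 1), (60.5, 2), (90.0, 2), (120.0, 2), (120.5, 3), (179.9, 3)],
    )
    def test_boundaries(self, deg, expected):
        out = sa.direction_bins(pd.DataFrame({"direction_deg": [deg]}))
        assert out["direction_bin"].iloc[0] == expected

    def test_out_of_range_rejected(self):
        for bad in (-1.0, 180.0, 250.0):
            with pytest.raises(ValueError):
                sa.direction_bins(pd.DataFrame({"direction_deg": [bad]}))

    def test_uniform_directions_fill_bins_evenly(self, rng):
        df = pd.DataFrame({"direction_deg": rng.uniform(0, 180, 30_000)})
        props = sa.direction_bins(df)["direction_bin"].value_counts(normalize=True)
        assert np.allclose(props.sort_index(), 1 / 3, atol=0.02)


class TestSlopes:
    def test_per_subject_slope_values(self):
        table = _one_way_table({"s1": [2.0, 1.5, 1.0], "s2": [1.0, 1.0, 1.0]})
        slopes = sa.per_subject_slopes(table, "y", "subject", "lvl")
        assert slopes.loc["s1", "slope"] == pytest.approx(-0.5)
        assert slopes.loc["s2", "slope"] == pytest.approx(0.0)


class TestSlopeComparison:
    def test_complete_separation(self):
        res = sa.slope_comparison([1, 2, 3], [4, 5, 6])
        assert res.U == 0
        assert res.rank_biserial == pytest.approx(1.0)

    def test_interleaved_enumeration_example(self):
        # 4 pairs: only (3 > 2) has the first group larger -> U = 1
        res = sa.slope_comparison([1, 3], [2, 4])
        assert res.U == 1
        assert res.rank_biserial == pytest.approx(0.5)

    def test_swap_antisymmetry(self, rng):
        a, b = rng.normal(size=8), rng.normal(0.5, 1, 9)
        fwd = sa.slope_comparison(a, b)
        rev = sa.slope_comparison(b, a)
        assert rev.rank_biserial == pytest.approx(-fwd.rank_biserial, abs=1e-12)
        assert rev.p == pytest.approx(fwd.p, abs=1e-12)

    def test_exact_p_matches_permutation_enumeration(self, rng):
        a, b = rng.normal(size=4), rng.normal(size=3)
        res = sa.slope_comparison(a, b)
        assert res.method == "exact"
        # brute-force null: all assignments of the 7 values to groups
        pooled = np.concatenate([a, b])
        def u_stat(ga, gb):
            return sum(x > y for x in ga for y in gb)
        u_obs = u_stat(a, b)
        n1 = len(a)
        us = [
            u_stat(pooled[list(c)], np.delete(pooled, list(c)))
            for c in itertools.combinations(range(7), n1)
        ]
        us = np.array(us)
        mu = n1 * (7 - n1) / 2
        p_exact = np.mean(np.abs(us - mu) >= np.abs(u_obs - mu) - 1e-12)
        assert res.p == pytest.approx(p_exact, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            sa.slope_comparison([], [1.0])
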