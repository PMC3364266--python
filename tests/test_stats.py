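"""Group statistics: Mann-Whitney, Spearman, repeated-measures ANOVA with
Greenhouse-Geisser correction, and the normality screen."""

import itertools

import numpy as np
import pytest

from csfpulse import log_transform_if_nonnormal, mann_whitney, rm_anova_gg, spearman_rho


def permutation_mw_p(x, y):
    """Brute-force two-sided permutation p-value for the Mann-Whitney U."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    combined = np.concatenate([x, y])
    nx = len(x)

    def u_stat(xs, ys):
        u = 0.0
        for a in xs:
            for b in ys:
                u += (a > b) + 0.5 * (a == b)
        return min(u, len(xs) * len(ys) - u)

    observed = u_stat(x, y)
    count = total = 0
    for idx in itertools.combinations(range(len(combined)), nx):
        xs = combined[list(idx)]
        ys = np.delete(combined, list(idx))
        total += 1
        if u_stat(xs, ys) <= observed + 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.extras["U"] in (0.0, 9.0)
        assert res.p_value == pytest.approx(0.1)
        assert res.extras["exact"]

    def test_identical_samples_p_one(self):
        res = mann_whitney([1.0, 2.0, 3.0, 4.0] * 4, [1.0, 2.0, 3.0, 4.0] * 4)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_tied_data_uses_corrected_approximation(self):
        res = mann_whitney([1, 2], [1, 2])
        assert not res.extras["exact"]
        assert 0.0 <= res.p_value <= 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_permutation_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        nx, ny = rng.integers(3, 6), rng.integers(3, 6)
        # distinct values to stay on the exact branch
        vals = rng.permutation(np.arange(1.0, 1.0 + nx + ny))
        x, y = vals[:nx], vals[nx:]
        res = mann_whitney(x, y)
        assert res.extras["exact"]
        assert res.p_value == pytest.approx(min(1.0, permutation_mw_p(x, y)), abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestSpearman:
    def test_monotone_increasing_rho_one(self):
        x = np.arange(10.0)
        res = spearman_rho(x, np.exp(x))
        assert res.statistic == pytest.approx(1.0)

    def test_monotone_decreasing_rho_minus_one(self):
        x = np.arange(10.0)
        assert spearman_rho(x, -(x**3)).statistic == pytest.approx(-1.0)

    def test_independent_samples_near_zero(self):
        rng = np.random.default_rng(12)
        res = spearman_rho(rng.uniform(size=1000), rng.uniform(size=1000))
        assert abs(res.statistic) < 0.1

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRmAnovaGG:
    def test_two_levels_force_epsilon_one(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(10, 2))
        res = rm_anova_gg(Y)
        assert res["measure"].extras["epsilon"] == pytest.approx(1.0)

    def test_matches_pingouin_mixed_anova(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        n, k = 12, 4
        Y = rng.normal(size=(n, k)) + np.linspace(0, 1.0, k)
        groups = np.repeat(["a", "b"], n // 2)
        Y[groups == "b"] += 0.8
        res = rm_anova_gg(Y, groups)

        df = pd.DataFrame({
            "subject": np.repeat(np.arange(n), k),
            "measure": np.tile(np.arange(k), n),
            "group": np.repeat(groups, k),
            "value": Y.ravel(),
        })
        pg = pingouin.mixed_anova(df, dv="value", within="measure",
                                  subject="subject", between="group", correction=True)
        row_int = pg[pg["Source"] == "Interaction"].iloc[0]
        row_meas = pg[pg["Source"] == "measure"].iloc[0]
        row_group = pg[pg["Source"] == "group"].iloc[0]
        assert res["measure"].statistic == pytest.approx(row_meas["F"], rel=1e-6)
        assert res["group"].statistic == pytest.approx(row_group["F"], rel=1e-6)
        assert res["interaction"].statistic == pytest.approx(row_int["F"], rel=1e-6)
        assert res["measure"].extras["epsilon"] == pytest.approx(row_meas["eps"], rel=1e-6)

    def test_matches_pingouin_one_way_rm_anova(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(8)
        n, k = 10, 5
        Y = rng.normal(size=(n, k)) + np.linspace(0, 0.8, k)
        res = rm_anova_gg(Y)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(n), k),
            "measure": np.tile(np.arange(k), n),
            "value": Y.ravel(),
        })
        pg = pingouin.rm_anova(df, dv="value", within="measure",
                               subject="subject", correction=True)
        row = pg.iloc[0]
        assert res["measure"].statistic == pytest.approx(row["F"], rel=1e-6)
        assert res["measure"].extras["epsilon"] == pytest.approx(row["eps"], rel=1e-6)
        assert res["measure"].p_value == pytest.approx(row["p_GG_corr"], rel=1e-4)

    def test_strong_group_shift_detected(self):
        rng = np.random.default_rng(9)
        n, k = 12, 5
        Y = rng.normal(size=(n, k))
        groups = np.repeat(["young", "elderly"], n // 2)
        Y[groups == "elderly"] += 3.0  # three within-subject SDs
        res = rm_anova_gg(Y, groups)
        assert res["group"].p_value < 0.001

    def test_group_label_relabeling_invariance(self):
        rng = np.random.default_rng(13)
        Y = rng.normal(size=(10, 3))
        g1 = np.repeat(["a", "b"], 5)
        g2 = np.repeat(["young", "elderly"], 5)
        r1 = rm_anova_gg(Y, g1)
        r2 = rm_anova_gg(Y, g2)
        for key in ("measure", "group", "interaction"):
            assert r1[key].p_value == pytest.approx(r2[key].p_value)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            rm_anova_gg(np.zeros((2, 3)), ["a", "b"])


class TestLogTransform:
    def test_normal_sample_unchanged(self):
        rng = np.random.default_rng(21)
        x = rng.normal(10.0, 1.0, 50)
        out, flag = log_transform_if_nonnormal(x)
        assert not flag
        assert np.array_equal(out, x)

    def test_lognormal_sample_transformed(self):
        rng = np.random.default_rng(22)
        x = rng.lognormal(0.0, 1.5, 50)
        out, flag = log_transform_if_nonnormal(x)
        assert flag
        assert np.allclose(out, np.log(x))

    def test_nonpositive_nonnormal_rejected(self):
        rng = np.random.default_rng(23)
        x = np.concatenate([rng.lognormal(0, 1.5, 49), [0.0]])
        with pytest.raises(ValueError):
            log_transform_if_nonnormal(x)
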