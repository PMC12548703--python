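"""Within-subject ANOVA and paired t-tests against independent oracles."""

import numpy as np
import pytest
from scipy import stats as sst

from pamtonic.stats import decide, paired_t, rm_anova_2x2x2

EFFECTS = ["A", "B", "C", "A x B", "A x C", "B x C", "A x B x C"]


def anova_oracle(y):
    """Brute-force textbook sum-of-squares decomposition, written with
    explicit loops over marginal means (independent of the implementation)."""
    n = y.shape[0]
    grand = y.mean()
    m_a = y.mean(axis=(0, 2, 3))
    m_b = y.mean(axis=(0, 1, 3))
    m_c = y.mean(axis=(0, 1, 2))
    m_s = y.mean(axis=(1, 2, 3))
    m_ab = y.mean(axis=(0, 3))
    m_ac = y.mean(axis=(0, 2))
    m_bc = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=(2, 3))
    m_sb = y.mean(axis=(1, 3))
    m_sc = y.mean(axis=(1, 2))
    m_abc = y.mean(axis=0)
    m_sab = y.mean(axis=3)
    m_sac = y.mean(axis=2)
    m_sbc = y.mean(axis=1)

    out = {}
    ss_a = 4 * n * sum((m_a[a] - grand) ** 2 for a in range(2))
    ss_as = 4 * sum(
        (m_sa[s, a] - m_s[s] - m_a[a] + grand) ** 2 for s in range(n) for a in range(2)
    )
    out["A"] = (ss_a, ss_as)
    ss_b = 4 * n * sum((m_b[b] - grand) ** 2 for b in range(2))
    ss_bs = 4 * sum(
        (m_sb[s, b] - m_s[s] - m_b[b] + grand) ** 2 for s in range(n) for b in range(2)
    )
    out["B"] = (ss_b, ss_bs)
    ss_c = 4 * n * sum((m_c[c] - grand) ** 2 for c in range(2))
    ss_cs = 4 * sum(
        (m_sc[s, c] - m_s[s] - m_c[c] + grand) ** 2 for s in range(n) for c in range(2)
    )
    out["C"] = (ss_c, ss_cs)

    ss_ab = 2 * n * sum(
        (m_ab[a, b] - m_a[a] - m_b[b] + grand) ** 2 for a in range(2) for b in range(2)
    )
    ss_abs = 2 * sum(
        (
            m_sab[s, a, b]
            - m_sa[s, a]
            - m_sb[s, b]
            - m_ab[a, b]
            + m_s[s]
            + m_a[a]
            + m_b[b]
            - grand
        )
        ** 2
        for s in range(n)
        for a in range(2)
        for b in range(2)
    )
    out["A x B"] = (ss_ab, ss_abs)
    ss_ac = 2 * n * sum(
        (m_ac[a, c] - m_a[a] - m_c[c] + grand) ** 2 for a in range(2) for c in range(2)
    )
    ss_acs = 2 * sum(
        (
            m_sac[s, a, c]
            - m_sa[s, a]
            - m_sc[s, c]
            - m_ac[a, c]
            + m_s[s]
            + m_a[a]
            + m_c[c]
            - grand
        )
        ** 2
        for s in range(n)
        for a in range(2)
        for c in range(2)
    )
    out["A x C"] = (ss_ac, ss_acs)
    ss_bc = 2 * n * sum(
        (m_bc[b, c] - m_b[b] - m_c[c] + grand) ** 2 for b in range(2) for c in range(2)
    )
    ss_bcs = 2 * sum(
        (
            m_sbc[s, b, c]
            - m_sb[s, b]
            - m_sc[s, c]
            - m_bc[b, c]
            + m_s[s]
            + m_b[b]
            + m_c[c]
            - grand
        )
        ** 2
        for s in range(n)
        for b in range(2)
        for c in range(2)
    )
    out["B x C"] = (ss_bc, ss_bcs)

    ss_abc = n * sum(
        (
            m_abc[a, b, c]
            - m_ab[a, b]
            - m_ac[a, c]
            - m_bc[b, c]
            + m_a[a]
            + m_b[b]
            + m_c[c]
            - grand
        )
        ** 2
        for a in range(2)
        for b in range(2)
        for c in range(2)
    )
    # three-way-by-subject residual: total minus every other term
    ss_total = ((y - grand) ** 2).sum()
    ss_s = 8 * sum((m_s[s] - grand) ** 2 for s in range(n))
    others = (
        ss_s
        + sum(v[0] + v[1] for v in out.values())
        + ss_abc
    )
    ss_abcs = ss_total - others
    out["A x B x C"] = (ss_abc, ss_abcs)

    f = {}
    for name, (ss_e, ss_err) in out.items():
        f[name] = (ss_e / 1) / (ss_err / (n - 1))
    return f


class TestRmAnova:
    @pytest.mark.parametrize("n_subjects", [3, 4, 5])
    def test_matches_bruteforce_oracle(self, n_subjects, rng):
        y = rng.standard_normal((n_subjects, 2, 2, 2))
        res = rm_anova_2x2x2(y)
        oracle = anova_oracle(y)
        for name in EFFECTS:
            assert res.effect(name)["F"] == pytest.approx(oracle[name], rel=1e-10)

    def test_f_equals_squared_paired_t_on_contrasts(self, rng):
        """Each two-level within effect satisfies F = t^2 with matching p."""
        y = rng.standard_normal((8, 2, 2, 2))
        res = rm_anova_2x2x2(y)
        signs = {1: np.array([1, -1])}
        for name, axes in [
            ("A", (1,)), ("B", (2,)), ("C", (3,)),
            ("A x B", (1, 2)), ("A x C", (1, 3)), ("B x C", (2, 3)),
            ("A x B x C", (1, 2, 3)),
        ]:
            c = np.ones((2, 2, 2))
            for ax in axes:
                shape = [1, 1, 1]
                shape[ax - 1] = 2
                c = c * np.array([1, -1]).reshape(shape)
            plus = y.reshape(len(y), -1)[:, c.ravel() > 0].mean(axis=1)
            minus = y.reshape(len(y), -1)[:, c.ravel() < 0].mean(axis=1)
            tt = paired_t(plus, minus)
            eff = res.effect(name)
            assert eff["F"] == pytest.approx(tt.t**2, rel=1e-10)
            assert eff["p"] == pytest.approx(tt.p, rel=1e-10)

    def test_matches_statsmodels_anovarm(self, rng):
        """Cross-check against an independent implementation."""
        import pandas as pd
        from statsmodels.stats.anova import AnovaRM

        y = rng.standard_normal((6, 2, 2, 2))
        rows = []
        for s in range(6):
            for a in range(2):
                for b in range(2):
                    for c in range(2):
                        rows.append({"s": s, "F1": a, "F2": b, "F3": c, "y": y[s, a, b, c]})
        df = pd.DataFrame(rows)
        sm = AnovaRM(df, depvar="y", subject="s", within=["F1", "F2", "F3"]).fit()
        res = rm_anova_2x2x2(y)
        mapping = {"F1": "A", "F2": "B", "F3": "C", "F1:F2": "A x B",
                   "F1:F3": "A x C", "F2:F3": "B x C", "F1:F2:F3": "A x B x C"}
        for sm_name, name in mapping.items():
            assert res.effect(name)["F"] == pytest.approx(
                sm.anova_table.loc[sm_name, "F Value"], rel=1e-8
            )

    def test_location_invariance_and_dfs(self, rng):
        y = rng.standard_normal((17, 2, 2, 2))
        base = rm_anova_2x2x2(y)
        shifted = rm_anova_2x2x2(y + 42.0)
        np.testing.assert_allclose(shifted.table["F"], base.table["F"], rtol=1e-9)
        assert (base.table["df1"] == 1).all()
        assert (base.table["df2"] == 16).all()

    def test_pes_definition(self, rng):
        y = rng.standard_normal((5, 2, 2, 2))
        res = rm_anova_2x2x2(y)
        assert ((res.table["pes"] >= 0) & (res.table["pes"] < 1)).all()
        # pes = F / (F + df2) for df1 = 1
        np.testing.assert_allclose(
            res.table["pes"],
            res.table["F"] / (res.table["F"] + res.table["df2"]),
            rtol=1e-10,
        )

    def test_bad_inputs(self, rng):
        with pytest.raises(ValueError, match="shape"):
            rm_anova_2x2x2(rng.standard_normal((5, 2, 2)))
        y = rng.standard_normal((5, 2, 2, 2))
        y[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova_2x2x2(y)


class TestPairedT:
    def test_identical_inputs(self):
        res = paired_t(np.arange(5.0), np.arange(5.0))
        assert res.t == 0.0 and res.p == 1.0

    def test_closed_form_example(self):
        """Differences {1, 2, 3}: t = 2 / (1 / sqrt(3)) = 2 sqrt(3)."""
        res = paired_t(np.array([1.0, 2.0, 3.0]), np.zeros(3))
        assert res.t == pytest.approx(2 * np.sqrt(3), rel=1e-12)
        assert res.df == 2
        assert res.p == pytest.approx(2 * sst.t.sf(2 * np.sqrt(3), 2), rel=1e-12)

    def test_antisymmetry(self, rng):
        x, y = rng.standard_normal(10), rng.standard_normal(10)
        a, b = paired_t(x, y), paired_t(y, x)
        assert a.t == pytest.approx(-b.t)
        assert a.p == pytest.approx(b.p)

    def test_matches_scipy(self, rng):
        x, y = rng.standard_normal(12), rng.standard_normal(12)
        res = paired_t(x, y)
        ref = sst.ttest_rel(x, y)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_constant_nonzero_difference_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t(np.arange(4.0) + 1.0, np.arange(4.0))


class TestDecide:
    @pytest.mark.parametrize("p,expected", [(0.049, True), (0.05, False), (1.0, False)])
    def test_threshold_convention(self, p, expected):
        assert decide(p) is expected

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            decide(0.0)


def test_null_type_i_error_rate(rng):
    """Exchangeable tables reject each effect at ~alpha."""
    n_sim = 400
    rejections = 0
    for _ in range(n_sim):
        y = rng.standard_normal((10, 2, 2, 2))
        rejections += decide(float(rm_anova_2x2x2(y).effect("B")["p"]))
    rate = rejections / n_sim
    assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_sim)
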