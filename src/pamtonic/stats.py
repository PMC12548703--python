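"""Fully within-subject statistics: 2 x 2 x 2 repeated-measures ANOVA,
paired t-tests, and partial eta-squared.

With every factor at two levels, each effect is tested with 1 and N-1
degrees of freedom against its own effect-by-subject interaction mean
square (sphericity is moot at two levels), and F equals the squared
paired t on the corresponding subject-level contrast.  Effect sizes are
partial eta-squared, SS_effect / (SS_effect + SS_error).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = ["RmAnovaResult", "TTestResult", "rm_anova_2x2x2", "paired_t", "decide"]

ALPHA = 0.05


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


@dataclass
class RmAnovaResult:
    """Per-effect F, degrees of freedom, p, and partial eta-squared."""

    table: pd.DataFrame  # effect, F, df1, df2, p, pes

    def effect(self, name: str) -> pd.Series:
        row = self.table.loc[self.table["effect"] == name]
        if row.empty:
            raise KeyError(f"unknown effect {name!r}")
        return row.iloc[0]

    def to_csv(self, path, alpha_levels: tuple[float, float] = (0.05, 0.01)) -> None:
        out = self.table.copy()
        out["sig"] = np.select(
            [out["p"] < alpha_levels[1], out["p"] < alpha_levels[0]], ["**", "*"], ""
        )
        out.to_csv(path, index=False)


def _marginal_mean(y: np.ndarray, keep_axes: tuple[int, ...]) -> np.ndarray:
    drop = tuple(ax for ax in range(y.ndim) if ax not in keep_axes)
    return y.mean(axis=drop, keepdims=True)


def _effect_term(y: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    """Moebius (inclusion-exclusion) effect estimate for a factor subset."""
    term = np.zeros_like(_marginal_mean(y, axes))
    k = len(axes)
    for r in range(k + 1):
        for sub in combinations(axes, r):
            term = term + ((-1) ** (k - r)) * _marginal_mean(y, sub)
    return term


def rm_anova_2x2x2(
    y: np.ndarray, factor_names: tuple[str, str, str] = ("A", "B", "C")
) -> RmAnovaResult:
    """Repeated-measures ANOVA on an (N, 2, 2, 2) array of cell means.

    Axis 0 indexes subjects; axes 1-3 the three two-level within factors.
    Each effect's F is MS_effect / MS_(effect x subject) with df (1, N-1);
    p comes from the exact F distribution.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 4 or y.shape[1:] != (2, 2, 2):
        raise ValueError(f"expected shape (N, 2, 2, 2), got {y.shape}")
    if np.isnan(y).any():
        raise ValueError("missing cells in the design table")
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    rows = []
    for k in (1, 2, 3):
        for axes in combinations((1, 2, 3), k):
            name = " x ".join(factor_names[ax - 1] for ax in axes)
            term = _effect_term(y, axes)
            ss_eff = float(np.sum(np.broadcast_to(term, y.shape) ** 2))
            term_err = _effect_term(y, (0,) + axes)
            ss_err = float(np.sum(np.broadcast_to(term_err, y.shape) ** 2))
            df1, df2 = 1, n - 1
            if ss_err == 0:
                raise ValueError(f"zero error mean square for effect {name!r}")
            f = (ss_eff / df1) / (ss_err / df2)
            p = float(sst.f.sf(f, df1, df2))
            pes = ss_eff / (ss_eff + ss_err)
            rows.append(
                {"effect": name, "F": f, "df1": df1, "df2": df2, "p": p, "pes": pes}
            )
    return RmAnovaResult(table=pd.DataFrame(rows))


def paired_t(x: np.ndarray, y: np.ndarray) -> TTestResult:
    """Two-tailed within-subject t-test: t = mean(d) / (SD(d) / sqrt(N))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-d arrays with N >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):  # identical inputs: no evidence either way
            return TTestResult(t=0.0, df=len(d) - 1, p=1.0)
        raise ValueError("zero-variance nonzero differences; t undefined")
    n = len(d)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * float(sst.t.sf(abs(t), n - 1))
    return TTestResult(t=float(t), df=n - 1, p=p)


def decide(p: float, alpha: float = ALPHA) -> bool:
    """Reject the null iff p < alpha (strict inequality)."""
    if not (0 < p <= 1):
        raise ValueError("p must lie in (0, 1]")
    return p < alpha
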