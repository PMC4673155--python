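"""Shared statistics helpers.

Thin, contract-enforcing wrappers over scipy.stats so every stage reports
statistics in one shape (StatResult) and degenerate inputs are handled
uniformly instead of surfacing NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

from .model import ContractError


@dataclass
class StatResult:
    name: str
    value: float
    p_value: Optional[float]
    n: int
    df: Optional[float] = None
    extra: dict = None

    def as_dict(self) -> dict:
        d = {"statistic": self.name, "value": self.value, "p_value": self.p_value,
             "n": self.n}
        if self.df is not None:
            d["df"] = self.df
        if self.extra:
            d.update(self.extra)
        return d


def two_sample_t(x, y, welch: bool = True) -> StatResult:
    """Two-sided two-sample t-test (Welch by default).

    Degenerate contract: both groups constant with equal means -> p = 1;
    both constant with unequal means -> flagged degenerate (p None).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ContractError("two_sample_t requires n >= 2 in each group")
    if x.std() == 0 and y.std() == 0:
        if x.mean() == y.mean():
            return StatResult("t", 0.0, 1.0, len(x) + len(y),
                              extra={"degenerate": False})
        return StatResult("t", float("inf"), None, len(x) + len(y),
                          extra={"degenerate": True})
    res = sps.ttest_ind(x, y, equal_var=not welch)
    return StatResult("t", float(res.statistic), float(res.pvalue),
                      len(x) + len(y), df=float(res.df))


def chi_square_2x2(counts, correction: bool = False) -> StatResult:
    """Pearson chi-square on a 2x2 table, no continuity correction by default."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ContractError(f"chi_square_2x2 needs a 2x2 table, got {table.shape}")
    if (table < 0).any():
        raise ContractError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return StatResult("chi2", float("nan"), None, int(table.sum()),
                          extra={"degenerate": True})
    chi2, p, df, _ = sps.chi2_contingency(table, correction=correction)
    return StatResult("chi2", float(chi2), float(p), int(table.sum()), df=float(df))


def pearson_regression(x, y) -> StatResult:
    """Least-squares fit of y on x with Pearson r and the slope t-test p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ContractError("pearson_regression requires matched n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return StatResult("pearson_r", float("nan"), None, len(x),
                          extra={"degenerate": True, "slope": float("nan"),
                                 "intercept": float("nan")})
    fit = sps.linregress(x, y)
    return StatResult("pearson_r", float(fit.rvalue), float(fit.pvalue), len(x),
                      extra={"slope": float(fit.slope),
                             "intercept": float(fit.intercept),
                             "degenerate": False})


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> StatResult:
    """Two-sided two-proportion z-test with pooled standard error."""
    if min(n1, n2) == 0:
        return StatResult("z", float("nan"), None, n1 + n2,
                          extra={"degenerate": True})
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return StatResult("z", 0.0, 1.0, n1 + n2, extra={"delta": p2 - p1})
    z = (p2 - p1) / se
    p = 2 * sps.norm.sf(abs(z))
    return StatResult("z", float(z), float(p), n1 + n2,
                      extra={"delta": float(p2 - p1)})


def benjamini_hochberg(p_values):
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj
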