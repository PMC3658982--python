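"""Shared elementary statistics: Welch's two-sample t test.

Both the expression and RPPA modules compare subgroups with an unpooled
(Welch) t test; the implementation lives here so the two layers share one
contract, including the degenerate zero-variance conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = ["TTestResult", "welch_t_test", "welch_t_matrix"]


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: float
    mean_a: float
    mean_b: float
    degenerate: bool = False


def _welch_arrays(ma, mb, va, vb, na, nb):
    """Vectorised Welch statistic, dof and p with degenerate conventions."""
    ma, mb, va, vb = (np.atleast_1d(np.asarray(x, dtype=float))
                      for x in (ma, mb, va, vb))
    sa, sb = va / na, vb / nb
    denom = np.sqrt(sa + sb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
        df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    zerovar = (va == 0) & (vb == 0)
    degenerate = np.zeros_like(t, dtype=bool)
    p = np.empty_like(t)
    ok = ~zerovar
    p[ok] = 2.0 * _sps.t.sf(np.abs(t[ok]), df[ok])
    # both groups constant: equal means -> no evidence (t=0, p=1);
    # unequal means with zero variance -> separation is exact, flagged.
    eq = zerovar & (ma == mb)
    ne = zerovar & (ma != mb)
    t[eq], p[eq], df[eq] = 0.0, 1.0, na + nb - 2
    t[ne] = np.sign(ma[ne] - mb[ne]) * np.inf
    p[ne], df[ne] = 0.0, na + nb - 2
    degenerate[ne] = True
    return t, p, df, degenerate


def welch_t_test(a, b) -> TTestResult:
    """Welch two-sample t with Welch-Satterthwaite degrees of freedom."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    t, p, df, degen = _welch_arrays(
        a.mean(), b.mean(), a.var(ddof=1), b.var(ddof=1), len(a), len(b)
    )
    return TTestResult(float(t[0]), float(p[0]), float(df[0]),
                       float(a.mean()), float(b.mean()), bool(degen[0]))


def welch_t_matrix(A: np.ndarray, B: np.ndarray):
    """Row-wise Welch t over two feature x sample matrices.

    Returns arrays (t, p, df, mean_a, mean_b, degenerate), one entry per row.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape[1] < 2 or B.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples")
    ma, mb = A.mean(axis=1), B.mean(axis=1)
    va, vb = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)
    t, p, df, degen = _welch_arrays(ma, mb, va, vb, A.shape[1], B.shape[1])
    return t, p, df, ma, mb, degen
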