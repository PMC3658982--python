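"""Cross-layer association statistics.

Spearman rank correlation (mid-ranks for ties; exact permutation p for small
n, t-approximation otherwise) and the Mann-Whitney rank-sum test (exact
enumeration for small totals) for comparing bounded scores between
subgroups, plus a concordance report across omic layers.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "SpearmanResult",
    "PairedLayerView",
    "spearman",
    "rank_sum_test",
    "layer_concordance_report",
]

SPEARMAN_EXACT_MAX_N = 8
RANKSUM_EXACT_MAX_TOTAL = 20


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    n: int
    method: str  # "exact" | "t-approx" | "undefined"


@dataclass
class PairedLayerView:
    """Paired values from two layers over their common samples."""

    sample_ids: list
    x: np.ndarray
    y: np.ndarray
    layer_names: tuple[str, str] = ("x", "y")

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.x) != len(self.y) or len(self.x) != len(self.sample_ids):
            raise ValueError("paired layers must have equal length")
        if len(self.x) < 3:
            raise ValueError("paired view needs >= 3 samples")

    @classmethod
    def from_series(cls, a: pd.Series, b: pd.Series,
                    layer_names: tuple[str, str] = ("x", "y")) -> "PairedLayerView":
        common = a.dropna().index.intersection(b.dropna().index)
        return cls(sample_ids=list(common), x=a[common].to_numpy(),
                   y=b[common].to_numpy(), layer_names=layer_names)


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    return float(rx @ ry) / denom


def spearman(view_or_x, y=None) -> SpearmanResult:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of mid-ranks.  For n <= 8 the p-value is
    computed by exhaustive enumeration of all rank permutations of one margin;
    beyond that the usual t-approximation t = rho*sqrt((n-2)/(1-rho^2)) on
    n-2 dof is used.  Zero rank variance in either margin is undefined.
    """
    if y is None:
        x, y = view_or_x.x, view_or_x.y
    else:
        x = np.asarray(view_or_x, dtype=float)
        y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("spearman needs n >= 3")
    rx = _sps.rankdata(x)
    ry = _sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return SpearmanResult(float("nan"), float("nan"), n, "undefined")
    rho = _rank_rho(rx, ry)
    if n <= SPEARMAN_EXACT_MAX_N:
        count = 0
        total = 0
        target = abs(rho) - 1e-12
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_rank_rho(rx, np.array(perm))) >= target:
                count += 1
        return SpearmanResult(rho, count / total, n, "exact")
    if abs(rho) >= 1.0:
        return SpearmanResult(rho, 0.0, n, "t-approx")
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * float(_sps.t.sf(abs(t), n - 2))
    return SpearmanResult(rho, p, n, "t-approx")


def rank_sum_test(scores_a, scores_b) -> tuple[float, float]:
    """Mann-Whitney U with mid-ranks; exact enumeration for small samples.

    Returns (U for the first group, two-sided p).  When the pooled size is at
    most 20 the null distribution of U is enumerated over all group
    assignments of the observed (possibly tied) values; otherwise the normal
    approximation with tie correction is used.  Two-sided p is
    min(1, 2*min(P(U <= u), P(U >= u))).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = _sps.rankdata(pooled)
    u = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    total = na + nb
    if total <= RANKSUM_EXACT_MAX_TOTAL:
        base = na * (na + 1) / 2.0
        us = np.array([
            sum(ranks[i] for i in comb) - base
            for comb in itertools.combinations(range(total), na)
        ])
        pl = float(np.mean(us <= u + 1e-12))
        pg = float(np.mean(us >= u - 1e-12))
        return u, min(1.0, 2.0 * min(pl, pg))
    mu = na * nb / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / (total * (total - 1))
    var = na * nb / 12.0 * ((total + 1) - tie_term)
    if var <= 0:
        return u, 1.0
    z = (u - mu) / math.sqrt(var)
    return u, 2.0 * float(_sps.norm.sf(abs(z)))


def layer_concordance_report(layers: dict[str, pd.Series],
                             strata: pd.Series,
                             pairs: list[tuple[str, str]] | None = None,
                             min_n: int = 3) -> pd.DataFrame:
    """Spearman table for layer pairs, overall and within each stratum.

    ``layers`` maps a layer name to a per-sample Series (e.g. driver mRNA,
    corrected protein, copy-number amplitude, proliferation-marker mRNA);
    ``strata`` maps sample id to subgroup.  Strata with fewer than ``min_n``
    shared samples are reported as not computed rather than raising.
    """
    if pairs is None:
        names = list(layers)
        pairs = list(itertools.combinations(names, 2))
    rows = []
    strata_levels = ["all"] + sorted(strata.dropna().unique(), key=str)
    for la, lb in pairs:
        for stratum in strata_levels:
            sa, sb = layers[la].dropna(), layers[lb].dropna()
            common = sa.index.intersection(sb.index)
            if stratum != "all":
                common = [s for s in common if strata.get(s) == stratum]
            n = len(common)
            if n < min_n:
                rows.append({"pair": f"{la}~{lb}", "stratum": stratum, "n": n,
                             "rho": float("nan"), "p": float("nan"),
                             "computed": False})
                continue
            res = spearman(sa[common].to_numpy(), sb[common].to_numpy())
            rows.append({"pair": f"{la}~{lb}", "stratum": stratum, "n": n,
                         "rho": res.rho, "p": res.p,
                         "computed": res.method != "undefined"})
    return pd.DataFrame(rows)
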