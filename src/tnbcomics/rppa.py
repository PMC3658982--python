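"""Reverse-phase protein array normalisation.

Pipeline per antibody slide (array): collapse each sample's 2-fold dilution
series to one log2 value, median-centre and MAD-scale the array, then remove
per-sample loading effects by regressing each array on the per-sample median
across all arrays of the same group and keeping intercept + residual.  Tumor
samples and cell lines are processed independently throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import TTestResult, welch_t_test

__all__ = [
    "RPPA_COLUMNS",
    "NormalizedRppa",
    "validate_rppa_table",
    "collapse_dilutions",
    "normalize_arrays",
    "loading_correction",
    "normalize_rppa",
    "differential_abundance",
]

RPPA_COLUMNS = ("array_id", "sample_id", "dilution_step", "intensity")


@dataclass
class NormalizedRppa:
    """Array x sample matrix of normalised log2 abundance with diagnostics."""

    values: pd.DataFrame
    per_array_median: pd.Series
    per_array_mad: pd.Series
    loading_slopes_pre: pd.Series
    loading_slopes_post: pd.Series
    skipped_arrays: list = field(default_factory=list)
    group: str | None = None


def validate_rppa_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RPPA_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"RPPA table lacks columns {missing}")
    if (table["intensity"] <= 0).any():
        raise ValueError("intensities must be positive")
    if (table["dilution_step"] < 0).any():
        raise ValueError("dilution steps must be >= 0")
    if table.duplicated(subset=["array_id", "sample_id", "dilution_step"]).any():
        raise ValueError("(array, sample, dilution) keys must be unique")
    return table


def collapse_dilutions(table: pd.DataFrame) -> pd.DataFrame:
    """One log2 value per (array, sample): median of dilution-adjusted spots.

    Each spot is corrected by its expected 2-fold factor,
    ``log2(intensity) + dilution_step``, before taking the median over steps,
    so a single saturated or failed spot cannot drag the estimate.  Missing
    (array, sample) pairs stay absent (NaN in the pivoted matrix).
    """
    table = validate_rppa_table(table)
    adj = np.log2(table["intensity"].to_numpy(dtype=float)) + table["dilution_step"].to_numpy(dtype=float)
    work = table.assign(_adjusted=adj)
    collapsed = work.groupby(["array_id", "sample_id"], sort=True)["_adjusted"].median()
    return collapsed.unstack("sample_id")


def normalize_arrays(values: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Per array (row): subtract the median, divide by the unscaled MAD.

    The MAD is the median absolute deviation from the median with no Gaussian
    consistency factor.  Arrays with MAD 0 (constant signal) are rejected with
    a diagnostic; arrays need >= 3 samples.
    """
    if (values.notna().sum(axis=1) < 3).any():
        bad = values.index[values.notna().sum(axis=1) < 3].tolist()
        raise ValueError(f"arrays with fewer than 3 samples: {bad}")
    med = values.median(axis=1)
    mad = (values.sub(med, axis=0)).abs().median(axis=1)
    zero = mad.index[mad == 0].tolist()
    if zero:
        raise ValueError(f"arrays with zero MAD (constant signal): {zero}")
    normalized = values.sub(med, axis=0).div(mad, axis=0)
    return normalized, med, mad


def loading_correction(normalized: pd.DataFrame, min_samples: int = 3,
                       group: str | None = None,
                       proxy: pd.Series | None = None,
                       per_array_median: pd.Series | None = None,
                       per_array_mad: pd.Series | None = None) -> NormalizedRppa:
    """Remove per-sample loading effects by regression on the loading proxy.

    The proxy is each sample's median over all arrays of the group, computed
    once before any correction (an explicit ``proxy`` can be supplied, e.g.
    to re-apply the correction with the original proxy).  For each array an
    OLS fit value ~ a + b*proxy is computed over its non-missing samples and
    values are replaced by a + residual (equivalently value - b*proxy),
    removing the proxy-dependent component while preserving the array's
    centred level.  Arrays with fewer than ``min_samples`` usable samples are
    skipped with a warning.
    """
    if normalized.shape[0] < 2:
        raise ValueError("loading correction needs >= 2 arrays")
    if proxy is None:
        proxy = normalized.median(axis=0)  # per-sample median across arrays
    corrected = normalized.copy()
    pre, post = {}, {}
    skipped = []

    def _slope(y: np.ndarray, x: np.ndarray) -> float:
        xc = x - x.mean()
        denom = float(xc @ xc)
        if denom == 0:
            return float("nan")
        return float(xc @ (y - y.mean())) / denom

    for array_id, row in normalized.iterrows():
        ok = row.notna() & proxy.notna()
        y = row[ok].to_numpy(dtype=float)
        x = proxy[ok].to_numpy(dtype=float)
        if len(y) < min_samples:
            warnings.warn(
                f"array {array_id}: only {len(y)} samples; loading correction skipped",
                stacklevel=2,
            )
            skipped.append(array_id)
            pre[array_id] = float("nan")
            post[array_id] = float("nan")
            continue
        b = _slope(y, x)
        pre[array_id] = b
        corrected.loc[array_id, ok] = y - b * x
        post[array_id] = _slope(corrected.loc[array_id, ok].to_numpy(dtype=float), x)
    return NormalizedRppa(
        values=corrected,
        per_array_median=per_array_median if per_array_median is not None
        else pd.Series(np.nan, index=normalized.index),
        per_array_mad=per_array_mad if per_array_mad is not None
        else pd.Series(np.nan, index=normalized.index),
        loading_slopes_pre=pd.Series(pre),
        loading_slopes_post=pd.Series(post),
        skipped_arrays=skipped,
        group=group,
    )


def normalize_rppa(table: pd.DataFrame, group_column: str = "group") -> dict[str, NormalizedRppa]:
    """Full RPPA preprocessing, run independently per sample group.

    Collapses dilution series, normalises every array (log2 / median / MAD)
    and applies the loading correction, separately for each level of
    ``group_column`` (e.g. tumor vs cell_line).  Tables without a group column
    are treated as a single 'tumor' group.
    """
    if group_column not in table.columns:
        table = table.assign(**{group_column: "tumor"})
    out: dict[str, NormalizedRppa] = {}
    for grp, sub in table.groupby(group_column, sort=True):
        collapsed = collapse_dilutions(sub)
        normalized, med, mad = normalize_arrays(collapsed)
        out[grp] = loading_correction(normalized, group=grp,
                                      per_array_median=med, per_array_mad=mad)
    return out


def differential_abundance(norm: NormalizedRppa, array_id: str,
                           annotations: pd.Series, group_a: str, group_b: str
                           ) -> TTestResult:
    """Welch t test on one array's corrected values between two subgroups."""
    row = norm.values.loc[array_id]
    a = row[[s for s in row.index if annotations.get(s) == group_a]].dropna()
    b = row[[s for s in row.index if annotations.get(s) == group_b]].dropna()
    return welch_t_test(a.to_numpy(), b.to_numpy())
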