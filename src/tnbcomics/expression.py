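"""Expression preprocessing: replicate averaging, batch adjustment, noise filter.

The input is an already-normalised gene x sample log2 matrix.  Processing
order follows the upstream narrative: technical replicates are averaged
first, then an additive linear model (batch + subgroup, per feature) removes
estimated batch effects while retaining subgroup effects, and finally probes
sitting at the noise floor of the bimodal intensity distribution (log2 < 4 in
>= 95% of samples by default) are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .stats import welch_t_matrix

__all__ = [
    "OmicsMatrix",
    "average_replicates",
    "adjust_batch",
    "noise_floor_filter",
    "differential_expression",
]

_REQUIRED_COLUMNS = ("subgroup", "batch", "replicate_group")


@dataclass
class OmicsMatrix:
    """Feature x sample log2 matrix with per-sample annotations.

    ``values`` is a DataFrame indexed by feature id with sample-id columns;
    ``sample_info`` is indexed by sample id and must carry ``subgroup``,
    ``batch`` and ``replicate_group`` columns (technical replicates share a
    replicate_group label).
    """

    layer: str
    values: pd.DataFrame
    sample_info: pd.DataFrame

    def __post_init__(self) -> None:
        if self.layer not in ("mRNA", "protein"):
            raise ValueError(f"unknown layer {self.layer!r}")
        missing = [c for c in _REQUIRED_COLUMNS if c not in self.sample_info.columns]
        if missing:
            raise ValueError(f"sample_info lacks columns {missing}")
        if list(self.values.columns) != list(self.sample_info.index):
            raise ValueError("values columns and sample_info index must match")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in(self, subgroup: str) -> list[str]:
        info = self.sample_info
        return list(info.index[info["subgroup"] == subgroup])


def average_replicates(m: OmicsMatrix) -> OmicsMatrix:
    """Collapse technical replicates to one column per replicate group.

    Values are arithmetic means per feature; annotations must agree within a
    group (conflicting annotations raise).  The surviving column is named
    after the replicate group.
    """
    groups = m.sample_info["replicate_group"]
    if groups.is_unique:
        return m
    new_cols = {}
    info_rows = {}
    for g, idx in groups.groupby(groups).groups.items():
        cols = list(idx)
        sub = m.sample_info.loc[cols]
        for col in m.sample_info.columns:
            if col == "replicate_group":
                continue
            if sub[col].nunique(dropna=False) > 1:
                raise ValueError(
                    f"replicate group {g!r} has conflicting {col!r} annotations: "
                    f"{sorted(map(str, sub[col].unique()))}"
                )
        new_cols[g] = m.values[cols].mean(axis=1)
        info_rows[g] = sub.iloc[0]
    order = list(dict.fromkeys(groups))  # first-appearance order
    values = pd.DataFrame({g: new_cols[g] for g in order})
    info = pd.DataFrame({g: info_rows[g] for g in order}).T
    info.index.name = m.sample_info.index.name
    info["replicate_group"] = info.index
    return OmicsMatrix(layer=m.layer, values=values, sample_info=info)


def _dummies(labels: pd.Series) -> tuple[np.ndarray, list]:
    levels = sorted(labels.unique(), key=str)
    mat = np.column_stack([(labels == lv).to_numpy(float) for lv in levels[1:]]) \
        if len(levels) > 1 else np.empty((len(labels), 0))
    return mat, levels


def adjust_batch(m: OmicsMatrix) -> OmicsMatrix:
    """Remove additive batch effects estimated per feature by least squares.

    Fits value = mu + batch + subgroup + error on replicate-averaged data and
    subtracts the estimated batch component, centred across samples so the
    global mean of every feature is unchanged.  Subgroup effects stay in the
    data.  Requires >= 2 samples per batch and no perfect batch-subgroup
    confounding.
    """
    if not m.sample_info["replicate_group"].is_unique:
        raise ValueError("average replicates before batch adjustment")
    batches = m.sample_info["batch"]
    if batches.nunique() == 1:
        return m
    small = batches.value_counts()
    small = small[small < 2]
    if len(small):
        raise ValueError(f"batches with fewer than 2 samples: {list(small.index)}")
    B, _ = _dummies(batches)
    S, _ = _dummies(m.sample_info["subgroup"])
    X = np.column_stack([np.ones(m.n_samples), B, S])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        cross = pd.crosstab(batches, m.sample_info["subgroup"])
        confounded = [str(b) for b in cross.index if (cross.loc[b] > 0).sum() == 1]
        raise ValueError(
            "batch and subgroup are perfectly confounded; "
            f"batches seen in a single subgroup: {confounded}; design:\n{cross}"
        )
    Y = m.values.to_numpy(dtype=float)  # features x samples
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    batch_cols = slice(1, 1 + B.shape[1])
    batch_component = B @ beta[batch_cols]  # samples x features
    batch_component -= batch_component.mean(axis=0, keepdims=True)
    adjusted = pd.DataFrame(Y - batch_component.T, index=m.values.index,
                            columns=m.values.columns)
    return replace(m, values=adjusted)


def noise_floor_filter(m: OmicsMatrix, threshold_log2: float = 4.0,
                       fraction: float = 0.95) -> tuple[OmicsMatrix, pd.Index]:
    """Discard features below the noise floor.

    A feature is discarded iff the proportion of samples with value strictly
    below ``threshold_log2`` is >= ``fraction`` ("less than 4 in 95% or more
    of samples").  Returns the retained matrix and the discarded feature ids.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    below = (m.values < threshold_log2).mean(axis=1)
    discard = m.values.index[below >= fraction]
    kept = m.values.drop(index=discard)
    return replace(m, values=kept), discard


def differential_expression(m: OmicsMatrix, group_a: str, group_b: str,
                            fdr: bool = False) -> pd.DataFrame:
    """Per-feature Welch t test between two subgroups.

    Returns a DataFrame (feature-indexed) with group means, t, Welch dof, and
    two-sided p; ``degenerate`` flags zero-variance separations.  Raw
    p-values are the default; ``fdr=True`` adds a Benjamini-Hochberg
    ``q`` column.
    """
    cols_a = m.samples_in(group_a)
    cols_b = m.samples_in(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each subgroup needs >= 2 samples")
    t, p, df, ma, mb, degen = welch_t_matrix(
        m.values[cols_a].to_numpy(), m.values[cols_b].to_numpy()
    )
    out = pd.DataFrame(
        {"mean_a": ma, "mean_b": mb, "t": t, "df": df, "p": p, "degenerate": degen},
        index=m.values.index,
    )
    if fdr and len(out):
        from scipy.stats import false_discovery_control
        out["q"] = false_discovery_control(out["p"].to_numpy(), method="bh")
    return out
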