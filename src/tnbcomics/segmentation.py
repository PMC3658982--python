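"""Least-squares change-point segmentation of ordered probe signal.

A copy-number profile is modelled as a piecewise-constant mean plus noise.
The segmenter finds the exact global minimiser of

    RSS + penalty * (number of breakpoints)

or of the RSS subject to a bound on the number of segments, by dynamic
programming over closed-form least-squares segment costs.  On top of the
single-pass solver sits the two-round protocol used for SNP-array data:
a first round to identify singleton-segment outlier probes, which are
discarded, then a second round followed by merging of segments shorter
than five probes into the adjacent segment with the nearest mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProbeTrack",
    "SegmentationResult",
    "auto_penalty",
    "segment_signal",
    "remove_singleton_outliers",
    "merge_small_segments",
    "run_two_round",
]


@dataclass
class ProbeTrack:
    """One sample's ordered genomic probe signal on a single chromosome.

    Positions are 1-based inclusive genomic coordinates and must be strictly
    increasing; ``values`` are per-probe log2 signal.
    """

    sample_id: str
    chrom: str
    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.ndim != 1 or self.values.ndim != 1:
            raise ValueError("positions and values must be 1-D")
        if len(self.positions) != len(self.values):
            raise ValueError("positions and values must have equal length")
        if len(self.positions) == 0:
            raise ValueError("empty probe track")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("probe values must be finite")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SegmentationResult:
    """Piecewise-constant fit of a probe track.

    ``breakpoints[k] = i`` means the signal changes between retained probes
    ``i`` and ``i + 1`` (0-based indices on the retained probes).  ``smoothed``
    holds each probe's segment mean.  ``retained_index`` maps retained-probe
    indices back to the original track (identity unless outliers were
    discarded); ``discarded_probes`` lists removed original indices.
    """

    breakpoints: np.ndarray
    segment_means: np.ndarray
    segment_sizes: np.ndarray
    smoothed: np.ndarray
    rss: float
    discarded_probes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    retained_index: np.ndarray | None = None
    values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=np.int64)
        self.segment_means = np.asarray(self.segment_means, dtype=float)
        self.segment_sizes = np.asarray(self.segment_sizes, dtype=np.int64)
        self.smoothed = np.asarray(self.smoothed, dtype=float)
        self.discarded_probes = np.asarray(self.discarded_probes, dtype=np.int64)
        if self.retained_index is None:
            self.retained_index = np.arange(len(self.smoothed), dtype=np.int64)
        else:
            self.retained_index = np.asarray(self.retained_index, dtype=np.int64)
        if self.segment_sizes.sum() != len(self.smoothed):
            raise ValueError("segment sizes must sum to retained probe count")

    @property
    def n_segments(self) -> int:
        return len(self.segment_means)

    @property
    def breakpoints_original(self) -> np.ndarray:
        """Breakpoints expressed as original-track probe indices."""
        return self.retained_index[self.breakpoints]

    def segment_bounds(self) -> list[tuple[int, int]]:
        """(start, end) inclusive retained-probe index per segment."""
        starts = np.concatenate(([0], self.breakpoints + 1))
        ends = np.concatenate((self.breakpoints, [len(self.smoothed) - 1]))
        return list(zip(starts.tolist(), ends.tolist()))


def _prefix_sums(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    cs = np.concatenate(([0.0], np.cumsum(values)))
    cs2 = np.concatenate(([0.0], np.cumsum(values * values)))
    return cs, cs2


def auto_penalty(values: np.ndarray) -> float:
    """Default per-breakpoint penalty 2*sigma^2*log(n).

    The noise scale sigma is estimated robustly from the first differences of
    the signal: MAD of successive differences divided by sqrt(2)*0.6745, so
    that isolated level shifts do not inflate the estimate.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        return 1.0
    d = np.diff(values)
    mad = np.median(np.abs(d - np.median(d)))
    sigma = mad / (math.sqrt(2.0) * 0.6745)
    if sigma <= 0:
        sigma = float(np.std(values)) or 1e-6
    return max(2.0 * sigma * sigma * math.log(n), 1e-12)


def _dp_penalized(values: np.ndarray, penalty: float) -> list[int]:
    """Exact optimal-partitioning DP; returns segment end indices (inclusive)."""
    n = len(values)
    cs, cs2 = _prefix_sums(values)
    dp = np.empty(n + 1)
    dp[0] = -penalty
    prev = np.zeros(n + 1, dtype=np.int64)
    idx = np.arange(n + 1, dtype=float)
    for j in range(1, n + 1):
        s = cs[j] - cs[:j]
        cost = (cs2[j] - cs2[:j]) - s * s / (idx[j] - idx[:j])
        cand = dp[:j] + cost
        k = int(np.argmin(cand))
        dp[j] = cand[k] + penalty
        prev[j] = k
    ends = []
    j = n
    while j > 0:
        ends.append(j - 1)
        j = int(prev[j])
    return ends[::-1]


def _dp_max_segments(values: np.ndarray, max_segments: int) -> list[int]:
    """DP minimising RSS with at most ``max_segments`` segments."""
    n = len(values)
    kmax = min(max_segments, n)
    cs, cs2 = _prefix_sums(values)
    idx = np.arange(n + 1, dtype=float)

    def costs_to(j: int) -> np.ndarray:
        s = cs[j] - cs[:j]
        return (cs2[j] - cs2[:j]) - s * s / (idx[j] - idx[:j])

    INF = np.inf
    dp = np.full((kmax + 1, n + 1), INF)
    prev = np.zeros((kmax + 1, n + 1), dtype=np.int64)
    dp[0, 0] = 0.0
    for j in range(1, n + 1):
        cst = costs_to(j)
        for k in range(1, kmax + 1):
            cand = dp[k - 1, :j] + cst
            i = int(np.argmin(cand))
            dp[k, j] = cand[i]
            prev[k, j] = i
    # Prefer the smallest k among (near-)ties so exact fits stay parsimonious.
    best_k = 1
    best = dp[1, n]
    for k in range(2, kmax + 1):
        if dp[k, n] < best - 1e-12:
            best = dp[k, n]
            best_k = k
    ends = []
    j, k = n, best_k
    while k > 0:
        ends.append(j - 1)
        j = int(prev[k, j])
        k -= 1
    return ends[::-1]


def _result_from_ends(values: np.ndarray, ends: list[int],
                      retained_index: np.ndarray | None = None,
                      discarded: np.ndarray | None = None) -> SegmentationResult:
    values = np.asarray(values, dtype=float)
    starts = [0] + [e + 1 for e in ends[:-1]]
    means, sizes = [], []
    smoothed = np.empty_like(values)
    rss = 0.0
    for s, e in zip(starts, ends):
        seg = values[s:e + 1]
        m = float(seg.mean())
        means.append(m)
        sizes.append(e - s + 1)
        smoothed[s:e + 1] = m
        rss += float(((seg - m) ** 2).sum())
    return SegmentationResult(
        breakpoints=np.array(ends[:-1], dtype=np.int64),
        segment_means=np.array(means),
        segment_sizes=np.array(sizes, dtype=np.int64),
        smoothed=smoothed,
        rss=rss,
        discarded_probes=discarded if discarded is not None else np.empty(0, dtype=np.int64),
        retained_index=retained_index,
        values=values.copy(),
    )


def segment_signal(track: ProbeTrack | np.ndarray, penalty: float | str | None = "auto",
                   max_segments: int | None = None) -> SegmentationResult:
    """Single-round exact segmentation (no outlier or merge steps).

    Exactly one of ``penalty`` (> 0, or "auto") and ``max_segments`` is used;
    if ``max_segments`` is given it takes precedence.
    """
    values = track.values if isinstance(track, ProbeTrack) else np.asarray(track, dtype=float)
    if len(values) == 0:
        raise ValueError("cannot segment an empty track")
    if not np.all(np.isfinite(values)):
        raise ValueError("cannot segment non-finite values")
    if max_segments is not None:
        if not 1 <= max_segments:
            raise ValueError("max_segments must be >= 1")
        ends = _dp_max_segments(values, int(max_segments))
    else:
        if penalty is None or penalty == "auto":
            pen = auto_penalty(values)
        else:
            pen = float(penalty)
            if pen <= 0:
                raise ValueError("penalty must be positive")
        ends = _dp_penalized(values, pen)
    return _result_from_ends(values, ends)


def remove_singleton_outliers(track: ProbeTrack, first_round: SegmentationResult
                              ) -> tuple[ProbeTrack, np.ndarray]:
    """Drop every probe forming a 1-probe segment in the first round.

    Returns the reduced track and the removed original probe indices.  Order
    and genomic coordinates of the surviving probes are preserved.
    """
    if len(first_round.smoothed) != len(track):
        raise ValueError("first_round was not produced on this track")
    singleton = np.zeros(len(track), dtype=bool)
    for (s, e), size in zip(first_round.segment_bounds(), first_round.segment_sizes):
        if size == 1:
            singleton[s] = True
    removed = np.flatnonzero(singleton).astype(np.int64)
    if removed.size == 0:
        return track, removed
    keep = ~singleton
    if keep.sum() < 2:
        raise ValueError(
            f"outlier removal would leave {int(keep.sum())} probe(s) of {len(track)}; "
            "the penalty isolates (almost) every probe as a singleton segment"
        )
    reduced = ProbeTrack(
        sample_id=track.sample_id,
        chrom=track.chrom,
        positions=track.positions[keep],
        values=track.values[keep],
    )
    return reduced, removed


def merge_small_segments(seg: SegmentationResult, min_probes: int = 5) -> SegmentationResult:
    """Merge undersized segments into the adjacent segment with nearest mean.

    Iteratively the smallest segment below ``min_probes`` is merged into
    whichever genomic neighbour has the closest mean (ties and exact
    mean-distance ties break toward the left neighbour); means, sizes and RSS
    are recomputed after every merge.  Stops when no segment is undersized or
    a single segment remains.
    """
    means = seg.segment_means.astype(float).tolist()
    sizes = seg.segment_sizes.astype(int).tolist()
    ends = [e for _, e in seg.segment_bounds()]
    rss = float(seg.rss)
    while len(means) > 1:
        under = [(sz, i) for i, sz in enumerate(sizes) if sz < min_probes]
        if not under:
            break
        _, i = min(under)  # smallest first; ties toward the leftmost
        if i == 0:
            j = 1
        elif i == len(means) - 1:
            j = i - 1
        else:
            dl = abs(means[i] - means[i - 1])
            dr = abs(means[i] - means[i + 1])
            j = i - 1 if dl <= dr else i + 1
        a, b = (j, i) if j < i else (i, j)
        na, nb = sizes[a], sizes[b]
        ma, mb = means[a], means[b]
        merged_mean = (na * ma + nb * mb) / (na + nb)
        # pooled SS identity: merging adds n_a*n_b/(n_a+n_b)*(m_a-m_b)^2
        rss += na * nb / (na + nb) * (ma - mb) ** 2
        means[a] = merged_mean
        sizes[a] = na + nb
        ends[a] = ends[b]
        del means[b], sizes[b], ends[b]
    n = int(np.sum(sizes))
    smoothed = np.empty(n)
    start = 0
    for m, sz in zip(means, sizes):
        smoothed[start:start + sz] = m
        start += sz
    return SegmentationResult(
        breakpoints=np.array(ends[:-1], dtype=np.int64),
        segment_means=np.array(means),
        segment_sizes=np.array(sizes, dtype=np.int64),
        smoothed=smoothed,
        rss=rss,
        discarded_probes=seg.discarded_probes,
        retained_index=seg.retained_index,
        values=seg.values,
    )


def run_two_round(track: ProbeTrack, penalty: float | str | None = "auto",
                  min_probes: int = 5) -> SegmentationResult:
    """Full segmentation protocol: segment, drop singleton outliers, re-segment,
    merge sub-``min_probes`` segments, smooth.

    The returned result is indexed on retained probes; ``retained_index`` maps
    back to the original track and ``discarded_probes`` lists removed probes.
    """
    first = segment_signal(track, penalty=penalty)
    reduced, removed = remove_singleton_outliers(track, first)
    second = segment_signal(reduced, penalty=penalty)
    retained = np.setdiff1d(np.arange(len(track), dtype=np.int64), removed)
    second = SegmentationResult(
        breakpoints=second.breakpoints,
        segment_means=second.segment_means,
        segment_sizes=second.segment_sizes,
        smoothed=second.smoothed,
        rss=second.rss,
        discarded_probes=removed,
        retained_index=retained,
        values=reduced.values,
    )
    return merge_small_segments(second, min_probes=min_probes)
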