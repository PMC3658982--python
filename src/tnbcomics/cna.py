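"""Gain/loss calling on smoothed copy-number signal.

Thresholds are the extreme empirical quantiles (default .999 / .001, type-7
linear interpolation) of pooled smoothed probe signal from healthy reference
tissue.  Calls use strict comparisons: a smoothed value exactly at a threshold
is neutral.  A locus is called gained in a sample if any probe overlapping the
locus interval is called gain (symmetrically for loss).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .segmentation import ProbeTrack, SegmentationResult

__all__ = [
    "GAIN",
    "NEUTRAL",
    "LOSS",
    "GenomicInterval",
    "CnaCallSet",
    "calibrate_thresholds",
    "call_cna",
    "locus_amplitude",
    "gain_frequency_by_group",
]

GAIN, NEUTRAL, LOSS = 1, 0, -1
_LABELS = {GAIN: "gain", NEUTRAL: "neutral", LOSS: "loss"}


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("interval end before start")


@dataclass
class CnaCallSet:
    gain_threshold: float
    loss_threshold: float
    probe_calls: np.ndarray
    segment_calls: np.ndarray
    locus_calls: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.loss_threshold > self.gain_threshold:
            raise ValueError("loss threshold above gain threshold")

    def probe_labels(self) -> list[str]:
        return [_LABELS[c] for c in self.probe_calls]


def calibrate_thresholds(healthy_smoothed: np.ndarray,
                         gain_quantile: float = 0.999,
                         loss_quantile: float = 0.001) -> tuple[float, float]:
    """Gain/loss thresholds as empirical quantiles of the healthy pool.

    Uses linear-interpolation (type-7) quantiles so thresholds are
    bit-reproducible.  Warns when the pool is small (< 1000 values) because
    extreme quantiles are then poorly determined.
    """
    pool = np.asarray(healthy_smoothed, dtype=float).ravel()
    if pool.size == 0:
        raise ValueError("empty healthy pool")
    if pool.size < 1000:
        warnings.warn(
            f"healthy pool has only {pool.size} values; "
            "extreme quantile thresholds will be unstable",
            stacklevel=2,
        )
    gain = float(np.quantile(pool, gain_quantile, method="linear"))
    loss = float(np.quantile(pool, loss_quantile, method="linear"))
    return gain, loss


def _classify(values: np.ndarray, gain: float, loss: float) -> np.ndarray:
    calls = np.zeros(len(values), dtype=np.int8)
    calls[values > gain] = GAIN
    calls[values < loss] = LOSS
    return calls


def call_cna(seg: SegmentationResult, thresholds: tuple[float, float],
             track: ProbeTrack | None = None,
             loci: dict[str, GenomicInterval] | None = None) -> CnaCallSet:
    """Call gains/losses on a segmentation at probe, segment and locus level.

    ``thresholds`` is ``(gain_threshold, loss_threshold)`` from
    :func:`calibrate_thresholds`.  Locus calls require the originating
    ``track`` for probe coordinates; loci with no overlapping probes are
    called neutral with a warning.
    """
    gain, loss = thresholds
    probe_calls = _classify(seg.smoothed, gain, loss)
    segment_calls = _classify(seg.segment_means, gain, loss)
    locus_calls: dict[str, int] = {}
    if loci:
        if track is None:
            raise ValueError("locus calls require the probe track for coordinates")
        positions = track.positions[seg.retained_index]
        for name, iv in loci.items():
            if iv.chrom != track.chrom:
                mask = np.zeros(len(positions), dtype=bool)
            else:
                mask = (positions >= iv.start) & (positions <= iv.end)
            if not mask.any():
                warnings.warn(f"locus {name} overlaps no probes; called neutral", stacklevel=2)
                locus_calls[name] = NEUTRAL
                continue
            calls_here = probe_calls[mask]
            if (calls_here == GAIN).any():
                locus_calls[name] = GAIN
            elif (calls_here == LOSS).any():
                locus_calls[name] = LOSS
            else:
                locus_calls[name] = NEUTRAL
    return CnaCallSet(gain_threshold=gain, loss_threshold=loss,
                      probe_calls=probe_calls, segment_calls=segment_calls,
                      locus_calls=locus_calls)


def locus_amplitude(seg: SegmentationResult, track: ProbeTrack,
                    locus: GenomicInterval) -> float:
    """Smoothed log2 amplitude at a locus: mean over overlapping probes."""
    positions = track.positions[seg.retained_index]
    mask = (positions >= locus.start) & (positions <= locus.end)
    if locus.chrom != track.chrom or not mask.any():
        return float("nan")
    return float(seg.smoothed[mask].mean())


def gain_frequency_by_group(locus_calls: dict[str, int],
                            annotations: dict[str, str],
                            call: int = GAIN) -> tuple[dict[str, float], pd.DataFrame]:
    """Per-subgroup locus-call fractions plus pairwise Fisher exact tests.

    ``locus_calls`` maps sample id to the locus call code of that sample and
    ``annotations`` maps sample id to subgroup.  Returns the per-subgroup
    fraction carrying ``call`` (default: gain) and a table of two-sided Fisher
    exact p-values for every subgroup pair with the underlying 2x2 counts.
    Subgroups without samples are excluded with a warning.
    """
    missing = [s for s in locus_calls if s not in annotations]
    if missing:
        raise ValueError(f"samples without subgroup annotation: {missing[:5]}")
    counts: dict[str, list[int]] = {}
    for sample, c in locus_calls.items():
        grp = annotations[sample]
        counts.setdefault(grp, [0, 0])
        if c == call:
            counts[grp][0] += 1
        else:
            counts[grp][1] += 1
    empty = [g for g, (a, b) in counts.items() if a + b == 0]
    for g in empty:
        warnings.warn(f"subgroup {g} has no samples; excluded", stacklevel=2)
        del counts[g]
    fractions = {g: a / (a + b) for g, (a, b) in counts.items()}
    rows = []
    for ga, gb in itertools.combinations(sorted(counts), 2):
        table = [counts[ga], counts[gb]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({
            "group_a": ga, "group_b": gb,
            "gained_a": counts[ga][0], "other_a": counts[ga][1],
            "gained_b": counts[gb][0], "other_b": counts[gb][1],
            "fisher_p": float(p),
        })
    return fractions, pd.DataFrame(rows)
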