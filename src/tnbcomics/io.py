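"""Readers and writers for the pipeline's tab-delimited interchange formats.

All tables are plain TSV.  Probe tracks are long-format
(probe_id, chrom, pos, sample_id, log2_signal); the expression matrix is
features x samples with a sidecar annotation table; RPPA is long
(array_id, sample_id, dilution_step, intensity[, group]); survival is
(sample_id, time, event, endpoint).  Segment tables are written in SEG
convention (1-based inclusive coordinates) and calls in BED convention
(0-based half-open); the conversion happens here and only here.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .cna import CnaCallSet, _LABELS
from .expression import OmicsMatrix
from .segmentation import ProbeTrack, SegmentationResult

__all__ = [
    "write_probe_tracks", "read_probe_tracks",
    "write_omics_matrix", "read_omics_matrix",
    "write_rppa_table", "read_rppa_table",
    "write_survival", "read_survival",
    "write_seg", "write_bed_calls",
]


def write_probe_tracks(tracks: dict[str, ProbeTrack], path: str | Path) -> None:
    frames = []
    for sample_id, track in tracks.items():
        frames.append(pd.DataFrame({
            "probe_id": [f"p{i:06d}" for i in range(len(track))],
            "chrom": track.chrom,
            "pos": track.positions,
            "sample_id": sample_id,
            "log2_signal": track.values,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_probe_tracks(path: str | Path) -> dict[str, ProbeTrack]:
    df = pd.read_csv(path, sep="\t")
    tracks = {}
    for sample_id, sub in df.groupby("sample_id", sort=False):
        sub = sub.sort_values("pos")
        tracks[sample_id] = ProbeTrack(
            sample_id=str(sample_id),
            chrom=str(sub["chrom"].iloc[0]),
            positions=sub["pos"].to_numpy(),
            values=sub["log2_signal"].to_numpy(),
        )
    return tracks


def write_omics_matrix(m: OmicsMatrix, matrix_path: str | Path,
                       annotation_path: str | Path) -> None:
    m.values.to_csv(matrix_path, sep="\t", index_label="feature_id")
    m.sample_info.to_csv(annotation_path, sep="\t", index_label="sample_id")


def read_omics_matrix(matrix_path: str | Path, annotation_path: str | Path,
                      layer: str = "mRNA") -> OmicsMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col="feature_id")
    info = pd.read_csv(annotation_path, sep="\t", index_col="sample_id")
    return OmicsMatrix(layer=layer, values=values, sample_info=info)


def write_rppa_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_rppa_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_survival(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_survival(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_seg(results: dict[str, tuple[ProbeTrack, SegmentationResult]],
              path: str | Path) -> None:
    """Segment table, SEG convention: 1-based inclusive start/end positions."""
    rows = []
    for sample_id, (track, seg) in results.items():
        positions = track.positions[seg.retained_index]
        for (s, e), mean, size in zip(seg.segment_bounds(),
                                      seg.segment_means, seg.segment_sizes):
            rows.append({
                "sample": sample_id, "chrom": track.chrom,
                "start": int(positions[s]), "end": int(positions[e]),
                "num_probes": int(size), "seg_mean": float(mean),
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_bed_calls(results: dict[str, tuple[ProbeTrack, SegmentationResult, CnaCallSet]],
                    path: str | Path) -> None:
    """Per-segment calls, BED convention: 0-based half-open intervals."""
    rows = []
    for sample_id, (track, seg, calls) in results.items():
        positions = track.positions[seg.retained_index]
        for (s, e), call in zip(seg.segment_bounds(), calls.segment_calls):
            rows.append({
                "chrom": track.chrom,
                "start": int(positions[s]) - 1,  # SEG 1-based -> BED 0-based
                "end": int(positions[e]),
                "name": f"{sample_id}:{_LABELS[int(call)]}",
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)
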