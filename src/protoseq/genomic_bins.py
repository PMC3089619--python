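"""Annotation-free expression comparison on fixed-width genomic bins.

The genome is tiled with non-overlapping bins (default 100 bp, last bin of
a chromosome may be short). Reads are counted into the bin containing
their 5' position (strand ignored), bin RPM uses the same library-level
non-ribo/mito denominator as transcript RPM, and differential bins are
those with RPM above a floor in at least one group and a group ratio above
a fold threshold. Bins are classified exonic > intronic > intergenic by
>= 1 bp overlap with exons / locus spans.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import (
    BinTrack,
    ReadSet,
    TranscriptModel,
    ValidationError,
    as_chrom_sizes,
)

BIN_CLASSES = ("exonic", "intronic", "intergenic")


@dataclass
class BinDEConfig:
    """Differential-bin thresholds: RPM floor for eligibility (in at least
    one group) and the strict fold threshold."""

    min_rpm: float = 0.95
    min_ratio: float = 3.0

    def __post_init__(self) -> None:
        if self.min_rpm < 0:
            raise ValidationError("min_rpm must be >= 0")
        if self.min_ratio <= 1:
            raise ValidationError("min_ratio must be > 1")


def make_bins(chrom_sizes: Mapping[str, int], width: int = 100) -> BinTrack:
    """Tile each chromosome with ceil(size/width) half-open bins."""
    if width < 1:
        raise ValidationError("bin width must be >= 1")
    sizes = as_chrom_sizes(chrom_sizes)
    frames = []
    for chrom in sizes:
        size = sizes[chrom]
        starts = np.arange(0, size, width, dtype=np.int64)
        ends = np.minimum(starts + width, size)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    bins = pd.concat(frames, ignore_index=True)
    return BinTrack(width=width, bins=bins)


def _chrom_offsets(track: BinTrack) -> dict[str, tuple[int, int]]:
    """Per chromosome: (row offset of first bin, number of bins)."""
    out = {}
    for chrom, grp in track.bins.groupby("chrom", sort=False):
        out[chrom] = (int(grp.index[0]), len(grp))
    return out


def count_bins(track: BinTrack, reads: ReadSet | Sequence[ReadSet]) -> BinTrack:
    """Count each read into the bin containing its 5' position.

    Strand is ignored. Reads on chromosomes absent from the track trigger a
    warning and are skipped. Adds one count column per channel (existing
    columns are kept).
    """
    readsets = [reads] if isinstance(reads, ReadSet) else list(reads)
    offsets = _chrom_offsets(track)
    counts = track.counts.copy() if track.counts is not None else pd.DataFrame(
        index=track.bins.index
    )
    for rs in readsets:
        col = np.zeros(track.n_bins, dtype=np.int64)
        n_unknown = 0
        chroms = np.asarray(rs.chroms)
        for chrom in pd.unique(chroms):
            pos = rs.positions[chroms == chrom]
            if chrom not in offsets:
                n_unknown += len(pos)
                continue
            off, n = offsets[chrom]
            idx = pos // track.width
            bad = (idx < 0) | (idx >= n)
            if bad.any():
                raise ValidationError(
                    f"read position outside chromosome {chrom}"
                )
            np.add.at(col, off + idx, 1)
        if n_unknown:
            warnings.warn(
                f"channel {rs.channel.channel_id}: {n_unknown} reads on unknown "
                "chromosomes skipped",
                stacklevel=2,
            )
        counts[rs.channel.channel_id] = col
    return BinTrack(width=track.width, bins=track.bins, counts=counts, rpm=track.rpm)


def bin_rpm(track: BinTrack, library_totals: Mapping[str, int]) -> BinTrack:
    """Bin RPM = bin count x 1e6 / library-level non-ribo/mito read total.

    Using the library denominator (not a bin-universe denominator) keeps
    bin RPM on the same scale as transcript RPM, so an RPM floor translates
    directly into a raw-read floor for the shallowest library.
    """
    if track.counts is None:
        raise ValidationError("track has no counts")
    rpm = {}
    for ch in track.counts.columns:
        if ch not in library_totals:
            raise ValidationError(f"no library total for channel {ch!r}")
        total = float(library_totals[ch])
        if total <= 0:
            raise ValidationError(f"zero library total for channel {ch!r}")
        rpm[ch] = track.counts[ch].astype(float) * 1_000_000.0 / total
    return BinTrack(width=track.width, bins=track.bins, counts=track.counts,
                    rpm=pd.DataFrame(rpm, index=track.bins.index))


def differential_bins(
    track: BinTrack,
    group_a: str,
    group_b: str,
    config: BinDEConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Bins expressed above the fold threshold in one group.

    Eligible bins have RPM >= min_rpm in at least one of the two groups;
    the A-higher set has RPM_A / RPM_B > min_ratio (zero denominator counts
    as infinite ratio). The two direction sets are disjoint. Returns per
    direction a copy of the bin rows with ``rpm_a``, ``rpm_b`` and
    ``ratio`` columns.
    """
    if config is None:
        config = BinDEConfig()
    if track.rpm is None:
        raise ValidationError("track has no RPM (run bin_rpm first)")
    a = track.rpm[group_a].to_numpy()
    b = track.rpm[group_b].to_numpy()
    eligible = (a >= config.min_rpm) | (b >= config.min_rpm)

    def higher(num: np.ndarray, den: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            r = num / den
        return eligible & (((den > 0) & (r > config.min_ratio)) | ((den == 0) & (num > 0)))

    out = {}
    for name, mask, num, den in (
        ("a_higher", higher(a, b), a, b),
        ("b_higher", higher(b, a), b, a),
    ):
        rows = track.bins[mask].copy()
        rows["rpm_a"] = a[mask]
        rows["rpm_b"] = b[mask]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(den[mask] > 0, num[mask] / den[mask], np.inf)
        rows["ratio"] = ratio
        out[name] = rows
    return out


def _merged(intervals: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    ivs = sorted(intervals)
    starts, ends = [], []
    for a, b in ivs:
        if ends and a <= ends[-1]:
            ends[-1] = max(ends[-1], b)
        else:
            starts.append(a)
            ends.append(b)
    return np.array(starts, dtype=np.int64), np.array(ends, dtype=np.int64)


def _overlaps_any(starts: np.ndarray, ends: np.ndarray,
                  bin_starts: np.ndarray, bin_ends: np.ndarray) -> np.ndarray:
    """For each bin, whether any merged interval overlaps it by >= 1 bp."""
    if len(starts) == 0:
        return np.zeros(len(bin_starts), dtype=bool)
    # first interval whose end is > bin start; overlap iff it starts before bin end
    pos = np.searchsorted(ends, bin_starts, side="right")
    ok = pos < len(starts)
    res = np.zeros(len(bin_starts), dtype=bool)
    res[ok] = starts[pos[ok]] < bin_ends[ok]
    return res


def classify_bins(track: BinTrack, models: Sequence[TranscriptModel]) -> BinTrack:
    """Classify each bin exonic / intronic / intergenic (strand ignored).

    A bin is exonic if it overlaps >= 1 bp of any exon, else intronic if it
    overlaps the genomic span of any locus, else intergenic.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    spans: dict[str, list[tuple[int, int]]] = {}
    for m in models:
        exons.setdefault(m.chrom, []).extend(m.exons)
        spans.setdefault(m.chrom, []).append(m.span)
    classes = np.full(track.n_bins, "intergenic", dtype=object)
    for chrom, grp in track.bins.groupby("chrom", sort=False):
        bs = grp["start"].to_numpy()
        be = grp["end"].to_numpy()
        idx = grp.index.to_numpy()
        if chrom in spans:
            s, e = _merged(spans[chrom])
            intronic = _overlaps_any(s, e, bs, be)
            classes[idx[intronic]] = "intronic"
        if chrom in exons:
            s, e = _merged(exons[chrom])
            exonic = _overlaps_any(s, e, bs, be)
            classes[idx[exonic]] = "exonic"
    bins = track.bins.copy()
    bins["bin_class"] = classes
    return BinTrack(width=track.width, bins=bins, counts=track.counts, rpm=track.rpm)


def write_differential_bed(
    diff: Mapping[str, pd.DataFrame], path, score_cap: float = 1000.0
) -> None:
    """Write differential bins as BED (name = direction, score = ratio
    capped at ``score_cap``)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for direction, rows in diff.items():
            for _, r in rows.iterrows():
                score = min(float(r["ratio"]), score_cap)
                w.writerow([r["chrom"], int(r["start"]), int(r["end"]),
                            direction, f"{score:g}"])


def class_summary(track: BinTrack) -> pd.Series:
    """Counts of bins per class (requires classify_bins)."""
    if "bin_class" not in track.bins.columns:
        raise ValidationError("track is not classified")
    return track.bins["bin_class"].value_counts().reindex(BIN_CLASSES, fill_value=0)
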