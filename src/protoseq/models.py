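"""Core containers shared by every pipeline stage.

Coordinates are 0-based, half-open (BED convention) throughout the package;
GFF3 input is converted on load. Transcript categories are ``ribosomal``,
``mitochondrial`` and ``other``; ribosomal and mitochondrial reads are
excluded from every expression denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

Interval = tuple[int, int]

CATEGORIES = ("ribosomal", "mitochondrial", "other")
BIOTYPES = ("coding", "noncoding", "histone", "other")

#: resolution order when collapsed members disagree (lower wins ties)
CATEGORY_PRECEDENCE = {"mitochondrial": 0, "ribosomal": 1, "other": 2}
BIOTYPE_PRECEDENCE = {"coding": 0, "noncoding": 1, "histone": 2, "other": 3}

CATEGORY_COLUMNS = (
    "ribosomal_reads",
    "mitochondrial_reads",
    "other_reads",
    "total_reads",
)


class ProtoseqError(Exception):
    """Base class for all package errors."""


class ParseError(ProtoseqError):
    """A record in an input file could not be parsed."""


class ValidationError(ProtoseqError):
    """An input violated a documented contract."""


@dataclass
class TranscriptModel:
    """A (possibly collapsed) transcript locus with exon structure.

    ``median_length`` is the representative length used for length binning
    and length normalization; for a freshly loaded transcript it equals
    ``spliced_length``, for a collapsed locus it is the median over members.
    """

    id: str
    chrom: str
    strand: str
    exons: list[Interval]
    category: str = "other"
    biotype: str = "other"
    is_polyadenylated: bool | None = None
    locus_id: str | None = None
    median_length: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.id}: strand must be '+' or '-', got {self.strand!r}")
        if self.category not in CATEGORIES:
            raise ValidationError(f"{self.id}: unknown category {self.category!r}")
        if self.biotype not in BIOTYPES:
            raise ValidationError(f"{self.id}: unknown biotype {self.biotype!r}")
        exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in exons:
            if b <= a:
                raise ValidationError(f"{self.id}: empty or inverted exon [{a},{b})")
        for (_, b0), (a1, _) in zip(exons, exons[1:]):
            if a1 < b0:
                raise ValidationError(f"{self.id}: overlapping exons")
        self.exons = exons
        if self.spliced_length <= 0:
            raise ValidationError(f"{self.id}: spliced length must be positive")
        if self.locus_id is None:
            self.locus_id = self.id
        if self.median_length is None:
            self.median_length = float(self.spliced_length)
        if self.median_length <= 0:
            raise ValidationError(f"{self.id}: median length must be positive")

    @property
    def spliced_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])


@dataclass
class ChannelMeta:
    """Identity of one sequencing channel (flow-cell lane equivalent)."""

    channel_id: str
    sample: str = ""
    protocol: str = ""
    replicate: str = ""


@dataclass
class ReadSet:
    """Aligned-read evidence for one channel: 5' positions only.

    Read length plays no role anywhere in the package; a read is located by
    the genomic coordinate of its 5' end and its strand.
    """

    channel: ChannelMeta
    chroms: np.ndarray  # dtype object/str
    positions: np.ndarray  # int
    strands: np.ndarray  # '+' / '-'

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.strands = np.asarray(self.strands, dtype=object)
        if not (len(self.chroms) == len(self.positions) == len(self.strands)):
            raise ValidationError("ReadSet arrays must have equal length")

    def __len__(self) -> int:
        return len(self.positions)


class CountTable:
    """Integer read counts per transcript per channel plus category totals.

    ``category_totals`` has one row per channel with columns
    ``ribosomal_reads / mitochondrial_reads / other_reads / total_reads``;
    when built by this package the first three sum exactly to the fourth.
    ``other_reads`` counts *all* non-ribosomal/non-mitochondrial reads,
    including those that hit no annotated exon — it is the RPM denominator.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        category_totals: pd.DataFrame,
        transcript_categories: pd.Series | None = None,
        channels: Sequence[ChannelMeta] | None = None,
        validate: bool = True,
    ) -> None:
        self.counts = counts.astype(np.int64)
        self.category_totals = category_totals.loc[counts.columns, list(CATEGORY_COLUMNS)].astype(
            np.int64
        )
        if transcript_categories is None:
            transcript_categories = pd.Series("other", index=counts.index, dtype=object)
        self.transcript_categories = transcript_categories.reindex(counts.index).fillna("other")
        self.channels = list(channels) if channels is not None else [
            ChannelMeta(channel_id=str(c)) for c in counts.columns
        ]
        if validate:
            self.validate()

    # -- basic introspection -------------------------------------------------
    @property
    def transcript_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def channel_ids(self) -> list[str]:
        return list(self.counts.columns)

    def validate(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative count in CountTable")
        ids = pd.Index(self.channel_ids)
        if ids.has_duplicates:
            raise ValidationError("duplicate channel ids")
        tot = self.category_totals
        if (tot.to_numpy() < 0).any():
            raise ValidationError("negative category total")
        lhs = tot["ribosomal_reads"] + tot["mitochondrial_reads"] + tot["other_reads"]
        if (lhs > tot["total_reads"]).any():
            raise ValidationError("category totals exceed total_reads")

    def copy(self) -> "CountTable":
        return CountTable(
            self.counts.copy(),
            self.category_totals.copy(),
            self.transcript_categories.copy(),
            [ChannelMeta(**vars(c)) for c in self.channels],
            validate=False,
        )


@dataclass
class ExpressionMatrix:
    """Normalized expression per transcript per channel group.

    In RPM mode each column sums to 1e6 x (assigned non-ribo/mito reads /
    all non-ribo/mito reads) for its group. Ribosomal and mitochondrial
    transcripts are excluded from the rows and from the denominators.
    """

    values: pd.DataFrame
    mode: str  # "RPM", "RPKM", "permuted-length"
    denominators: pd.Series  # per-group non-ribo/mito read count
    normalization_total: float = 1_000_000.0

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression values must be nonnegative")

    @property
    def group_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GatingRule:
    """Expression-presence gate: strictly greater than ``threshold`` RPM."""

    threshold: float = 5.0
    scope: str = "any"  # "any" (any compared group) or "each"

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValidationError("gating threshold must be >= 0")
        if self.scope not in ("any", "each"):
            raise ValidationError("scope must be 'any' or 'each'")


STRATA_LABELS = ("5-10", ">10-50", ">50-100", ">100-1K", ">1K-10K", ">10K")
#: stratum boundaries: first stratum [5, 10], then (10, 50], (50, 100], ...
STRATA_EDGES = (5.0, 10.0, 50.0, 100.0, 1000.0, 10000.0)


@dataclass
class StrataCounts:
    """Counts of expressed transcripts per RPM stratum (detection gate >= 5 RPM)."""

    counts: dict[str, int]
    total: int

    def __post_init__(self) -> None:
        if self.total != sum(self.counts.values()):
            raise ValidationError("strata total must equal the sum of strata")


@dataclass
class BinTrack:
    """Fixed-width genomic bins with per-channel counts.

    ``bins`` has columns chrom/start/end (plus ``bin_class`` after
    classification); ``counts`` and ``rpm`` are row-aligned with ``bins``.
    Bins tile each chromosome without overlap; the last bin may be short.
    """

    width: int
    bins: pd.DataFrame
    counts: pd.DataFrame | None = None
    rpm: pd.DataFrame | None = None

    @property
    def n_bins(self) -> int:
        return len(self.bins)


def as_chrom_sizes(sizes: Mapping[str, int] | pd.Series) -> dict[str, int]:
    out = {str(k): int(v) for k, v in dict(sizes).items()}
    for chrom, size in out.items():
        if size < 1:
            raise ValidationError(f"chromosome {chrom} has nonpositive size")
    return out


def models_by_id(models: Iterable[TranscriptModel]) -> dict[str, TranscriptModel]:
    out: dict[str, TranscriptModel] = {}
    for m in models:
        if m.id in out:
            raise ValidationError(f"duplicate transcript id {m.id}")
        out[m.id] = m
    return out


def median_length_series(models: Iterable[TranscriptModel]) -> pd.Series:
    d = {m.id: float(m.median_length) for m in models}
    return pd.Series(d, dtype=float)
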