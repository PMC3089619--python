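"""Annotation / read / count-table I-O, locus collapsing and read assignment.

Readers: BED12 and GFF3 transcript annotations, BED6 read positions,
two-column chrom.sizes tables, and TSV count tables with reserved summary
rows ``__ribosomal__`` / ``__mitochondrial__`` / ``__total__``.
"""

from __future__ import annotations

import csv
import warnings
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .models import (
    CATEGORY_COLUMNS,
    CATEGORY_PRECEDENCE,
    BIOTYPE_PRECEDENCE,
    ChannelMeta,
    CountTable,
    Interval,
    ParseError,
    ReadSet,
    TranscriptModel,
    ValidationError,
    as_chrom_sizes,
)

RESERVED_ROWS = ("__ribosomal__", "__mitochondrial__", "__total__")


# ---------------------------------------------------------------------------
# annotation loading
# ---------------------------------------------------------------------------

def load_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>size`` table."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 'chrom<TAB>size'")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: size is not an integer") from exc
    return as_chrom_sizes(sizes)


def _categorize(tid: str, chrom: str, mito_chrom: str, ribo_ids: set[str]) -> str:
    if chrom == mito_chrom:
        return "mitochondrial"
    if tid in ribo_ids:
        return "ribosomal"
    return "other"


def _parse_bed12_line(parts: list[str], lineno: int, path: str) -> TranscriptModel:
    try:
        chrom = parts[0]
        start = int(parts[1])
        end = int(parts[2])
        name = parts[3]
        strand = parts[5]
        n_blocks = int(parts[9])
        sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
        offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
    except (IndexError, ValueError) as exc:
        raise ParseError(f"{path}:{lineno}: malformed BED12 record") from exc
    if len(sizes) != n_blocks or len(offsets) != n_blocks:
        raise ParseError(f"{path}:{lineno}: blockCount disagrees with block lists")
    exons = [(start + off, start + off + sz) for off, sz in zip(offsets, sizes)]
    if exons[-1][1] != end:
        raise ParseError(f"{path}:{lineno}: blocks do not reach chromEnd")
    return TranscriptModel(id=name, chrom=chrom, strand=strand, exons=exons)


def load_annotation(
    path: str | Path,
    format: str = "BED12",
    mito_chrom: str = "chrM",
    ribo_ids: Iterable[str] = (),
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[TranscriptModel]:
    """Load transcript models from BED12 or GFF3.

    Categories are assigned from ``mito_chrom`` (chromosome name) and
    ``ribo_ids`` (caller-supplied id set). If ``chrom_sizes`` is given,
    transcripts on chromosomes absent from it raise a validation error.
    """
    ribo = set(ribo_ids)
    fmt = format.upper()
    if fmt == "BED12":
        models = _load_bed12(path)
    elif fmt == "GFF3":
        models = _load_gff3(path)
    else:
        raise ValidationError(f"unknown annotation format {format!r}")
    for m in models:
        m.category = _categorize(m.id, m.chrom, mito_chrom, ribo)
        if chrom_sizes is not None and m.chrom not in chrom_sizes:
            raise ValidationError(f"{m.id}: chromosome {m.chrom} absent from chrom.sizes")
    return models


def _load_bed12(path: str | Path) -> list[TranscriptModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            models.append(_parse_bed12_line(line.split("\t"), lineno, str(path)))
    return models


def _gff3_attributes(field: str) -> dict[str, str]:
    out = {}
    for item in field.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            continue
        k, v = item.split("=", 1)
        out[k] = v
    return out


def _load_gff3(path: str | Path) -> list[TranscriptModel]:
    """Minimal GFF3 reader: exon features grouped by their Parent attribute.

    1-based closed GFF3 coordinates are converted to 0-based half-open.
    """
    exons: dict[str, list[Interval]] = {}
    meta: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated GFF3 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype.lower() != "exon":
                continue
            try:
                iv = (int(start) - 1, int(end))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            parent = _gff3_attributes(attrs).get("Parent")
            if parent is None:
                raise ParseError(f"{path}:{lineno}: exon without Parent attribute")
            for pid in parent.split(","):
                exons.setdefault(pid, []).append(iv)
                prev = meta.setdefault(pid, (chrom, strand))
                if prev != (chrom, strand):
                    raise ParseError(f"{path}:{lineno}: exons of {pid} disagree on chrom/strand")
    models = []
    for tid in sorted(exons):
        chrom, strand = meta[tid]
        models.append(TranscriptModel(id=tid, chrom=chrom, strand=strand, exons=exons[tid]))
    return models


# ---------------------------------------------------------------------------
# locus collapsing
# ---------------------------------------------------------------------------

def _merge_intervals(ivs: Iterable[Interval]) -> list[Interval]:
    ivs = sorted(ivs)
    out: list[Interval] = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def _majority(values: list[str], precedence: Mapping[str, int]) -> str:
    counts = Counter(values)
    best = max(counts.values())
    tied = [v for v, c in counts.items() if c == best]
    return min(tied, key=lambda v: precedence[v])


def collapse_loci(models: Sequence[TranscriptModel]) -> list[TranscriptModel]:
    """Merge same-strand transcripts with overlapping genomic spans.

    The collapsed exon set is the interval union of member exons; the locus
    ``median_length`` is the median of member median_lengths (equal to
    member spliced lengths for freshly loaded transcripts, which makes the
    operation idempotent). Category/biotype are resolved by majority with
    mitochondrial > ribosomal > other (and coding > noncoding > histone >
    other) winning ties. The locus id is the lexicographically smallest
    member id.
    """
    groups: dict[tuple[str, str], list[TranscriptModel]] = {}
    for m in models:
        groups.setdefault((m.chrom, m.strand), []).append(m)
    out: list[TranscriptModel] = []
    for (chrom, strand), members in groups.items():
        members = sorted(members, key=lambda m: m.span)
        cluster: list[TranscriptModel] = []
        cluster_end = -1
        clusters: list[list[TranscriptModel]] = []
        for m in members:
            s, e = m.span
            if cluster and s < cluster_end:
                cluster.append(m)
                cluster_end = max(cluster_end, e)
            else:
                if cluster:
                    clusters.append(cluster)
                cluster = [m]
                cluster_end = e
        if cluster:
            clusters.append(cluster)
        for cl in clusters:
            locus_id = min(m.id for m in cl)
            exons = _merge_intervals(iv for m in cl for iv in m.exons)
            polya_votes = [m.is_polyadenylated for m in cl if m.is_polyadenylated is not None]
            polya = None
            if polya_votes:
                polya = sum(polya_votes) * 2 >= len(polya_votes)
            out.append(
                TranscriptModel(
                    id=locus_id,
                    locus_id=locus_id,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    category=_majority([m.category for m in cl], CATEGORY_PRECEDENCE),
                    biotype=_majority([m.biotype for m in cl], BIOTYPE_PRECEDENCE),
                    is_polyadenylated=polya,
                    median_length=float(np.median([m.median_length for m in cl])),
                )
            )
    out.sort(key=lambda m: (m.chrom, m.span, m.id))
    return out


# ---------------------------------------------------------------------------
# read assignment
# ---------------------------------------------------------------------------

def load_reads_bed(path: str | Path, channel: ChannelMeta | str) -> ReadSet:
    """Read BED6 read positions; the 5' position is chromStart on '+' and
    chromEnd-1 on '-'."""
    if isinstance(channel, str):
        channel = ChannelMeta(channel_id=channel)
    chroms, positions, strands = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: BED6 requires 6 columns (strand needed)")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = parts[5]
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: strand must be '+' or '-'")
            chroms.append(parts[0])
            positions.append(start if strand == "+" else end - 1)
            strands.append(strand)
    return ReadSet(channel, np.array(chroms, dtype=object),
                   np.array(positions), np.array(strands, dtype=object))


def _exon_trees(models: Sequence[TranscriptModel]) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for idx, m in enumerate(models):
        t = trees.setdefault((m.chrom, m.strand), IntervalTree())
        for a, b in m.exons:
            t.addi(a, b, idx)
    return trees


def assign_reads(
    reads: ReadSet | Sequence[ReadSet],
    models: Sequence[TranscriptModel],
    chrom_sizes: Mapping[str, int] | None = None,
) -> CountTable:
    """Count reads per collapsed locus, strand-aware, by 5' position.

    A read increments the transcript whose exon contains its 5' position on
    the same strand; when exons of several loci contain it, the
    lexicographically smallest ``locus_id`` wins. Reads hitting no exon
    still count toward ``other_reads``/``total_reads`` (they remain
    available to the genomic-bin stage); reads on chromosomes absent from
    ``chrom_sizes`` trigger a warning and count in ``total_reads`` only.
    """
    readsets = [reads] if isinstance(reads, ReadSet) else list(reads)
    trees = _exon_trees(models)
    ids = [m.id for m in models]
    cats = [m.category for m in models]
    counts = pd.DataFrame(
        0, index=pd.Index(ids, name="transcript_id"),
        columns=[rs.channel.channel_id for rs in readsets], dtype=np.int64,
    )
    totals = pd.DataFrame(
        0, index=counts.columns, columns=list(CATEGORY_COLUMNS), dtype=np.int64
    )
    for rs in readsets:
        ch = rs.channel.channel_id
        n_unknown = 0
        for chrom, pos, strand in zip(rs.chroms, rs.positions, rs.strands):
            totals.loc[ch, "total_reads"] += 1
            if chrom_sizes is not None and chrom not in chrom_sizes:
                n_unknown += 1
                continue
            tree = trees.get((chrom, strand))
            hits = tree[pos] if tree is not None else set()
            if hits:
                idx = min(hits, key=lambda h: models[h.data].locus_id).data
                counts.iloc[idx, counts.columns.get_loc(ch)] += 1
                cat = cats[idx]
            else:
                cat = "other"
            if cat == "ribosomal":
                totals.loc[ch, "ribosomal_reads"] += 1
            elif cat == "mitochondrial":
                totals.loc[ch, "mitochondrial_reads"] += 1
            else:
                totals.loc[ch, "other_reads"] += 1
        if n_unknown:
            warnings.warn(
                f"channel {ch}: {n_unknown} reads on chromosomes absent from chrom.sizes "
                "counted in total_reads only",
                stacklevel=2,
            )
    tx_cat = pd.Series(cats, index=counts.index, dtype=object)
    return CountTable(counts, totals, tx_cat, [rs.channel for rs in readsets])


# ---------------------------------------------------------------------------
# count-table round trip
# ---------------------------------------------------------------------------

def write_counts(table: CountTable, path: str | Path) -> None:
    """Write a TSV count table with reserved summary rows.

    ``other_reads`` is recoverable as total - ribosomal - mitochondrial.
    Transcript categories are stored in a ``#category=`` header comment so
    the round trip is lossless.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        nondefault = table.transcript_categories[table.transcript_categories != "other"]
        if len(nondefault):
            spec = ",".join(f"{t}:{c}" for t, c in nondefault.items())
            fh.write(f"#category={spec}\n")
        w.writerow(["transcript_id", *table.channel_ids])
        for tid, row in table.counts.iterrows():
            w.writerow([tid, *row.tolist()])
        tot = table.category_totals
        w.writerow(["__ribosomal__", *tot["ribosomal_reads"].tolist()])
        w.writerow(["__mitochondrial__", *tot["mitochondrial_reads"].tolist()])
        w.writerow(["__total__", *tot["total_reads"].tolist()])


def load_counts(path: str | Path, permissive: bool = False) -> CountTable:
    """Load a TSV count table written by :func:`write_counts`.

    Refuses tables whose reserved category rows are inconsistent with the
    total (ribo + mito > total, or per-transcript sums exceeding the
    implied category totals) unless ``permissive`` is set. Negative or
    non-integer counts are always rejected.
    """
    categories: dict[str, str] = {}
    rows: list[list[str]] = []
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#category="):
                    for item in line[len("#category="):].split(","):
                        if item:
                            t, c = item.split(":")
                            categories[t] = c
                continue
            parts = line.split("\t")
            if header is None:
                if parts[0] != "transcript_id":
                    raise ParseError(f"{path}:{lineno}: header must start with 'transcript_id'")
                header = parts[1:]
                continue
            if len(parts) != len(header) + 1:
                raise ParseError(f"{path}:{lineno}: wrong number of columns")
            rows.append(parts)
    if header is None:
        raise ParseError(f"{path}: missing header")

    def parse_count(text: str, lineno_hint: str) -> int:
        try:
            val = int(text)
        except ValueError as exc:
            raise ValidationError(f"{path}: non-integer count {text!r} in {lineno_hint}") from exc
        if val < 0:
            raise ValidationError(f"{path}: negative count in {lineno_hint}")
        return val

    data: dict[str, list[int]] = {}
    reserved: dict[str, list[int]] = {}
    for parts in rows:
        tid = parts[0]
        vals = [parse_count(x, tid) for x in parts[1:]]
        if tid in RESERVED_ROWS:
            reserved[tid] = vals
        else:
            data[tid] = vals
    counts = pd.DataFrame.from_dict(data, orient="index", columns=header)
    counts.index.name = "transcript_id"
    ribo = np.array(reserved.get("__ribosomal__", [0] * len(header)))
    mito = np.array(reserved.get("__mitochondrial__", [0] * len(header)))
    cat_series = pd.Series(categories, dtype=object).reindex(counts.index).fillna("other")
    if "__total__" in reserved:
        total = np.array(reserved["__total__"])
    else:
        total = counts.to_numpy().sum(axis=0)
    other = total - ribo - mito
    if not permissive:
        if (other < 0).any():
            raise ValidationError(f"{path}: ribosomal+mitochondrial exceed total")
        is_other = (cat_series == "other").to_numpy()
        assigned_other = counts.to_numpy()[is_other].sum(axis=0)
        if (assigned_other > other).any():
            raise ValidationError(
                f"{path}: per-transcript counts exceed the implied non-ribo/mito total "
                "(use permissive=True to accept)"
            )
    totals = pd.DataFrame(
        {
            "ribosomal_reads": ribo,
            "mitochondrial_reads": mito,
            "other_reads": np.maximum(other, 0),
            "total_reads": total,
        },
        index=pd.Index(header),
    )
    return CountTable(counts, totals, cat_series, validate=not permissive)


def write_annotation_bed12(models: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as BED12 (score column carries 0)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for m in models:
            start, end = m.span
            sizes = ",".join(str(b - a) for a, b in m.exons)
            offsets = ",".join(str(a - start) for a, b in m.exons)
            w.writerow(
                [m.chrom, start, end, m.id, 0, m.strand, start, end, "0,0,0",
                 len(m.exons), sizes, offsets]
            )
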