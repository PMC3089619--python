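import numpy as np
import pandas as pd
import pytest

from protoseq.models import ChannelMeta, CountTable, ReadSet, TranscriptModel


@pytest.fixture
def three_locus_models():
    """Three non-overlapping loci on two chromosomes, one per category."""
    return [
        TranscriptModel(id="locA", chrom="chr1", strand="+",
                        exons=[(100, 200), (300, 400)], category="other"),
        TranscriptModel(id="locB", chrom="chr1", strand="-",
                        exons=[(1000, 1600)], category="ribosomal"),
        TranscriptModel(id="locC", chrom="chrM", strand="+",
                        exons=[(10, 500)], category="mitochondrial"),
    ]


@pytest.fixture
def chrom_sizes():
    return {"chr1": 5000, "chrM": 1000}


def make_readset(channel, records):
    """records: list of (chrom, pos, strand)."""
    chroms, pos, strands = zip(*records) if records else ((), (), ())
    return ReadSet(
        ChannelMeta(channel_id=channel),
        np.array(chroms, dtype=object),
        np.array(pos, dtype=np.int64),
        np.array(strands, dtype=object),
    )


def make_count_table(counts: dict, ribo=0, mito=0, unassigned=0,
                     categories=None):
    """CountTable from {transcript: {channel: n}} plus per-channel extras.

    ribo/mito/unassigned may be ints (same for every channel) or dicts.
    """
    df = pd.DataFrame(counts).T.fillna(0).astype(int)
    df.index.name = "transcript_id"

    def per_channel(x):
        return x if isinstance(x, dict) else {c: x for c in df.columns}

    ribo, mito, unassigned = map(per_channel, (ribo, mito, unassigned))
    cats = pd.Series(categories or {}, dtype=object).reindex(df.index).fillna("other")
    totals = pd.DataFrame(
        {
            "ribosomal_reads": df.loc[cats == "ribosomal"].sum(axis=0) + pd.Series(ribo),
            "mitochondrial_reads": df.loc[cats == "mitochondrial"].sum(axis=0)
            + pd.Series(mito),
            "other_reads": df.loc[cats == "other"].sum(axis=0) + pd.Series(unassigned),
        }
    )
    totals["total_reads"] = totals.sum(axis=1)
    return CountTable(df, totals, cats)
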