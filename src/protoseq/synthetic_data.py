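"""Synthetic transcriptomes and protocol-specific read sampling.

The generator emulates the composition of human total RNA: a handful of
ribosomal species carrying ~85% of the sampling mass, polyadenylated
mitochondrial transcripts carrying ~5%, and a remainder of coding polyA+,
noncoding (mostly polyA-), and histone (polyA-) transcripts with
log-normal lengths and abundances spanning several orders of magnitude.

Sampling models:

* multi-read RNA-Seq (random-hexamer priming): weight = m * L — longer
  molecules offer more priming sites, so reads scale with molar abundance
  times length;
* DGE (3' tag counting): weight = m for polyadenylated transcripts, 0
  otherwise — one read per molecule regardless of length;
* protocol multipliers: rRNA depletion leaves a residual fraction of rRNA
  weight; each polyA-selection round retains ``capture`` of polyA+ and
  ``polya_carryover`` of polyA- weight; selected primers suppress rRNA and
  very short (<200 nt) species; fragmentation retains r(L) = L / (L +
  frag_scale) of each transcript's weight.

Reads per channel are a multinomial draw of the configured depth over the
normalized weights; channel seeds derive from one master seed by the
counter scheme SeedSequence([master, channel_index]).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .models import (
    CATEGORY_COLUMNS,
    ChannelMeta,
    CountTable,
    ReadSet,
    TranscriptModel,
    ValidationError,
)

PROTOCOLS = ("total", "ribominus", "polya1", "polya2", "selected_primers", "dge")


@dataclass
class TranscriptomeParams:
    """Distribution settings for :func:`generate_transcriptome`.

    Lengths are log-normal with the given median (nt) and log10 sd;
    abundances are log-normal with ``sigma_log10_abundance`` (1.0 spans
    about four decades across a transcriptome). ``ribo_weight_share`` /
    ``mito_weight_share`` fix the fraction of total-RNA sampling mass
    (m*L) carried by the ribosomal / mitochondrial sets. The remaining
    transcript count is split coding polyA+ / noncoding polyA- / histone
    polyA- / noncoding polyA+ by the ``frac_*`` fields.
    """

    median_length: float = 2000.0
    sigma_log10_length: float = 0.4
    sigma_log10_abundance: float = 1.0
    n_ribo: int = 8
    n_mito: int = 15
    ribo_weight_share: float = 0.85
    mito_weight_share: float = 0.05
    frac_coding: float = 0.70
    frac_noncoding_polya_minus: float = 0.20
    frac_histone: float = 0.05
    frac_noncoding_polya_plus: float = 0.05
    transcripts_per_chrom: int = 500
    min_gap: int = 1000
    max_exons: int = 5
    mito_chrom: str = "chrM"

    def __post_init__(self) -> None:
        fracs = (self.frac_coding, self.frac_noncoding_polya_minus,
                 self.frac_histone, self.frac_noncoding_polya_plus)
        if any(f < 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
            raise ValidationError("class fractions must be nonnegative and sum to 1")
        if not (0 <= self.ribo_weight_share < 1 and 0 <= self.mito_weight_share < 1):
            raise ValidationError("weight shares must be in [0,1)")
        if self.ribo_weight_share + self.mito_weight_share >= 1:
            raise ValidationError("ribo+mito weight share must be < 1")


@dataclass
class ProtocolConfig:
    """Simulator parameters for one library protocol.

    ``rrna_residual``: fraction of rRNA weight surviving depletion
    (ribominus). ``polya_carryover`` / ``capture``: per-round weight
    retention of polyA- / polyA+ transcripts under polyA selection.
    ``frag_scale``: nt scale of the fragmentation retention r(L) =
    L/(L+frag_scale). ``sp_rrna_residual`` / ``sp_short_penalty``:
    selected-primer multipliers for rRNA and for transcripts < 200 nt.
    ``rt_stop_rate``: per-nt RT termination probability for DGE 5' tag
    displacement.
    """

    protocol: str = "total"
    depth: int = 1_000_000
    seed: int = 0
    fragmented: bool = False
    rrna_residual: float = 0.2
    polya_carryover: float = 0.02
    capture: float = 0.9
    frag_scale: float = 400.0
    sp_rrna_residual: float = 0.1
    sp_short_penalty: float = 0.1
    rt_stop_rate: float = 1.0 / 4000.0

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValidationError(f"unknown protocol {self.protocol!r}")
        if self.depth < 1:
            raise ValidationError("depth must be >= 1")
        for name in ("rrna_residual", "polya_carryover", "capture",
                     "sp_rrna_residual", "sp_short_penalty", "rt_stop_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0,1]")
        if self.frag_scale < 0:
            raise ValidationError("frag_scale must be >= 0")


@dataclass
class SyntheticTranscriptome:
    """Truth table of a simulated transcriptome plus genome placement.

    ``table`` columns: length, abundance, category, biotype,
    is_polyadenylated, chrom, strand; ``exons`` holds per-transcript exon
    interval lists in genomic coordinates.
    """

    table: pd.DataFrame
    exons: dict[str, list[tuple[int, int]]]
    chrom_sizes: dict[str, int]
    params: TranscriptomeParams

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def ribo_ids(self) -> set[str]:
        return set(self.table.index[self.table["category"] == "ribosomal"])

    def lengths(self) -> pd.Series:
        return self.table["length"].astype(float)

    def weight_shares(self, config: ProtocolConfig | None = None) -> pd.Series:
        """Per-category share of total sampling weight under a protocol
        (default: plain total-RNA RNA-Seq)."""
        if config is None:
            config = ProtocolConfig(protocol="total")
        w = sampling_weights(self, config)
        shares = pd.Series(w, index=self.table.index).groupby(
            self.table["category"]
        ).sum()
        return shares / shares.sum()

    def to_annotation(self, exclude: Sequence[str] = ()) -> list[TranscriptModel]:
        """Truth annotation as collapsed transcript models (loci are placed
        without overlap, so no further collapsing is needed)."""
        excluded = set(exclude)
        models = []
        for tid, row in self.table.iterrows():
            if tid in excluded:
                continue
            models.append(
                TranscriptModel(
                    id=tid,
                    chrom=row["chrom"],
                    strand=row["strand"],
                    exons=self.exons[tid],
                    category=row["category"],
                    biotype=row["biotype"],
                    is_polyadenylated=bool(row["is_polyadenylated"]),
                )
            )
        return models


def _split_lengths(rng: np.random.Generator, total: int, parts: int) -> list[int]:
    """Random composition of ``total`` into ``parts`` positive integers."""
    if parts == 1:
        return [total]
    cuts = np.sort(rng.choice(np.arange(1, total), size=parts - 1, replace=False))
    bounds = np.concatenate([[0], cuts, [total]])
    return list(np.diff(bounds).astype(int))


def generate_transcriptome(
    n: int,
    seed: int,
    params: TranscriptomeParams | None = None,
) -> SyntheticTranscriptome:
    """Draw a seed-reproducible synthetic transcriptome.

    ``n`` counts all transcripts including the ribosomal and mitochondrial
    sets. Lengths and abundances are drawn independently; ribosomal and
    mitochondrial abundances are rescaled so their total-RNA sampling-mass
    shares equal the configured targets exactly. Transcripts are tiled onto
    synthetic chromosomes with >= ``min_gap`` nt gaps and 1..max_exons
    exons; mitochondrial transcripts live on ``mito_chrom``.
    """
    if params is None:
        params = TranscriptomeParams()
    if n < 10:
        raise ValidationError("n must be >= 10")
    n_ribo = params.n_ribo
    n_mito = params.n_mito
    if n_ribo + n_mito >= n:
        raise ValidationError("n too small for the ribo/mito sets")
    if n_ribo == 0 and params.ribo_weight_share > 0:
        raise ValidationError("ribo_weight_share > 0 requires n_ribo > 0")
    if n_mito == 0 and params.mito_weight_share > 0:
        raise ValidationError("mito_weight_share > 0 requires n_mito > 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    ln10 = np.log(10.0)
    lengths = np.maximum(
        np.round(
            rng.lognormal(np.log(params.median_length),
                          params.sigma_log10_length * ln10, size=n)
        ).astype(int),
        50,
    )
    abundance = rng.lognormal(0.0, params.sigma_log10_abundance * ln10, size=n)

    n_other = n - n_ribo - n_mito
    n_coding = round(params.frac_coding * n_other)
    n_nc_minus = round(params.frac_noncoding_polya_minus * n_other)
    n_hist = round(params.frac_histone * n_other)
    n_nc_plus = round(params.frac_noncoding_polya_plus * n_other)
    n_coding += n_other - (n_coding + n_nc_minus + n_hist + n_nc_plus)

    category = (["ribosomal"] * n_ribo + ["mitochondrial"] * n_mito
                + ["other"] * n_other)
    biotype = (["other"] * n_ribo + ["coding"] * n_mito
               + ["coding"] * n_coding + ["noncoding"] * n_nc_minus
               + ["histone"] * n_hist + ["noncoding"] * n_nc_plus)
    polya = ([False] * n_ribo + [True] * n_mito
             + [True] * n_coding + [False] * n_nc_minus
             + [False] * n_hist + [True] * n_nc_plus)

    # rescale ribo/mito molar abundances to hit the target weight shares of
    # the total-RNA sampling mass w = m * L
    w = abundance * lengths
    w_other = w[n_ribo + n_mito:].sum()
    share_other = 1.0 - params.ribo_weight_share - params.mito_weight_share
    if n_ribo:
        target = params.ribo_weight_share / share_other * w_other
        abundance[:n_ribo] *= target / w[:n_ribo].sum()
    if n_mito:
        target = params.mito_weight_share / share_other * w_other
        abundance[n_ribo:n_ribo + n_mito] *= target / w[n_ribo:n_ribo + n_mito].sum()

    ids = [f"tx{i:05d}" for i in range(n)]
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    strands[n_ribo:n_ribo + n_mito] = "+"

    exons: dict[str, list[tuple[int, int]]] = {}
    chroms = np.empty(n, dtype=object)
    chrom_sizes: dict[str, int] = {}
    cursor = 0
    chrom_idx = 0
    placed_on_chrom = 0
    for i in range(n):
        is_mito = n_ribo <= i < n_ribo + n_mito
        if is_mito:
            chrom = params.mito_chrom
        else:
            if placed_on_chrom >= params.transcripts_per_chrom:
                chrom_sizes[f"chr{chrom_idx + 1}"] = cursor + params.min_gap
                chrom_idx += 1
                placed_on_chrom = 0
                cursor = 0
            chrom = f"chr{chrom_idx + 1}"
        L = int(lengths[i])
        k = int(rng.integers(1, params.max_exons + 1)) if L > params.max_exons else 1
        sizes = _split_lengths(rng, L, k)
        introns = rng.integers(100, 2001, size=k - 1)
        if is_mito:
            start = chrom_sizes.get(params.mito_chrom, 0)
        else:
            start = cursor + params.min_gap + int(rng.integers(0, 500))
        ivs = []
        pos = start
        for j, sz in enumerate(sizes):
            ivs.append((pos, pos + sz))
            pos += sz
            if j < k - 1:
                pos += int(introns[j])
        exons[ids[i]] = ivs
        chroms[i] = chrom
        if is_mito:
            chrom_sizes[params.mito_chrom] = pos + params.min_gap
        else:
            cursor = pos
            placed_on_chrom += 1
    if placed_on_chrom or chrom_idx == 0:
        chrom_sizes[f"chr{chrom_idx + 1}"] = cursor + params.min_gap

    table = pd.DataFrame(
        {
            "length": lengths,
            "abundance": abundance,
            "category": category,
            "biotype": biotype,
            "is_polyadenylated": polya,
            "chrom": chroms,
            "strand": strands,
        },
        index=pd.Index(ids, name="transcript_id"),
    )
    return SyntheticTranscriptome(table=table, exons=exons,
                                  chrom_sizes=chrom_sizes, params=params)


def sampling_weights(tx: SyntheticTranscriptome, config: ProtocolConfig) -> np.ndarray:
    """Per-transcript sampling weight under one protocol configuration."""
    t = tx.table
    m = t["abundance"].to_numpy(dtype=float)
    L = t["length"].to_numpy(dtype=float)
    polya = t["is_polyadenylated"].to_numpy(dtype=bool)
    ribo = (t["category"] == "ribosomal").to_numpy()
    if config.protocol == "dge":
        w = np.where(polya, m, 0.0)
    else:
        w = m * L
    if config.protocol == "ribominus":
        w = np.where(ribo, w * config.rrna_residual, w)
    elif config.protocol in ("polya1", "polya2"):
        rounds = 1 if config.protocol == "polya1" else 2
        w = np.where(polya, w * config.capture ** rounds,
                     w * config.polya_carryover ** rounds)
    elif config.protocol == "selected_primers":
        w = np.where(ribo, w * config.sp_rrna_residual, w)
        w = np.where(L < 200, w * config.sp_short_penalty, w)
    if config.fragmented:
        w = w * L / (L + config.frag_scale)
    return w


def _spliced_to_genomic(exons: list[tuple[int, int]], offsets: np.ndarray) -> np.ndarray:
    """Map offsets in genomic (left-to-right) spliced coordinates to genome."""
    sizes = np.array([b - a for a, b in exons], dtype=np.int64)
    starts = np.array([a for a, _ in exons], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(sizes)])
    which = np.searchsorted(cum, offsets, side="right") - 1
    return starts[which] + (offsets - cum[which])


def _read_positions(
    tx: SyntheticTranscriptome,
    counts: np.ndarray,
    config: ProtocolConfig,
    rng: np.random.Generator,
) -> ReadSet:
    chroms_out: list[np.ndarray] = []
    pos_out: list[np.ndarray] = []
    strand_out: list[np.ndarray] = []
    t = tx.table
    for i, (tid, row) in enumerate(t.iterrows()):
        c = int(counts[i])
        if c == 0:
            continue
        L = int(row["length"])
        if config.protocol == "dge":
            # RT starts at the 3' end and extends a geometric(rt_stop_rate)
            # number of nt; molecules extended past the 5' end read exactly
            # at the 5' end, so short transcripts pile up there
            extended = rng.geometric(max(config.rt_stop_rate, 1e-12), size=c)
            t5 = np.maximum(L - extended, 0)
        else:
            t5 = rng.integers(0, L, size=c)
        u = t5 if row["strand"] == "+" else (L - 1 - t5)
        g = _spliced_to_genomic(tx.exons[tid], np.asarray(u, dtype=np.int64))
        chroms_out.append(np.full(c, row["chrom"], dtype=object))
        pos_out.append(g)
        strand_out.append(np.full(c, row["strand"], dtype=object))
    meta = ChannelMeta(channel_id=f"{config.protocol}_s{config.seed}",
                       protocol=config.protocol)
    if not chroms_out:
        return ReadSet(meta, np.array([], dtype=object), np.array([], dtype=np.int64),
                       np.array([], dtype=object))
    return ReadSet(meta, np.concatenate(chroms_out), np.concatenate(pos_out),
                   np.concatenate(strand_out))


def simulate_channel(
    tx: SyntheticTranscriptome,
    config: ProtocolConfig,
    channel_id: str | None = None,
    return_reads: bool = False,
) -> CountTable | tuple[CountTable, ReadSet]:
    """Draw one channel: counts ~ multinomial(depth, w / sum w).

    Optionally also returns read 5' positions: uniform along the spliced
    transcript for multi-read protocols, geometric displacement from the 5'
    end (truncated at the transcript length) for DGE.
    """
    w = sampling_weights(tx, config)
    total = w.sum()
    if total <= 0:
        raise ValidationError("zero total sampling weight")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed)]))
    counts = rng.multinomial(config.depth, w / total)
    if channel_id is None:
        channel_id = f"{config.protocol}_s{config.seed}"
    cat = tx.table["category"]
    totals = pd.DataFrame(
        {
            "ribosomal_reads": [int(counts[(cat == "ribosomal").to_numpy()].sum())],
            "mitochondrial_reads": [int(counts[(cat == "mitochondrial").to_numpy()].sum())],
            "other_reads": [int(counts[(cat == "other").to_numpy()].sum())],
            "total_reads": [int(config.depth)],
        },
        index=pd.Index([channel_id]),
    )
    frame = pd.DataFrame({channel_id: counts}, index=tx.table.index)
    meta = ChannelMeta(channel_id=channel_id, protocol=config.protocol)
    table = CountTable(frame, totals, cat.copy(), [meta])
    if not return_reads:
        return table
    reads = _read_positions(tx, counts, config, rng)
    reads.channel = meta
    return table, reads


def channel_seed(master: int, index: int) -> int:
    """Derived per-channel seed: counter scheme SeedSequence([master, index])."""
    return int(np.random.SeedSequence([int(master), int(index)]).generate_state(1)[0] % (2**31))


def simulate_replicates(
    tx: SyntheticTranscriptome,
    config: ProtocolConfig,
    k: int,
    label: str | None = None,
) -> CountTable:
    """k independent channels of one protocol with derived seeds."""
    if k < 2:
        raise ValidationError("k must be >= 2")
    if label is None:
        label = config.protocol
    tables = []
    for i in range(k):
        cfg = replace(config, seed=channel_seed(config.seed, i))
        tables.append(simulate_channel(tx, cfg, channel_id=f"{label}_rep{i + 1}"))
    counts = pd.concat([t.counts for t in tables], axis=1)
    totals = pd.concat([t.category_totals for t in tables], axis=0)
    metas = [
        ChannelMeta(channel_id=f"{label}_rep{i + 1}", protocol=config.protocol,
                    replicate=str(i + 1))
        for i in range(k)
    ]
    return CountTable(counts, totals, tx.table["category"].copy(), metas)


def inject_fold_changes(
    tx: SyntheticTranscriptome,
    fraction: float,
    fold: float,
    seed: int,
    eligible: Sequence[str] | None = None,
) -> tuple[SyntheticTranscriptome, pd.DataFrame]:
    """Return a copy with fold changes injected into a seed-chosen subset.

    ``round(fraction * n_eligible)`` transcripts are relabeled, half up
    (abundance x fold) and half down (/ fold); all other fields are
    untouched. The returned truth labels have columns direction ('up' /
    'down') and fold.
    """
    if not 0 < fraction < 1:
        raise ValidationError("fraction must be in (0,1)")
    if fold <= 1:
        raise ValidationError("fold must be > 1")
    pool = list(tx.table.index if eligible is None else eligible)
    m = round(fraction * len(pool))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    chosen = list(rng.choice(pool, size=m, replace=False))
    n_up = m // 2
    table = tx.table.copy()
    table.loc[chosen[:n_up], "abundance"] *= fold
    table.loc[chosen[n_up:], "abundance"] /= fold
    labels = pd.DataFrame(
        {
            "direction": ["up"] * n_up + ["down"] * (m - n_up),
            "fold": fold,
        },
        index=pd.Index(chosen, name="transcript_id"),
    )
    out = SyntheticTranscriptome(table=table, exons=tx.exons,
                                 chrom_sizes=tx.chrom_sizes, params=tx.params)
    return out, labels


#: default spike truth set: seven species, concentrations spanning three
#: decades, including one short (325 nt) spike at the lowest concentration
DEFAULT_SPIKES = pd.DataFrame(
    {
        "id": ["spike_agp", "spike_b", "spike_c", "spike_d",
               "spike_e", "spike_f", "spike_g"],
        "length": [325, 9786, 1451, 2500, 1200, 800, 2000],
        "concentration": [1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0],
    }
)


def simulate_spikes(
    truth: pd.DataFrame,
    depth: int,
    seed: int,
    length_proportional: bool = True,
) -> pd.Series:
    """Multinomial spike counts with weights concentration x length (or
    concentration alone when ``length_proportional`` is off)."""
    if len(truth) < 2:
        raise ValidationError("need >= 2 spikes")
    t = truth.set_index("id")
    w = t["concentration"].to_numpy(dtype=float)
    if length_proportional:
        w = w * t["length"].to_numpy(dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    counts = rng.multinomial(int(depth), w / w.sum())
    return pd.Series(counts, index=t.index, name="count")
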