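"""End-to-end simulation experiments over the analysis stages.

Each experiment wires the synthetic-data generator into one analysis stage
and returns the summary quantities of interest: replicate reproducibility,
length-dependent DE power under multi-read vs tag counting, the
randomized-length correlation artifact, Bonferroni family-wise error under
the null, fragmentation length bias, spike linearity, and annotation-free
bin detection of an unannotated expressed region.

Every experiment takes one master seed; internal channel seeds derive from
it via the SeedSequence counter scheme, so results are reproducible.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import genomic_bins as gb
from .models import CountTable, GatingRule
from .differential_expression import DEConfig, de_t_test, length_binned_de
from .normalization import (
    gate,
    length_artifact_experiment,
    rpm_normalize,
    spearman,
)
from .protocol_effects import fragmentation_bias, spike_linearity
from .synthetic_data import (
    DEFAULT_SPIKES,
    ProtocolConfig,
    SyntheticTranscriptome,
    TranscriptomeParams,
    channel_seed,
    generate_transcriptome,
    inject_fold_changes,
    simulate_channel,
    simulate_replicates,
    simulate_spikes,
)

#: transcriptome preset for expression-only experiments: no ribo/mito mass,
#: all transcripts coding and polyadenylated (so DGE sees the same universe),
#: moderate abundance spread
_EXPRESSION_PARAMS = TranscriptomeParams(
    n_ribo=0, n_mito=0, ribo_weight_share=0.0, mito_weight_share=0.0,
    frac_coding=1.0, frac_noncoding_polya_minus=0.0, frac_histone=0.0,
    frac_noncoding_polya_plus=0.0,
)


def replicate_correlation_experiment(
    seed: int,
    n: int = 5000,
    depth: int = 1_000_000,
    protocol: str = "polya1",
    gate_rpm: float = 5.0,
) -> dict:
    """Gated Spearman between two independently sampled replicate channels."""
    tx = generate_transcriptome(n, channel_seed(seed, 101))
    table = simulate_replicates(tx, ProtocolConfig(protocol=protocol, depth=depth,
                                                   seed=channel_seed(seed, 102)), k=2)
    matrix = rpm_normalize(table)
    a, b = matrix.group_ids
    ids = gate(matrix, GatingRule(gate_rpm, "any"), [a, b])
    r = spearman(matrix.values.loc[ids, a], matrix.values.loc[ids, b])
    return {"spearman": r, "n_gated": len(ids), "depth": depth}


def _concat_channels(tables) -> CountTable:
    counts = pd.concat([t.counts for t in tables], axis=1)
    totals = pd.concat([t.category_totals for t in tables], axis=0)
    return CountTable(counts, totals, tables[0].transcript_categories)


def length_power_experiment(
    seed: int,
    protocol: str = "total",
    repeats: int = 10,
    n: int = 4400,
    depth: int = 1_000_000,
    fold: float = 2.0,
    fraction: float = 0.2,
    channels_per_condition: int = 4,
    sigma_log10_abundance: float = 0.5,
    config: DEConfig | None = None,
) -> dict:
    """Length dependence of DE power under one sampling model.

    Per repeat: fresh transcriptome (abundance independent of length), fold
    changes injected into a fraction of transcripts, 4-vs-4 channels
    simulated, per-channel RPM tested transcript-wise, and fraction
    significant summarized per 400-transcript length bin. The trend
    statistic is the Spearman correlation between bin index and fraction
    significant pooled over repeats (pooling keeps the statistic honest
    when the true trend is flat: its null sd shrinks as 1/sqrt(bins x
    repeats), whereas a single repeat's Spearman over 10 noisy bin
    fractions is scale-free noise).
    """
    if config is None:
        config = DEConfig()
    params = replace(_EXPRESSION_PARAMS,
                     sigma_log10_abundance=sigma_log10_abundance)
    points = []
    curves = []
    for r in range(repeats):
        tx = generate_transcriptome(n, channel_seed(seed, 1000 + r), params)
        tx2, labels = inject_fold_changes(tx, fraction, fold,
                                          channel_seed(seed, 2000 + r))
        cfg = ProtocolConfig(protocol=protocol, depth=depth,
                             seed=channel_seed(seed, 3000 + r))
        cfg2 = replace(cfg, seed=channel_seed(seed, 4000 + r))
        ta = simulate_replicates(tx, cfg, channels_per_condition, label="condA")
        tb = simulate_replicates(tx2, cfg2, channels_per_condition, label="condB")
        table = _concat_channels([ta, tb])
        matrix = rpm_normalize(table)
        res = de_t_test(matrix, ta.channel_ids, tb.channel_ids, config)
        bins = length_binned_de(res, tx.lengths(), config)
        full = bins[bins["n"] == config.length_bin_size]
        curves.append(full)
        for _, row in full.iterrows():
            points.append((row["bin"], row["fraction_significant"]))
    pts = np.array(points)
    trend = spearman(pts[:, 0], pts[:, 1])
    mean_curve = (
        pd.concat(curves).groupby("bin")["fraction_significant"].mean()
    )
    return {
        "trend_spearman": trend,
        "n_points": len(pts),
        "mean_fraction_by_bin": mean_curve,
        "repeats": repeats,
    }


def length_artifact_direction_experiment(
    seed: int,
    n: int = 3000,
    depth: int = 1_000_000,
    channels: int = 4,
    repeats: int = 10,
) -> dict:
    """Does permuted-length normalization inflate inter-channel correlation?

    Channels are independent draws from one transcriptome whose lengths and
    abundances are independent; dividing all channels by one shared
    permuted length vector adds a common component, so any correlation gain
    is purely arithmetic. The effect needs well-measured ranks: at depths
    where many gated transcripts carry only a handful of reads, rank noise
    from near-zero counts swamps the shared-divisor gain and the direction
    can invert, so the experiment runs at full (1e6) depth.
    """
    tx = generate_transcriptome(n, channel_seed(seed, 11), _EXPRESSION_PARAMS)
    table = simulate_replicates(
        tx, ProtocolConfig(protocol="total", depth=depth, seed=channel_seed(seed, 12)),
        k=channels,
    )
    report = length_artifact_experiment(table, tx.lengths(),
                                        seed=channel_seed(seed, 13), repeats=repeats)
    return report


def null_fwer_experiment(
    seed: int,
    repeats: int = 200,
    n: int = 2200,
    depth: int = 1_000_000,
    channels_per_condition: int = 4,
    config: DEConfig | None = None,
) -> dict:
    """Family-wise error of the threshold-division correction under the null.

    4-vs-4 channels drawn from one unchanged transcriptome per repeat; the
    family-wise error is the fraction of repeats with at least one
    significant call. Also returns the Kolmogorov-Smirnov distance of the
    first repeat's p-values from U(0,1).
    """
    from scipy import stats

    if config is None:
        config = DEConfig()
    tx = generate_transcriptome(n, channel_seed(seed, 21), _EXPRESSION_PARAMS)
    cfg = ProtocolConfig(protocol="total", depth=depth)
    any_hit = 0
    ks_stat = None
    for r in range(repeats):
        ta = simulate_replicates(tx, replace(cfg, seed=channel_seed(seed, 5000 + 2 * r)),
                                 channels_per_condition, label="condA")
        tb = simulate_replicates(tx, replace(cfg, seed=channel_seed(seed, 5001 + 2 * r)),
                                 channels_per_condition, label="condB")
        matrix = rpm_normalize(_concat_channels([ta, tb]))
        res = de_t_test(matrix, ta.channel_ids, tb.channel_ids, config)
        if res.n_significant > 0:
            any_hit += 1
        if r == 0:
            ks_stat = float(stats.kstest(res.table["p"], "uniform").statistic)
    return {
        "fwer": any_hit / repeats,
        "repeats": repeats,
        "ks_uniform": ks_stat,
        "alpha": config.alpha,
    }


def fragmentation_experiment(
    seed: int,
    n: int = 3000,
    depth: int = 1_000_000,
    frag_scale: float = 400.0,
    gate_rpm: float = 100.0,
) -> dict:
    """Unfragmented vs fragmented channel pair from one transcriptome.

    With retention r(L) = L/(L+scale) the expected ratio of unfragmented to
    fragmented RPM is C (L+scale)/L, C the weight-averaged retention, so
    short transcripts sit above 1 and long ones just below; the report
    checks the simulated medians against that closed form.
    """
    tx = generate_transcriptome(n, channel_seed(seed, 31), _EXPRESSION_PARAMS)
    base = ProtocolConfig(protocol="total", depth=depth, frag_scale=frag_scale)
    unfrag = simulate_channel(tx, replace(base, seed=channel_seed(seed, 32)),
                              channel_id="unfrag")
    frag = simulate_channel(tx, replace(base, fragmented=True,
                                        seed=channel_seed(seed, 33)),
                            channel_id="frag")
    matrix = rpm_normalize(_concat_channels([unfrag, frag]))
    report = fragmentation_bias(matrix.values["unfrag"], matrix.values["frag"],
                                tx.lengths(), gate_rpm=gate_rpm)
    L = tx.lengths().loc[report.ratios.index]
    w = tx.table["abundance"] * tx.table["length"]
    retention = tx.table["length"] / (tx.table["length"] + frag_scale)
    c_expected = float((w * retention).sum() / w.sum())
    return {
        "median_ratio_short": float(report.ratios[L < 1000].median()),
        "median_ratio_long": float(report.ratios[L > 2000].median()),
        "n_short": int((L < 1000).sum()),
        "n_long": int((L > 2000).sum()),
        "spearman_vs_log_length": report.spearman_vs_log_length,
        "expected_mean_retention": c_expected,
        "report": report,
    }


def spike_linearity_experiment(
    seed: int,
    repeats: int = 100,
    depth: int = 100_000,
) -> dict:
    """Fraction of seeded repeats in which the length-adjusted spike
    abundances rank exactly like the known concentrations (Spearman >= 0.99
    over seven spikes requires a perfect ranking)."""
    hits = 0
    last = None
    for r in range(repeats):
        counts = simulate_spikes(DEFAULT_SPIKES, depth, channel_seed(seed, 6000 + r))
        rep = spike_linearity(counts, DEFAULT_SPIKES, library_total=depth)
        last = rep
        if rep.spearman >= 0.99:
            hits += 1
    return {"n_success": hits, "repeats": repeats, "last_report": last}


def _vlinc_transcriptome(seed: int, n: int, vlinc_length: int,
                         vlinc_weight_share: float) -> SyntheticTranscriptome:
    tx = generate_transcriptome(n, seed, _EXPRESSION_PARAMS)
    chrom = "chrV"
    start = 1000
    exons = dict(tx.exons)
    exons["vlinc"] = [(start, start + vlinc_length)]
    w_total = float((tx.table["abundance"] * tx.table["length"]).sum())
    m_v = vlinc_weight_share / (1 - vlinc_weight_share) * w_total / vlinc_length
    row = pd.DataFrame(
        {
            "length": [vlinc_length],
            "abundance": [m_v],
            "category": ["other"],
            "biotype": ["noncoding"],
            "is_polyadenylated": [False],
            "chrom": [chrom],
            "strand": ["+"],
        },
        index=pd.Index(["vlinc"], name="transcript_id"),
    )
    table = pd.concat([tx.table, row])
    sizes = dict(tx.chrom_sizes)
    sizes[chrom] = start + vlinc_length + 1000
    return SyntheticTranscriptome(table=table, exons=exons, chrom_sizes=sizes,
                                  params=tx.params)


def genomic_bin_experiment(
    seed: int,
    n: int = 300,
    depth: int = 200_000,
    width: int = 100,
    vlinc_length: int = 30_000,
    vlinc_weight_share: float = 0.1,
    fold: float = 6.0,
) -> dict:
    """Annotation-free bin comparison on simulated reads.

    Matched scenario: two conditions differing only by injected transcript
    fold changes, annotation equal to the simulator truth — every
    differential bin must be exonic. Unannotated-region scenario: one
    condition additionally expresses a long transcript absent from the
    annotation — its span shows up as a contiguous run of intergenic
    differential bins.
    """
    tx_a = _vlinc_transcriptome(channel_seed(seed, 41), n, vlinc_length,
                                vlinc_weight_share)
    # condition B: same transcriptome, vlinc silenced, fold changes elsewhere
    other_ids = [t for t in tx_a.table.index if t != "vlinc"]
    tx_b, _ = inject_fold_changes(tx_a, 0.1, fold, channel_seed(seed, 42),
                                  eligible=other_ids)
    tx_b.table.loc["vlinc", "abundance"] /= 1e6

    cfg = ProtocolConfig(protocol="total", depth=depth)
    _, reads_a = simulate_channel(tx_a, replace(cfg, seed=channel_seed(seed, 43)),
                                  channel_id="condA", return_reads=True)
    _, reads_b = simulate_channel(tx_b, replace(cfg, seed=channel_seed(seed, 44)),
                                  channel_id="condB", return_reads=True)
    reads_a.channel.channel_id = "condA"
    reads_b.channel.channel_id = "condB"

    track = gb.make_bins(tx_a.chrom_sizes, width)
    track = gb.count_bins(track, [reads_a, reads_b])
    track = gb.bin_rpm(track, {"condA": depth, "condB": depth})

    annotation = tx_a.to_annotation(exclude=["vlinc"])
    track = gb.classify_bins(track, annotation)
    diff = gb.differential_bins(track, "condA", "condB")
    both = pd.concat([diff["a_higher"], diff["b_higher"]])
    n_intronic = int((both["bin_class"] == "intronic").sum())
    intergenic = diff["a_higher"][diff["a_higher"]["bin_class"] == "intergenic"]
    vlinc_bins = intergenic[intergenic["chrom"] == "chrV"].sort_values("start")
    # longest contiguous run of intergenic A-higher bins on the vlinc chromosome
    run = best = 0
    prev_end = None
    for _, r in vlinc_bins.iterrows():
        if prev_end is not None and r["start"] == prev_end:
            run += 1
        else:
            run = 1
        best = max(best, run)
        prev_end = r["end"]
    n_intergenic_off_vlinc = int((intergenic["chrom"] != "chrV").sum()) + int(
        (diff["b_higher"]["bin_class"] == "intergenic").sum()
    )

    # matched scenario: same two conditions but with the vlinc absent from
    # both, annotation matching the truth exactly
    tx_m = generate_transcriptome(n, channel_seed(seed, 41), _EXPRESSION_PARAMS)
    tx_m2, _ = inject_fold_changes(tx_m, 0.1, fold, channel_seed(seed, 45))
    _, r_a = simulate_channel(tx_m, replace(cfg, seed=channel_seed(seed, 46)),
                              channel_id="mA", return_reads=True)
    _, r_b = simulate_channel(tx_m2, replace(cfg, seed=channel_seed(seed, 47)),
                              channel_id="mB", return_reads=True)
    r_a.channel.channel_id = "mA"
    r_b.channel.channel_id = "mB"
    track_m = gb.make_bins(tx_m.chrom_sizes, width)
    track_m = gb.count_bins(track_m, [r_a, r_b])
    track_m = gb.bin_rpm(track_m, {"mA": depth, "mB": depth})
    track_m = gb.classify_bins(track_m, tx_m.to_annotation())
    diff_m = gb.differential_bins(track_m, "mA", "mB")
    both_m = pd.concat([diff_m["a_higher"], diff_m["b_higher"]])
    n_nonexonic_matched = int((both_m["bin_class"] != "exonic").sum())
    n_diff_matched = len(both_m)

    return {
        "vlinc_intergenic_run": best,
        "vlinc_expected_bins": vlinc_length // width,
        "n_intronic_diff": n_intronic,
        "n_intergenic_diff_off_vlinc": n_intergenic_off_vlinc,
        "matched_nonexonic_diff_bins": n_nonexonic_matched,
        "matched_total_diff_bins": n_diff_matched,
    }
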