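import numpy as np
import pandas as pd
import pytest

from protoseq import synthetic_data as sd
from protoseq.models import ValidationError
from protoseq.transcript_io import assign_reads
from protoseq import experiments as ex


@pytest.fixture(scope="module")
def tx():
    return sd.generate_transcriptome(1000, 42)


class TestGenerateTranscriptome:
    def test_same_seed_identical(self, tx):
        again = sd.generate_transcriptome(1000, 42)
        pd.testing.assert_frame_equal(tx.table, again.table)
        assert tx.exons == again.exons
        assert tx.chrom_sizes == again.chrom_sizes

    def test_class_count_fractions(self, tx):
        t = tx.table
        assert (t["category"] == "ribosomal").sum() == 8
        assert (t["category"] == "mitochondrial").sum() == 15
        other = t[t["category"] == "other"]
        assert (other["biotype"] == "coding").sum() == round(0.70 * len(other))
        assert (other["biotype"] == "histone").sum() == round(0.05 * len(other))
        assert (other["biotype"] == "noncoding").sum() == round(0.25 * len(other))

    def test_polya_flags_by_class(self, tx):
        t = tx.table
        assert not t.loc[t["category"] == "ribosomal", "is_polyadenylated"].any()
        assert t.loc[t["category"] == "mitochondrial", "is_polyadenylated"].all()
        assert not t.loc[t["biotype"] == "histone", "is_polyadenylated"].any()

    def test_total_rna_ribo_weight_share(self, tx):
        shares = tx.weight_shares()
        assert 0.80 <= shares["ribosomal"] <= 0.90

    def test_abundance_spans_four_decades(self, tx):
        m = tx.table.loc[tx.table["category"] == "other", "abundance"]
        assert np.log10(m.max() / m.min()) >= 4

    def test_genome_placement_disjoint_with_gaps(self, tx):
        for chrom, size in tx.chrom_sizes.items():
            spans = sorted(
                (min(a for a, _ in tx.exons[t]), max(b for _, b in tx.exons[t]))
                for t in tx.table.index[tx.table["chrom"] == chrom]
            )
            for (_, e0), (s1, _) in zip(spans, spans[1:]):
                assert s1 - e0 >= 1000
            assert spans[-1][1] <= size

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValidationError):
            sd.TranscriptomeParams(frac_coding=0.9)  # fractions no longer sum to 1


class TestSamplingWeights:
    def test_rnaseq_weight_proportional_to_length(self, tx):
        two = tx.table[tx.table["category"] == "other"].index[:2]
        t2 = tx.table.loc[two].copy()
        t2["abundance"] = 1.0
        t2["length"] = [1000, 2000]
        mini = sd.SyntheticTranscriptome(t2, {k: tx.exons[k] for k in two},
                                         tx.chrom_sizes, tx.params)
        w = sd.sampling_weights(mini, sd.ProtocolConfig("total"))
        assert w[1] / w[0] == pytest.approx(2.0)
        w_dge = sd.sampling_weights(mini, sd.ProtocolConfig("dge"))
        assert w_dge[1] / w_dge[0] == pytest.approx(1.0)

    def test_dge_ignores_nonpolyadenylated(self, tx):
        w = sd.sampling_weights(tx, sd.ProtocolConfig("dge"))
        polya = tx.table["is_polyadenylated"].to_numpy()
        assert (w[~polya] == 0).all()
        assert (w[polya] > 0).all()

    def test_double_selection_squares_carryover(self, tx):
        cfg1 = sd.ProtocolConfig("polya1", polya_carryover=0.1, capture=1.0)
        cfg2 = sd.ProtocolConfig("polya2", polya_carryover=0.1, capture=1.0)
        w1 = sd.sampling_weights(tx, cfg1)
        w2 = sd.sampling_weights(tx, cfg2)
        minus = ~tx.table["is_polyadenylated"].to_numpy()
        ratio = w2[minus] / w1[minus]
        assert np.allclose(ratio, 0.1)

    def test_fragmentation_retention(self, tx):
        cfg = sd.ProtocolConfig("total", fragmented=True, frag_scale=400)
        w = sd.sampling_weights(tx, cfg)
        w0 = sd.sampling_weights(tx, sd.ProtocolConfig("total"))
        L = tx.table["length"].to_numpy(dtype=float)
        assert np.allclose(w, w0 * L / (L + 400))

    def test_protocol_percent_ribo_ordering(self, tx):
        pct = {}
        mito_pct = {}
        for proto in ("total", "ribominus", "polya1", "polya2"):
            shares = tx.weight_shares(sd.ProtocolConfig(proto))
            pct[proto] = shares.get("ribosomal", 0)
            mito_pct[proto] = shares.get("mitochondrial", 0)
        assert pct["total"] > pct["ribominus"] > pct["polya1"] > pct["polya2"]
        assert (mito_pct["total"] < mito_pct["ribominus"]
                < mito_pct["polya1"] < mito_pct["polya2"])

    def test_ribominus_residual_in_observed_band(self, tx):
        share = tx.weight_shares(sd.ProtocolConfig("ribominus"))["ribosomal"]
        assert 0.47 <= share <= 0.77


class TestSimulateChannel:
    def test_exact_depth_and_determinism(self, tx):
        cfg = sd.ProtocolConfig("total", depth=50_000, seed=5)
        t1 = sd.simulate_channel(tx, cfg)
        t2 = sd.simulate_channel(tx, cfg)
        assert t1.counts.iloc[:, 0].sum() == 50_000
        pd.testing.assert_frame_equal(t1.counts, t2.counts)
        tot = t1.category_totals.iloc[0]
        assert (tot["ribosomal_reads"] + tot["mitochondrial_reads"]
                + tot["other_reads"]) == tot["total_reads"] == 50_000

    def test_counts_near_expectation(self):
        # two transcripts, weights 1:3 at depth 1e6
        params = sd.TranscriptomeParams(
            n_ribo=0, n_mito=0, ribo_weight_share=0, mito_weight_share=0,
            frac_coding=1.0, frac_noncoding_polya_minus=0.0,
            frac_histone=0.0, frac_noncoding_polya_plus=0.0)
        mini = sd.generate_transcriptome(10, 1, params)
        t = mini.table.copy()
        t["abundance"] = 0.0
        t.loc[t.index[0], ["abundance", "length"]] = [1.0, 1000]
        t.loc[t.index[1], ["abundance", "length"]] = [3.0, 1000]
        t = t.iloc[:2]
        mini2 = sd.SyntheticTranscriptome(
            t, {k: mini.exons[k] for k in t.index}, mini.chrom_sizes, params)
        depth = 1_000_000
        table = sd.simulate_channel(mini2, sd.ProtocolConfig("total", depth=depth, seed=9))
        c = table.counts.iloc[:, 0]
        se = np.sqrt(depth * 0.25 * 0.75)
        assert abs(c.iloc[0] - 250_000) < 4 * se
        assert abs(c.iloc[1] - 750_000) < 4 * se

    def test_category_shares_within_binomial_se(self, tx):
        depth = 1_000_000
        table = sd.simulate_channel(tx, sd.ProtocolConfig("total", depth=depth, seed=6))
        shares = tx.weight_shares()
        tot = table.category_totals.iloc[0]
        for cat, col in [("ribosomal", "ribosomal_reads"),
                         ("mitochondrial", "mitochondrial_reads"),
                         ("other", "other_reads")]:
            p = shares[cat]
            se = np.sqrt(depth * p * (1 - p))
            assert abs(tot[col] - depth * p) < 4 * se

    def test_zero_weight_rejected(self, tx):
        t = tx.table.copy()
        t["abundance"] = 0.0
        dead = sd.SyntheticTranscriptome(t, tx.exons, tx.chrom_sizes, tx.params)
        with pytest.raises(ValidationError):
            sd.simulate_channel(dead, sd.ProtocolConfig("total", depth=10, seed=0))

    def test_read_positions_land_in_own_exons(self, tx):
        cfg = sd.ProtocolConfig("total", depth=20_000, seed=7)
        table, reads = sd.simulate_channel(tx, cfg, return_reads=True)
        assert len(reads) == 20_000
        # recounting the emitted reads reproduces the counts exactly
        models = tx.to_annotation()
        recounted = assign_reads(reads, models)
        got = recounted.counts.iloc[:, 0]
        want = table.counts.iloc[:, 0]
        assert got.sum() == want.sum()
        pd.testing.assert_series_equal(got.sort_index(), want.sort_index(),
                                       check_names=False)

    def test_dge_reads_cluster_at_five_prime(self, tx):
        cfg = sd.ProtocolConfig("dge", depth=20_000, seed=8, rt_stop_rate=1 / 4000)
        table, reads = sd.simulate_channel(tx, cfg, return_reads=True)
        # most reads from short polyA+ transcripts should sit exactly at the
        # annotated 5' end
        models = {m.id: m for m in tx.to_annotation()}
        at_five_prime = 0
        total = 0
        polya_short = tx.table[(tx.table["is_polyadenylated"])
                               & (tx.table["length"] < 2000)].index
        starts = {}
        for tid in polya_short:
            m = models[tid]
            starts[(m.chrom, m.exons[0][0] if m.strand == "+"
                    else m.exons[-1][1] - 1)] = tid
        for chrom, pos in zip(reads.chroms, reads.positions):
            if (chrom, pos) in starts:
                at_five_prime += 1
        n_short_reads = table.counts.loc[polya_short].iloc[:, 0].sum()
        # P(full extension) = (1 - 1/4000)^L, >= 0.6 on average below 2 kb
        assert at_five_prime / n_short_reads > 0.6

    def test_depth_zero_rejected(self):
        with pytest.raises(ValidationError):
            sd.ProtocolConfig("total", depth=0)


class TestSimulateReplicates:
    def test_distinct_channels_and_determinism(self, tx):
        cfg = sd.ProtocolConfig("total", depth=10_000, seed=12)
        t1 = sd.simulate_replicates(tx, cfg, 3)
        t2 = sd.simulate_replicates(tx, cfg, 3)
        assert len(set(t1.channel_ids)) == 3
        pd.testing.assert_frame_equal(t1.counts, t2.counts)
        assert not t1.counts.iloc[:, 0].equals(t1.counts.iloc[:, 1])

    def test_k_below_two_rejected(self, tx):
        with pytest.raises(ValidationError):
            sd.simulate_replicates(tx, sd.ProtocolConfig("total", depth=10, seed=0), 1)


class TestInjectFoldChanges:
    def test_label_count_and_recovery(self, tx):
        tx2, labels = sd.inject_fold_changes(tx, 0.2, 2.0, seed=13)
        assert len(labels) == round(0.2 * tx.n)
        changed = tx.table["abundance"] != tx2.table["abundance"]
        assert set(tx2.table.index[changed]) == set(labels.index)
        ups = labels.index[labels["direction"] == "up"]
        ratio = tx2.table.loc[ups, "abundance"] / tx.table.loc[ups, "abundance"]
        assert np.allclose(ratio, 2.0)

    def test_fold_one_rejected(self, tx):
        with pytest.raises(ValidationError):
            sd.inject_fold_changes(tx, 0.2, 1.0, seed=0)


class TestSimulateSpikes:
    def test_expected_proportions(self):
        truth = pd.DataFrame({"id": ["a", "b"], "length": [1000, 2000],
                              "concentration": [1.0, 1.0]})
        counts = sd.simulate_spikes(truth, 90_000, seed=14)
        assert counts.sum() == 90_000
        assert abs(counts["b"] / counts["a"] - 2.0) < 0.1
        flat = sd.simulate_spikes(truth, 90_000, seed=14, length_proportional=False)
        assert abs(flat["b"] / flat["a"] - 1.0) < 0.05

    def test_default_truth_set_shape(self):
        t = sd.DEFAULT_SPIKES
        assert len(t) == 7
        assert (t["length"] == 325).any()
        span = t["concentration"].max() / t["concentration"].min()
        assert span >= 1000
        # the short spike sits at the lowest concentration
        assert t.loc[t["length"].idxmin(), "concentration"] == t["concentration"].min()

    def test_deterministic(self):
        c1 = sd.simulate_spikes(sd.DEFAULT_SPIKES, 1000, seed=15)
        c2 = sd.simulate_spikes(sd.DEFAULT_SPIKES, 1000, seed=15)
        pd.testing.assert_series_equal(c1, c2)
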