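import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from protoseq import normalization as norm
from protoseq.models import ExpressionMatrix, GatingRule, ValidationError
from protoseq import experiments as ex
from conftest import make_count_table


class TestCombineChannels:
    def test_counts_add(self):
        t = make_count_table({"A": {"ch1": 2, "ch2": 3}})
        g = norm.combine_channels(t, {"ch1": "g", "ch2": "g"})
        assert g.counts.loc["A", "g"] == 5

    def test_identity_grouping(self):
        t = make_count_table({"A": {"ch1": 2, "ch2": 3}, "B": {"ch1": 1, "ch2": 0}})
        g = norm.combine_channels(t, {"ch1": "ch1", "ch2": "ch2"})
        assert g.counts.equals(t.counts)
        assert g.category_totals.equals(t.category_totals)

    def test_unmapped_channel_rejected(self):
        t = make_count_table({"A": {"ch1": 2, "ch2": 3}})
        with pytest.raises(ValidationError):
            norm.combine_channels(t, {"ch1": "g"})

    def test_combine_then_normalize_commutes(self):
        # summing read counts before normalization equals normalizing the
        # pre-summed table
        rng = np.random.default_rng(0)
        counts = {f"t{i}": {f"ch{j}": int(rng.integers(0, 50)) for j in range(4)}
                  for i in range(30)}
        t = make_count_table(counts, ribo={f"ch{j}": 10 for j in range(4)})
        grouping = {"ch0": "g1", "ch1": "g1", "ch2": "g2", "ch3": "g2"}
        via_group = norm.rpm_normalize(norm.combine_channels(t, grouping))
        presummed = make_count_table(
            {tid: {"g1": row["ch0"] + row["ch1"], "g2": row["ch2"] + row["ch3"]}
             for tid, row in pd.DataFrame(counts).T.iterrows()},
            ribo={"g1": 20, "g2": 20},
        )
        direct = norm.rpm_normalize(presummed)
        pd.testing.assert_frame_equal(via_group.values, direct.values)


class TestRpmNormalize:
    def test_forced_arithmetic(self):
        t = make_count_table({"A": {"g": 2}, "B": {"g": 3}}, ribo=5)
        m = norm.rpm_normalize(t)
        assert m.values.loc["A", "g"] == 400_000
        assert m.values.loc["B", "g"] == 600_000
        assert "A" in m.values.index and len(m.values) == 2

    def test_zero_denominator_names_group(self):
        t = make_count_table({"A": {"g1": 0, "g2": 1}}, ribo=5)
        with pytest.raises(ValidationError, match="g1"):
            norm.rpm_normalize(t)

    def test_ribo_mito_rows_excluded(self):
        t = make_count_table(
            {"A": {"g": 2}, "R": {"g": 7}, "M": {"g": 1}},
            categories={"R": "ribosomal", "M": "mitochondrial"},
        )
        m = norm.rpm_normalize(t)
        assert list(m.values.index) == ["A"]
        assert m.values.loc["A", "g"] == 1_000_000

    def test_conservation_on_random_fixture(self):
        rng = np.random.default_rng(1)
        counts = {f"t{i}": {f"g{j}": int(rng.integers(0, 100)) for j in range(3)}
                  for i in range(50)}
        t = make_count_table(counts, ribo=17, mito=3)
        m = norm.rpm_normalize(t)
        np.testing.assert_allclose(m.values.sum(axis=0), 1_000_000, rtol=1e-6)

    def test_unassigned_reads_shrink_column_sum(self):
        t = make_count_table({"A": {"g": 3}}, unassigned=1)
        m = norm.rpm_normalize(t)
        assert m.values.loc["A", "g"] == pytest.approx(750_000)


class TestLengthNormalize:
    def test_rpkm_arithmetic(self):
        m = ExpressionMatrix(pd.DataFrame({"g": [10.0, 10.0]}, index=["a", "b"]),
                             "RPM", pd.Series({"g": 1e6}))
        lengths = pd.Series({"a": 1000.0, "b": 500.0})
        out = norm.length_normalize(m, lengths)
        assert out.values.loc["a", "g"] == 10
        assert out.values.loc["b", "g"] == 20
        assert out.mode == "RPKM"

    def test_missing_length_lists_ids(self):
        m = ExpressionMatrix(pd.DataFrame({"g": [1.0]}, index=["a"]),
                             "RPM", pd.Series({"g": 1e6}))
        with pytest.raises(ValidationError, match="a"):
            norm.length_normalize(m, pd.Series(dtype=float))

    def test_permuted_identity_when_single_length(self):
        # all lengths equal: every permutation is the identity
        m = ExpressionMatrix(pd.DataFrame({"g": [4.0, 8.0]}, index=["a", "b"]),
                             "RPM", pd.Series({"g": 1e6}))
        lengths = pd.Series({"a": 2000.0, "b": 2000.0})
        true = norm.length_normalize(m, lengths, "true")
        perm = norm.length_normalize(m, lengths, "permuted", seed=5)
        pd.testing.assert_frame_equal(true.values, perm.values)

    def test_permuted_is_seed_reproducible(self):
        rng = np.random.default_rng(2)
        ids = [f"t{i}" for i in range(20)]
        m = ExpressionMatrix(pd.DataFrame({"g": rng.random(20) * 100}, index=ids),
                             "RPM", pd.Series({"g": 1e6}))
        lengths = pd.Series(rng.integers(200, 5000, 20).astype(float), index=ids)
        a = norm.length_normalize(m, lengths, "permuted", seed=11)
        b = norm.length_normalize(m, lengths, "permuted", seed=11)
        pd.testing.assert_frame_equal(a.values, b.values)


class TestGate:
    @pytest.mark.parametrize("values,expected", [
        ((4.9, 5.0), False),   # strictly greater than 5
        ((6.0, 0.0), True),
        ((5.0001, 0.0), True),
    ])
    def test_strict_threshold_any_scope(self, values, expected):
        m = ExpressionMatrix(
            pd.DataFrame({"g1": [values[0]], "g2": [values[1]]}, index=["a"]),
            "RPM", pd.Series({"g1": 1e6, "g2": 1e6}),
        )
        ids = norm.gate(m, GatingRule(5, "any"), ["g1", "g2"])
        assert ("a" in ids) is expected

    def test_each_scope(self):
        m = ExpressionMatrix(
            pd.DataFrame({"g1": [6.0, 6.0], "g2": [4.0, 7.0]}, index=["a", "b"]),
            "RPM", pd.Series({"g1": 1e6, "g2": 1e6}),
        )
        assert norm.gate(m, GatingRule(5, "each")) == ["b"]

    def test_empty_group_set_rejected(self):
        m = ExpressionMatrix(pd.DataFrame({"g": [1.0]}, index=["a"]),
                             "RPM", pd.Series({"g": 1e6}))
        with pytest.raises(ValidationError):
            norm.gate(m, GatingRule(5, "any"), [])

    def test_matches_row_scan_oracle(self):
        rng = np.random.default_rng(3)
        vals = pd.DataFrame(rng.random((40, 3)) * 20,
                            index=[f"t{i}" for i in range(40)],
                            columns=["g1", "g2", "g3"])
        m = ExpressionMatrix(vals, "RPM", pd.Series(1e6, index=vals.columns))
        got = set(norm.gate(m, GatingRule(5, "any")))
        expected = {t for t in vals.index if any(vals.loc[t, g] > 5 for g in vals)}
        assert got == expected


class TestSpearman:
    def test_monotone(self):
        assert norm.spearman([1, 2, 3], [10, 20, 30]) == 1.0

    def test_antitone(self):
        assert norm.spearman([1, 2, 3], [3, 2, 1]) == -1.0

    def test_constant_vector_undefined(self):
        assert np.isnan(norm.spearman([1, 1, 1], [1, 2, 3]))

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            norm.spearman([1, 2, 3], [1, 2])

    def test_ties_equal_rank_pearson_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 6, 20).astype(float)  # heavy ties
        y = rng.integers(0, 6, 20).astype(float)
        expected = stats.pearsonr(stats.rankdata(x), stats.rankdata(y)).statistic
        assert norm.spearman(x, y) == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 1e6, allow_nan=False), min_size=3, max_size=30),
           st.integers(1, 5))
    def test_invariant_to_increasing_transform(self, xs, k):
        rng = np.random.default_rng(k)
        ys = list(rng.random(len(xs)))
        r1 = norm.spearman(xs, ys)
        # scaling is strictly increasing and cannot collapse distinct floats
        r2 = norm.spearman([x * 7.0 for x in xs], ys)
        if np.isnan(r1):
            assert np.isnan(r2)
        else:
            assert r1 == pytest.approx(r2, abs=1e-12)
            assert r1 == pytest.approx(norm.spearman(ys, xs), abs=1e-12)


class TestCorrelationTable:
    def test_duplicated_group_perfect(self):
        t = make_count_table({f"t{i}": {"g1": 10 + i, "g2": 10 + i} for i in range(10)})
        corr = norm.correlation_table(norm.rpm_normalize(t))
        assert corr.loc["g1", "g2"] == pytest.approx(1.0)
        assert (np.diag(corr) == 1).all()

    def test_cells_match_per_pair_oracle(self):
        rng = np.random.default_rng(5)
        t = make_count_table(
            {f"t{i}": {g: int(rng.integers(0, 200)) for g in ("g1", "g2", "g3")}
             for i in range(60)}
        )
        m = norm.rpm_normalize(t)
        corr = norm.correlation_table(m, GatingRule(5, "any"))
        for a, b in [("g1", "g2"), ("g1", "g3"), ("g2", "g3")]:
            ids = norm.gate(m, GatingRule(5, "any"), [a, b])
            expected = norm.spearman(m.values.loc[ids, a], m.values.loc[ids, b])
            assert corr.loc[a, b] == pytest.approx(expected)
            assert corr.loc[b, a] == corr.loc[a, b]

    def test_too_few_survivors_undefined(self):
        t = make_count_table({"t0": {"g1": 1, "g2": 1}}, unassigned=100)
        with pytest.raises(ValidationError):
            # only one transcript: matrix too small to correlate meaningfully
            norm.correlation_table(
                ExpressionMatrix(pd.DataFrame({"g1": [1.0]}, index=["t0"]),
                                 "RPM", pd.Series({"g1": 1e6})))
        m = norm.rpm_normalize(t)
        corr = norm.correlation_table(m, GatingRule(5, "any"))
        assert np.isnan(corr.loc["g1", "g2"])


class TestSummarizeCategories:
    # printed channel-summary rows: counts in, one-decimal percentages out
    @pytest.mark.parametrize("other,mito,ribo,expect", [
        (30_456_413, 6_600_803, 5_518_076, (71.5, 15.5, 13.0)),
        (4_673_697, 5_964_424, 81_889_062, (5.1, 6.4, 88.5)),
        (1, 2, 1, (25.0, 50.0, 25.0)),
    ])
    def test_percentages(self, other, mito, ribo, expect):
        t = make_count_table({"t": {"ch": 0}}, ribo=ribo, mito=mito, unassigned=other)
        s = norm.summarize_categories(t)
        row = s.loc["ch"]
        assert (row["pct_non_ribo_mito"], row["pct_mito"], row["pct_ribo"]) == expect
        assert row["total_reads"] == other + mito + ribo

    def test_percentages_sum_near_100(self):
        t = make_count_table({"t": {"ch": 0}}, ribo=7, mito=11, unassigned=13)
        row = norm.summarize_categories(t).loc["ch"]
        total_pct = row[["pct_non_ribo_mito", "pct_mito", "pct_ribo"]].sum()
        assert abs(total_pct - 100) <= 0.15

    def test_zero_total_rejected(self):
        t = make_count_table({"t": {"ch": 0}})
        with pytest.raises(ValidationError):
            norm.summarize_categories(t)


class TestLengthArtifact:
    def test_identical_groups_all_one(self):
        t = make_count_table({f"t{i}": {"g1": 20 + i, "g2": 20 + i}
                              for i in range(20)})
        lengths = pd.Series({f"t{i}": 1000.0 + 37 * i for i in range(20)})
        rep = norm.length_artifact_experiment(t, lengths, seed=1, repeats=2)
        assert rep["rpm"] == rep["rpkm"] == rep["permuted"] == pytest.approx(1.0)

    def test_constant_lengths_leave_rpkm_equal_rpm(self):
        rng = np.random.default_rng(6)
        t = make_count_table({f"t{i}": {"g1": int(rng.integers(5, 500)),
                                        "g2": int(rng.integers(5, 500))}
                              for i in range(40)})
        lengths = pd.Series(1500.0, index=[f"t{i}" for i in range(40)])
        rep = norm.length_artifact_experiment(t, lengths, seed=2, repeats=1)
        assert rep["rpkm"] == pytest.approx(rep["rpm"], abs=1e-12)
        assert rep["permuted"] == pytest.approx(rep["rpm"], abs=1e-12)

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(7)
        t = make_count_table({f"t{i}": {"g1": int(rng.integers(0, 500)),
                                        "g2": int(rng.integers(0, 500))}
                              for i in range(40)})
        lengths = pd.Series(rng.integers(200, 8000, 40).astype(float),
                            index=[f"t{i}" for i in range(40)])
        r1 = norm.length_artifact_experiment(t, lengths, seed=3, repeats=1)
        r2 = norm.length_artifact_experiment(t, lengths, seed=3, repeats=1)
        assert r1 == r2

    def test_permuted_exceeds_rpm_in_simulation(self):
        # the direction of the length-correction artifact on independently
        # sampled channels from one transcriptome
        rep = ex.length_artifact_direction_experiment(seed=5, n=2000, channels=3,
                                                      repeats=5)
        assert rep["permuted"] > rep["rpm"]


class TestReplicateRegime:
    def test_replicate_channels_highly_correlated(self):
        # counting noise alone: two multinomial draws from one transcriptome
        r = ex.replicate_correlation_experiment(seed=2)
        assert r["spearman"] > 0.9
        assert r["n_gated"] > 500

    def test_correlation_rises_with_depth(self):
        lo = ex.replicate_correlation_experiment(seed=3, n=2000, depth=10_000)
        hi = ex.replicate_correlation_experiment(seed=3, n=2000, depth=1_000_000)
        assert hi["spearman"] > lo["spearman"]
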