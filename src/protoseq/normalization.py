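"""RPM/length normalization, gating, Spearman correlation tables, category
summaries, and the randomized-length correlation-artifact experiment.

Expression is Reads Per Million (RPM): counts scaled so that all
non-ribosomal/non-mitochondrial reads in a sample total one million.
RPKM (RPM x 1000 / length) exists for the spike analysis and for the
length-artifact experiment only; correlations and differential expression
use RPM.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import (
    CATEGORY_COLUMNS,
    ChannelMeta,
    CountTable,
    ExpressionMatrix,
    GatingRule,
    ValidationError,
)

NORMALIZATION_TOTAL = 1_000_000.0


def combine_channels(table: CountTable, grouping: Mapping[str, str]) -> CountTable:
    """Sum read counts of channels that map to the same group.

    Counts are summed *before* normalization (the summed table is what
    :func:`rpm_normalize` consumes), so combine-then-normalize equals
    normalizing pre-summed counts.
    """
    missing = [c for c in table.channel_ids if c not in grouping]
    if missing:
        raise ValidationError(f"channels without a group: {missing}")
    groups: dict[str, list[str]] = {}
    for ch in table.channel_ids:
        groups.setdefault(grouping[ch], []).append(ch)
    counts = pd.DataFrame(
        {g: table.counts[chs].sum(axis=1) for g, chs in groups.items()}
    )
    totals = pd.DataFrame(
        {g: table.category_totals.loc[chs, list(CATEGORY_COLUMNS)].sum(axis=0)
         for g, chs in groups.items()}
    ).T
    meta = [ChannelMeta(channel_id=g) for g in counts.columns]
    return CountTable(counts, totals, table.transcript_categories, meta)


def rpm_normalize(table: CountTable) -> ExpressionMatrix:
    """Normalize counts to RPM.

    Ribosomal and mitochondrial transcripts are dropped from the matrix and
    from the denominator; the per-group denominator is the group's total
    non-ribo/mito read count (``other_reads``), which includes reads that
    hit no annotated exon.
    """
    denom = table.category_totals["other_reads"].astype(float)
    zero = denom[denom <= 0]
    if len(zero):
        raise ValidationError(
            f"zero non-ribo/mito read total for group(s): {list(zero.index)}"
        )
    keep = table.transcript_categories == "other"
    values = table.counts.loc[keep].astype(float) * NORMALIZATION_TOTAL / denom
    return ExpressionMatrix(values=values, mode="RPM", denominators=denom)


def length_normalize(
    matrix: ExpressionMatrix,
    lengths: pd.Series,
    mode: str = "true",
    seed: int | None = None,
) -> ExpressionMatrix:
    """Divide RPM by length in kb (RPKM), or by seed-permuted lengths.

    In ``permuted`` mode one shared permutation of the true lengths is
    applied to every group (the artifact under study is a common divisor).
    """
    missing = matrix.values.index.difference(lengths.index)
    if len(missing):
        raise ValidationError(f"missing lengths for: {sorted(missing)[:10]}")
    L = lengths.reindex(matrix.values.index).astype(float)
    if (L <= 0).any():
        raise ValidationError("lengths must be positive")
    if mode == "true":
        out_mode = "RPKM"
    elif mode == "permuted":
        if seed is None:
            raise ValidationError("permuted mode requires a seed")
        rng = np.random.default_rng(seed)
        L = pd.Series(rng.permutation(L.to_numpy()), index=L.index)
        out_mode = "permuted-length"
    else:
        raise ValidationError("mode must be 'true' or 'permuted'")
    values = matrix.values.mul(1000.0 / L, axis=0)
    return ExpressionMatrix(values=values, mode=out_mode,
                            denominators=matrix.denominators)


def gate(
    matrix: ExpressionMatrix,
    rule: GatingRule,
    groups: Sequence[str] | None = None,
) -> list[str]:
    """Transcripts whose value strictly exceeds the threshold in at least
    one ('any' scope) or all ('each' scope) of the named groups."""
    if groups is None:
        groups = matrix.group_ids
    groups = list(groups)
    if not groups:
        raise ValidationError("empty group set")
    unknown = [g for g in groups if g not in matrix.values.columns]
    if unknown:
        raise ValidationError(f"unknown groups: {unknown}")
    above = matrix.values[groups] > rule.threshold
    mask = above.any(axis=1) if rule.scope == "any" else above.all(axis=1)
    return list(matrix.values.index[mask])


def spearman(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN (the explicit undefined marker) when either vector is
    constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must have equal length")
    if len(x) < 3:
        raise ValidationError("spearman requires length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def correlation_table(matrix: ExpressionMatrix, rule: GatingRule | None = None) -> pd.DataFrame:
    """Pairwise gated Spearman correlations between groups.

    The gate is recomputed for each compared pair ('any' scope over the two
    groups). Pairs with fewer than 3 surviving transcripts get NaN.
    """
    if rule is None:
        rule = GatingRule()
    groups = matrix.group_ids
    if len(groups) < 2:
        raise ValidationError("correlation_table requires >= 2 groups")
    out = pd.DataFrame(np.eye(len(groups)), index=groups, columns=groups)
    for a, b in combinations(groups, 2):
        ids = gate(matrix, GatingRule(rule.threshold, "any"), [a, b])
        if len(ids) < 3:
            r = float("nan")
        else:
            r = spearman(matrix.values.loc[ids, a], matrix.values.loc[ids, b])
        out.loc[a, b] = out.loc[b, a] = r
    return out


def summarize_categories(table: CountTable) -> pd.DataFrame:
    """Per-channel read-category accounting.

    Returns reads and percentages (one decimal) for non-ribo/mito, mito and
    ribo reads, in the style of a sequencing-summary table.
    """
    tot = table.category_totals
    if (tot["total_reads"] <= 0).any():
        raise ValidationError("channel with zero total reads")
    total = tot["total_reads"].astype(float)
    out = pd.DataFrame(
        {
            "non_ribo_mito_reads": tot["other_reads"],
            "mito_reads": tot["mitochondrial_reads"],
            "ribo_reads": tot["ribosomal_reads"],
            "total_reads": tot["total_reads"],
            "pct_non_ribo_mito": (100.0 * tot["other_reads"] / total).round(1),
            "pct_mito": (100.0 * tot["mitochondrial_reads"] / total).round(1),
            "pct_ribo": (100.0 * tot["ribosomal_reads"] / total).round(1),
        }
    )
    return out


def _mean_pairwise(values: pd.DataFrame) -> float:
    cols = list(values.columns)
    rs = [spearman(values[a], values[b]) for a, b in combinations(cols, 2)]
    return float(np.mean(rs))


def length_artifact_experiment(
    table: CountTable,
    lengths: pd.Series,
    seed: int,
    repeats: int = 10,
    rule: GatingRule | None = None,
) -> dict[str, float]:
    """Mean pairwise correlation under RPM, RPKM and permuted-length modes.

    Dividing every sample by one shared vector of *randomized* lengths adds
    a common component to all columns; if the permuted-length correlation
    exceeds the RPM correlation the apparent gain from length "correction"
    is a mathematical artifact of the shared divisor, not biology. All
    three means use the same gated transcript set ('any' scope over all
    groups); each repeat draws a fresh permutation from ``seed``.
    """
    if repeats < 1:
        raise ValidationError("repeats must be >= 1")
    if rule is None:
        rule = GatingRule()
    matrix = rpm_normalize(table)
    if len(matrix.group_ids) < 2:
        raise ValidationError("need >= 2 groups")
    ids = gate(matrix, GatingRule(rule.threshold, "any"), matrix.group_ids)
    if len(ids) < 3:
        raise ValidationError("fewer than 3 gated transcripts")
    gated = ExpressionMatrix(matrix.values.loc[ids], matrix.mode, matrix.denominators)
    rpm_r = _mean_pairwise(gated.values)
    rpkm_r = _mean_pairwise(length_normalize(gated, lengths, "true").values)
    child = np.random.SeedSequence(seed).generate_state(repeats, dtype=np.uint32)
    perm_rs = [
        _mean_pairwise(length_normalize(gated, lengths, "permuted", int(s)).values)
        for s in child
    ]
    return {
        "rpm": rpm_r,
        "rpkm": rpkm_r,
        "permuted": float(np.mean(perm_rs)),
        "n_transcripts": len(ids),
        "repeats": repeats,
    }
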