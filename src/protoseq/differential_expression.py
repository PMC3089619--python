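"""Per-transcript t-tests with threshold-division multiple-testing control,
length-binned DE summaries, expression strata and extreme-change filters.

The test is a two-sided Welch t-test on per-channel RPM; a transcript is
called significant when p < alpha / N, N being the number of gated
transcripts (equivalent to Bonferroni control of the family-wise error).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import (
    ExpressionMatrix,
    GatingRule,
    StrataCounts,
    STRATA_EDGES,
    STRATA_LABELS,
    ValidationError,
)
from .normalization import gate


@dataclass
class DEConfig:
    """Differential-expression settings.

    alpha: base two-sided significance level, threshold-divided by the
    number of tested transcripts. gate_threshold: presence gate in RPM
    (strict >, 'any' scope over the compared channels). length_bin_size:
    transcripts per length bin.
    """

    alpha: float = 0.05
    gate_threshold: float = 5.0
    length_bin_size: int = 400

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0,1)")
        if self.length_bin_size < 2:
            raise ValidationError("length_bin_size must be >= 2")


@dataclass
class DEResults:
    """Result of :func:`de_t_test`.

    ``table`` columns: p, mean_a, mean_b, fold_change (larger/smaller, inf
    when the smaller mean is 0), direction (+1 A-higher, -1 B-higher, 0
    equal), significant.
    """

    table: pd.DataFrame
    n_tested: int
    alpha: float
    n_channels_a: int
    n_channels_b: int

    @property
    def threshold(self) -> float:
        return self.alpha / self.n_tested

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    @property
    def mean_rpm(self) -> pd.Series:
        """Per-transcript mean RPM pooled over all channels of both conditions."""
        na, nb = self.n_channels_a, self.n_channels_b
        return (na * self.table["mean_a"] + nb * self.table["mean_b"]) / (na + nb)


def _welch_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Welch t-test p-values (rows = transcripts).

    Degenerate rows (zero variance in both groups) get p = 1 when the means
    agree and p = 0 when they differ.
    """
    import warnings

    with warnings.catch_warnings():
        # scipy warns on zero-variance rows; those are patched below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    if degenerate.any():
        equal = a.mean(axis=1) == b.mean(axis=1)
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
    return p


def de_t_test(
    matrix: ExpressionMatrix,
    cond_a: Sequence[str],
    cond_b: Sequence[str],
    config: DEConfig | None = None,
) -> DEResults:
    """Welch two-sided t-test per gated transcript on per-channel RPM.

    ``matrix`` must be at channel granularity (each channel independently
    RPM-normalized). The gated set is transcripts above the gate threshold
    in any channel of either condition; N for the threshold division is the
    gated-set size.
    """
    if config is None:
        config = DEConfig()
    cond_a, cond_b = list(cond_a), list(cond_b)
    if len(cond_a) < 2 or len(cond_b) < 2:
        raise ValidationError("each condition needs >= 2 channels")
    ids = gate(matrix, GatingRule(config.gate_threshold, "any"), cond_a + cond_b)
    if not ids:
        return DEResults(
            pd.DataFrame(columns=["p", "mean_a", "mean_b", "fold_change",
                                  "direction", "significant"]),
            0, config.alpha, len(cond_a), len(cond_b),
        )
    a = matrix.values.loc[ids, cond_a].to_numpy(dtype=float)
    b = matrix.values.loc[ids, cond_b].to_numpy(dtype=float)
    p = _welch_p(a, b)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    hi = np.maximum(mean_a, mean_b)
    lo = np.minimum(mean_a, mean_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(lo > 0, hi / lo, np.where(hi > 0, np.inf, 1.0))
    direction = np.sign(mean_a - mean_b).astype(int)
    n = len(ids)
    table = pd.DataFrame(
        {
            "p": p,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fold,
            "direction": direction,
            "significant": p < config.alpha / n,
        },
        index=pd.Index(ids, name="transcript_id"),
    )
    return DEResults(table, n, config.alpha, len(cond_a), len(cond_b))


def length_binned_de(
    results: DEResults,
    lengths: pd.Series,
    config: DEConfig | None = None,
) -> pd.DataFrame:
    """Bin gated transcripts by representative length and summarize DE.

    Transcripts are sorted by median length ascending (id breaks ties, for
    determinism) and chunked into consecutive bins of ``length_bin_size``;
    the last bin may be short. Per bin: member count, mean length, fraction
    significant, and the median (over members) of the mean RPM pooled
    across all channels.
    """
    if config is None:
        config = DEConfig()
    tab = results.table
    if tab.empty:
        return pd.DataFrame(
            columns=["bin", "n", "mean_length", "fraction_significant", "median_rpm"]
        )
    missing = tab.index.difference(lengths.index)
    if len(missing):
        raise ValidationError(f"missing lengths for: {sorted(missing)[:10]}")
    L = lengths.reindex(tab.index)
    ids = list(L.sort_index().sort_values(kind="mergesort").index)
    rpm = results.mean_rpm
    rows = []
    size = config.length_bin_size
    for b, start in enumerate(range(0, len(ids), size)):
        members = ids[start:start + size]
        rows.append(
            {
                "bin": b,
                "n": len(members),
                "mean_length": float(L.loc[members].mean()),
                "fraction_significant": float(tab.loc[members, "significant"].mean()),
                "median_rpm": float(rpm.loc[members].median()),
            }
        )
    return pd.DataFrame(rows)


def expression_strata(matrix: ExpressionMatrix, group: str) -> StrataCounts:
    """Count expressed transcripts per RPM stratum for one group.

    Strata: [5,10], (10,50], (50,100], (100,1e3], (1e3,1e4], (1e4,inf);
    transcripts below 5 RPM are not counted as expressed.
    """
    if group not in matrix.values.columns:
        raise ValidationError(f"unknown group {group!r}")
    v = matrix.values[group].to_numpy(dtype=float)
    edges = STRATA_EDGES
    counts = {}
    counts[STRATA_LABELS[0]] = int(((v >= edges[0]) & (v <= edges[1])).sum())
    for i, label in enumerate(STRATA_LABELS[1:-1], start=1):
        counts[label] = int(((v > edges[i]) & (v <= edges[i + 1])).sum())
    counts[STRATA_LABELS[-1]] = int((v > edges[-1]).sum())
    return StrataCounts(counts=counts, total=sum(counts.values()))


def extreme_change_filter(
    mat_a: pd.Series,
    mat_b: pd.Series,
    min_level: float,
    min_fold: float,
    min_delta: float | None = None,
) -> dict[str, list[str]]:
    """Transcripts with extreme expression ratios between two groups.

    A transcript is selected in the A direction when max(A,B) >= min_level,
    A/B > min_fold (a zero denominator counts as infinite ratio when the
    numerator is positive), and |A-B| > min_delta when set; symmetrically
    for B.
    """
    a = mat_a.astype(float)
    b = mat_b.reindex(a.index).astype(float)
    level_ok = np.maximum(a, b) >= min_level
    delta_ok = (a - b).abs() > min_delta if min_delta is not None else pd.Series(True, index=a.index)

    def ratio_exceeds(num: pd.Series, den: pd.Series) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            r = num / den
        return ((den > 0) & (r > min_fold)) | ((den == 0) & (num > 0))

    sel_a = level_ok & delta_ok & ratio_exceeds(a, b)
    sel_b = level_ok & delta_ok & ratio_exceeds(b, a)
    return {
        "a_higher": list(a.index[sel_a]),
        "b_higher": list(a.index[sel_b]),
    }
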