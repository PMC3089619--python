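"""Protocol-comparison reports: fragmentation length bias, spike-in
linearity, transcriptome-complexity comparison, and selection outliers.

Fragmentation depletes short transcripts (fewer fragments survive per
molecule), so the unfragmented/fragmented expression ratio falls with
transcript length; spike-ins of known concentration and length probe
quantification linearity after length adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import ExpressionMatrix, StrataCounts, ValidationError
from .normalization import NORMALIZATION_TOTAL, spearman
from .differential_expression import expression_strata

#: fixed length-bin boundaries (nt) for the fragmentation report
FRAG_LENGTH_EDGES = (0, 250, 500, 1000, 2000, 4000)


@dataclass
class FragmentationReport:
    """Unfragmented/fragmented ratio statistics on the gated set."""

    ratios: pd.Series  # per-transcript unfrag/frag ratio (frag > 0)
    n_zero_fragmented: int  # gated transcripts with zero fragmented signal
    spearman_vs_log_length: float
    by_length_bin: pd.DataFrame  # bin label, n, median_ratio, mean_ratio


def _length_bin_labels() -> list[str]:
    edges = FRAG_LENGTH_EDGES
    labels = [f"{a}-{b}" for a, b in zip(edges, edges[1:])]
    labels.append(f">={edges[-1]}")
    return labels


def fragmentation_bias(
    unfrag: pd.Series,
    frag: pd.Series,
    lengths: pd.Series,
    gate_rpm: float = 100.0,
    bin_gate_rpm: float = 50.0,
) -> FragmentationReport:
    """Length dependence of the unfragmented/fragmented expression ratio.

    The global correlation uses transcripts > ``gate_rpm`` RPM in either
    sample; transcripts whose fragmented value is zero are excluded from
    ratio statistics (not clamped) and reported separately. The per-bin
    medians use the looser ``bin_gate_rpm`` gate and fixed length
    boundaries {0-250, 250-500, 500-1000, 1000-2000, 2000-4000, >=4000} nt.
    """
    u = unfrag.astype(float)
    f = frag.reindex(u.index).astype(float)
    L = lengths.reindex(u.index).astype(float)
    if L.isna().any():
        raise ValidationError("missing lengths for some transcripts")

    def gated_ratios(threshold: float) -> tuple[pd.Series, int]:
        sel = (u > threshold) | (f > threshold)
        if not sel.any():
            raise ValidationError("empty gated set")
        zero = sel & (f == 0)
        ok = sel & (f > 0)
        return (u[ok] / f[ok]), int(zero.sum())

    ratios, n_zero = gated_ratios(gate_rpm)
    if len(ratios) >= 3:
        rho = spearman(ratios, np.log10(L.loc[ratios.index]))
    else:
        rho = float("nan")
    bin_ratios, _ = gated_ratios(bin_gate_rpm)
    edges = list(FRAG_LENGTH_EDGES) + [np.inf]
    labels = _length_bin_labels()
    Lb = L.loc[bin_ratios.index]
    rows = []
    for i, label in enumerate(labels):
        members = bin_ratios[(Lb >= edges[i]) & (Lb < edges[i + 1])]
        rows.append(
            {
                "length_bin": label,
                "n": len(members),
                "median_ratio": float(members.median()) if len(members) else float("nan"),
                "mean_ratio": float(members.mean()) if len(members) else float("nan"),
            }
        )
    return FragmentationReport(
        ratios=ratios,
        n_zero_fragmented=n_zero,
        spearman_vs_log_length=rho,
        by_length_bin=pd.DataFrame(rows),
    )


@dataclass
class SpikeLinearityReport:
    """Length-adjusted spike abundances against known concentrations."""

    table: pd.DataFrame  # spike id, count, rpm, abundance, concentration
    excluded: list[str]  # spikes with zero reads, flagged out of correlations
    spearman: float
    pearson_log: float


def spike_linearity(
    counts: pd.Series,
    truth: pd.DataFrame,
    library_total: float,
) -> SpikeLinearityReport:
    """Correlate length-adjusted spike abundance with known concentration.

    Abundance is RPKM-style: RPM x 1000 / length. Both the rank (Spearman)
    and the log-linear (Pearson on log10) correlation are reported; spikes
    with zero reads are excluded and flagged.
    """
    req = {"id", "length", "concentration"}
    if not req.issubset(truth.columns):
        raise ValidationError(f"spike truth needs columns {sorted(req)}")
    t = truth.set_index("id")
    if (t["length"] <= 0).any() or (t["concentration"] <= 0).any():
        raise ValidationError("spike lengths and concentrations must be positive")
    c = counts.reindex(t.index).fillna(0).astype(float)
    if (c == 0).all():
        raise ValidationError("all spike counts are zero")
    rpm = c * NORMALIZATION_TOTAL / float(library_total)
    abundance = rpm * 1000.0 / t["length"].astype(float)
    table = pd.DataFrame(
        {
            "count": c,
            "rpm": rpm,
            "abundance": abundance,
            "concentration": t["concentration"].astype(float),
        }
    )
    nz = table[table["count"] > 0]
    if len(nz) < 3:
        raise ValidationError("need >= 3 spikes with nonzero counts")
    rho = spearman(nz["abundance"], nz["concentration"])
    r_log = float(
        stats.pearsonr(np.log10(nz["abundance"]), np.log10(nz["concentration"])).statistic
    )
    return SpikeLinearityReport(
        table=table,
        excluded=list(table.index[table["count"] == 0]),
        spearman=rho,
        pearson_log=r_log,
    )


@dataclass
class ComplexityReport:
    """Detected-transcript comparison across protocol groups."""

    strata: dict[str, StrataCounts]
    totals: pd.Series
    pairwise: pd.DataFrame  # group_a, group_b, n_lost, n_gained
    lost_sets: dict[tuple[str, str], list[str]]  # detected in a, not in b
    lost_composition: pd.DataFrame | None = None


def complexity_report(
    matrix: ExpressionMatrix,
    groups: Sequence[str] | None = None,
    biotypes: pd.Series | None = None,
    polyadenylated: pd.Series | None = None,
    detection_rpm: float = 5.0,
) -> ComplexityReport:
    """Per-group strata totals and pairwise detected-set differences.

    A transcript is detected in a group at >= ``detection_rpm`` RPM (the
    lower edge of the first stratum). For each ordered pair (a, b) the lost
    set is detected-in-a minus detected-in-b; when biotype / polyA truth is
    available the lost-set composition is tabulated.
    """
    if groups is None:
        groups = matrix.group_ids
    groups = list(groups)
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    strata = {g: expression_strata(matrix, g) for g in groups}
    totals = pd.Series({g: strata[g].total for g in groups})
    detected = {
        g: set(matrix.values.index[matrix.values[g] >= detection_rpm]) for g in groups
    }
    rows = []
    lost_sets: dict[tuple[str, str], list[str]] = {}
    comp_rows = []
    for a, b in combinations(groups, 2):
        lost = sorted(detected[a] - detected[b])
        gained = sorted(detected[b] - detected[a])
        lost_sets[(a, b)] = lost
        lost_sets[(b, a)] = gained
        rows.append({"group_a": a, "group_b": b,
                     "n_lost": len(lost), "n_gained": len(gained)})
        if biotypes is not None:
            for direction, ids in (("lost", lost), ("gained", gained)):
                bt = biotypes.reindex(ids).fillna("unknown")
                entry = {"group_a": a, "group_b": b, "direction": direction,
                         "n": len(ids)}
                entry.update(bt.value_counts().to_dict())
                if polyadenylated is not None and len(ids):
                    pa = polyadenylated.reindex(ids)
                    entry["n_polyA_minus"] = int((pa == False).sum())  # noqa: E712
                comp_rows.append(entry)
    return ComplexityReport(
        strata=strata,
        totals=totals,
        pairwise=pd.DataFrame(rows),
        lost_sets=lost_sets,
        lost_composition=pd.DataFrame(comp_rows) if comp_rows else None,
    )


def selection_outliers(
    mat_a: pd.Series,
    mat_b: pd.Series,
    min_fold: float = 5.0,
    min_rpm: float = 10.0,
    biotypes: pd.Series | None = None,
) -> dict[str, pd.DataFrame]:
    """Transcripts far off the diagonal between two protocol groups.

    Selected per direction: max(A, B) >= min_rpm and ratio > min_fold (zero
    denominator counts as infinite); sorted by descending ratio.
    """
    a = mat_a.astype(float)
    b = mat_b.reindex(a.index).astype(float)
    level_ok = np.maximum(a, b) >= min_rpm

    def direction(num: pd.Series, den: pd.Series) -> pd.DataFrame:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(den > 0, num / den, np.where(num > 0, np.inf, 1.0))
        ratio = pd.Series(ratio, index=a.index)
        sel = level_ok & (ratio > min_fold)
        out = pd.DataFrame({"value_high": num[sel], "value_low": den[sel],
                            "ratio": ratio[sel]})
        if biotypes is not None:
            out["biotype"] = biotypes.reindex(out.index).fillna("unknown")
        return out.sort_values("ratio", ascending=False, kind="mergesort")

    return {"a_higher": direction(a, b), "b_higher": direction(b, a)}
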