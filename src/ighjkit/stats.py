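"""Repertoire statistics: IGHJ usage and bands, U/T ratios, D-J pairing,
junction trimming/insertion summaries, and one-way ANOVA group comparison
with Bonferroni-corrected pairwise contrasts.

Usage frequencies are computed on unique sequences (clonotypes) by
default — duplicate counts measure clonal expansion, not gene choice —
and classified into the observed bands: high (> 40%), medium (10-20%),
low (< 4%); values between bands are reported as "unbanded" rather than
force-fit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateAnovaError, EmptyStratumError, ParameterError
from .repio import FRAME_IN, FRAME_OUT, RepertoireTable, collapse_unique

IGHJ_GENES = tuple(f"IGHJ{i}" for i in range(1, 7))

BAND_HIGH_MIN = 0.40  # exclusive lower edge of the high band
BAND_MEDIUM = (0.10, 0.20)  # inclusive
BAND_LOW_MAX = 0.04  # exclusive upper edge of the low band


def band_label(freq: float) -> str:
    if freq > BAND_HIGH_MIN:
        return "high"
    if BAND_MEDIUM[0] <= freq <= BAND_MEDIUM[1]:
        return "medium"
    if freq < BAND_LOW_MAX:
        return "low"
    return "unbanded"


@dataclass(frozen=True)
class UsageProfile:
    """Per-gene usage frequencies (fractions of unique sequences) in one stratum."""

    frequencies: Mapping[str, float]
    bands: Mapping[str, str]
    frame: str | None = None
    sample_id: str | None = None
    n_unique: int = 0
    ut_ratios: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.frequencies.values())
        if self.frequencies and abs(total - 1.0) > 1e-9:
            raise ParameterError(f"usage frequencies sum to {total}, not 1")


def ighj_usage(
    table: RepertoireTable,
    frame: str | None = None,
    weight_by_duplicates: bool = False,
) -> UsageProfile:
    """Usage frequency of each J gene among unique records of one frame stratum.

    ``frame`` is ``"in_frame"``, ``"out_of_frame"`` or None (both).  The
    table is expected to be filtered and collapsed; set
    ``weight_by_duplicates`` for a total-sequence-weighted sensitivity
    analysis.
    """
    df = table.df
    if frame is not None:
        if frame not in (FRAME_IN, FRAME_OUT):
            raise ParameterError(f"unknown frame stratum {frame!r}")
        df = df[df["frame"] == frame]
    df = df[df["j_call"].notna()]
    if not len(df):
        raise EmptyStratumError(f"no records in stratum frame={frame!r}")
    if weight_by_duplicates:
        counts = df.groupby("j_call")["duplicate_count"].sum()
    else:
        counts = df.groupby("j_call").size()
    freqs = (counts / counts.sum()).to_dict()
    sample_ids = df["sample_id"].dropna().unique() if "sample_id" in df.columns else []
    return UsageProfile(
        frequencies=freqs,
        bands={g: band_label(f) for g, f in freqs.items()},
        frame=frame,
        sample_id=sample_ids[0] if len(sample_ids) == 1 else None,
        n_unique=int(len(df)),
    )


def ut_ratio(
    total_table: RepertoireTable, unique_table: RepertoireTable | None = None
) -> dict[str, float]:
    """Unique-to-total sequence ratio per J gene, in (0, 1].

    ``total`` counts every sequence (sum of duplicate counts); ``unique``
    counts clonotypes.  Genes absent from the total table are reported as
    missing (absent keys), never as 0.
    """
    if unique_table is None:
        unique_table = collapse_unique(total_table)
    tot = total_table.df[total_table.df["j_call"].notna()]
    uni = unique_table.df[unique_table.df["j_call"].notna()]
    total_counts = tot.groupby("j_call")["duplicate_count"].sum()
    unique_counts = uni.groupby("j_call").size()
    return {
        g: float(unique_counts.get(g, 0)) / float(total_counts[g])
        for g in total_counts.index
        if total_counts[g] > 0
    }


@dataclass(frozen=True)
class PairingMatrix:
    """J x D pair frequencies; globally normalised or row-normalised per J."""

    matrix: pd.DataFrame  # index: j_call, columns: d_call
    normalization: str
    n_pairs: int
    n_excluded_missing_d: int


def dj_pairing_matrix(
    table: RepertoireTable, normalization: str = "global"
) -> PairingMatrix:
    """Pair-frequency matrix over unique records with both J and D calls."""
    if normalization not in ("global", "per_J"):
        raise ParameterError(f"unknown normalization {normalization!r}")
    df = table.df[table.df["j_call"].notna()]
    missing_d = int(df["d_call"].isna().sum()) if "d_call" in df.columns else len(df)
    if "d_call" not in df.columns:
        raise EmptyStratumError("no d_call column; no pairable records")
    paired = df[df["d_call"].notna()]
    if not len(paired):
        raise EmptyStratumError("no records with both j_call and d_call")
    counts = pd.crosstab(paired["j_call"], paired["d_call"])
    if normalization == "global":
        mat = counts / counts.values.sum()
    else:
        mat = counts.div(counts.sum(axis=1), axis=0)
    return PairingMatrix(
        matrix=mat,
        normalization=normalization,
        n_pairs=int(len(paired)),
        n_excluded_missing_d=missing_d,
    )


@dataclass(frozen=True)
class JunctionStats:
    """Per-gene mean/SD/count of 3'D trim, 5'J trim and N2 insertion lengths."""

    per_gene: pd.DataFrame  # index j_call; columns (field, stat)
    missing_counts: Mapping[str, int]


_JUNCTION_FIELDS = ("d_3_trim", "j_5_trim", "n2_length")


def junction_trim_stats(table: RepertoireTable, group_by: str = "j_call") -> JunctionStats:
    df = table.df[table.df[group_by].notna()]
    frames = {}
    missing = {}
    for fld in _JUNCTION_FIELDS:
        if fld not in df.columns:
            missing[fld] = len(df)
            continue
        col = pd.to_numeric(df[fld], errors="coerce")
        missing[fld] = int(col.isna().sum())
        sub = df.assign(_v=col).dropna(subset=["_v"])
        g = sub.groupby(group_by)["_v"]
        frames[fld] = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1), "count": g.size()})
    per_gene = pd.concat(frames, axis=1) if frames else pd.DataFrame()
    return JunctionStats(per_gene=per_gene, missing_counts=missing)


def significance_tier(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class GroupComparison:
    f_statistic: float
    p_value: float
    group_labels: tuple[str, ...]
    pairwise: Mapping[tuple[str, str], Mapping[str, object]]
    n_comparisons: int


def compare_groups(
    data: pd.DataFrame, value_col: str, group_col: str
) -> GroupComparison:
    """One-way (equal-variance) ANOVA plus Bonferroni-corrected pairwise t contrasts.

    Adjusted p-values are min(1, raw x number of pairs) and significance
    tiers follow the conventional star thresholds (0.05 / 0.01 / 0.001).
    """
    groups = {g: sub[value_col].to_numpy(dtype=float) for g, sub in data.groupby(group_col)}
    labels = tuple(sorted(groups))
    if len(labels) < 2:
        raise ParameterError("compare_groups needs at least two groups")
    if max(len(v) for v in groups.values()) < 2:
        raise ParameterError("at least one group must have >= 2 samples")
    if all(np.var(v) == 0 for v in groups.values()):
        means = [v.mean() for v in groups.values()]
        if np.ptp(means) > 0:
            raise DegenerateAnovaError("zero within-group variance in every group")
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = sps.f_oneway(*(groups[g] for g in labels))
        f_stat, p_val = float(f_stat), float(p_val)

    pairs = list(itertools.combinations(labels, 2))
    m = len(pairs)
    pairwise = {}
    for a, b in pairs:
        va, vb = groups[a], groups[b]
        if np.var(va) == 0 and np.var(vb) == 0:
            raw = 1.0 if va.mean() == vb.mean() else 0.0
        else:
            raw = float(sps.ttest_ind(va, vb, equal_var=True).pvalue)
        adj = min(1.0, raw * m)
        pairwise[(a, b)] = {"p_raw": raw, "p_adj": adj, "tier": significance_tier(adj)}
    return GroupComparison(
        f_statistic=f_stat,
        p_value=p_val,
        group_labels=labels,
        pairwise=pairwise,
        n_comparisons=m,
    )


def usage_profiles_per_sample(
    table: RepertoireTable, frame: str | None = None
) -> pd.DataFrame:
    """Tidy per-sample usage table (sample_id, j_call, frequency) for group comparison."""
    rows = []
    for sid, sub in table.df.groupby("sample_id"):
        prof = ighj_usage(RepertoireTable(sub.reset_index(drop=True)), frame=frame)
        for gene, f in prof.frequencies.items():
            rows.append({"sample_id": sid, "j_call": gene, "frequency": f})
    return pd.DataFrame(rows)
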