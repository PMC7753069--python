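"""Reading, filtering and collapsing annotated rearrangement tables.

Two dialects are supported: AIRR Rearrangement TSV (schema column names)
and an IMGT HighV-QUEST summary-table dialect.  Filtering follows the
standard repertoire QC convention: drop records the annotator returned
nothing for ("no results") and records whose junction could not be
identified ("unknown" functionality); out-of-frame rearrangements are
kept — they are genuine repertoire members, not artifacts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

FRAME_IN = "in_frame"
FRAME_OUT = "out_of_frame"
FRAME_UNASSIGNED = "unassigned"

FUNC_PRODUCTIVE = "productive"
FUNC_UNPRODUCTIVE = "unproductive"
FUNC_NO_RESULTS = "no_results"
FUNC_UNKNOWN = "unknown"

#: Clonotype identity used to collapse to unique sequences.
DEFAULT_UNIQUE_KEY = ("j_call", "d_call", "junction")

#: Column order for AIRR TSV output.
AIRR_COLUMNS = [
    "sequence_id", "v_call", "d_call", "j_call", "junction",
    "vj_in_frame", "productive", "d_3_trim", "j_5_trim", "n2_length",
    "duplicate_count", "sample_id", "group_id",
]
_INT_COLUMNS = ["d_3_trim", "j_5_trim", "n2_length", "duplicate_count"]
_BOOL_COLUMNS = ["vj_in_frame", "productive"]


@dataclass
class RepertoireTable:
    """A collection of rearrangement records plus provenance and filter log.

    ``df`` has one row per record with AIRR-style columns and two derived
    columns: ``functionality`` (productive / unproductive / no_results /
    unknown) and ``frame`` (in_frame / out_of_frame / unassigned).
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    filter_log: dict = field(default_factory=dict)

    @property
    def n_records(self) -> int:
        return len(self.df)

    @property
    def n_total(self) -> int:
        """Total sequences, counting duplicates."""
        return int(self.df["duplicate_count"].sum()) if len(self.df) else 0

    def with_df(self, df: pd.DataFrame, **log) -> "RepertoireTable":
        return RepertoireTable(
            df.reset_index(drop=True),
            provenance=dict(self.provenance),
            filter_log={**self.filter_log, **log},
        )


_GENE_CALL_RE = re.compile(r"(IGH[VDJ][0-9][\w.-]*?)(?:\*|$|\s)")


def normalize_gene_call(call: object) -> str | None:
    """Normalise an annotator gene call to subgroup/gene level.

    Strips species prefixes ("Homsap "), allele suffixes ("*02"),
    functionality letters, and keeps the first of a multi-gene call
    ("IGHJ4*02 F, or IGHJ5*01 F" → "IGHJ4").
    """
    if call is None or (isinstance(call, float) and np.isnan(call)):
        return None
    text = str(call).strip()
    if not text:
        return None
    first = re.split(r",| or ", text)[0]
    first = first.replace("Homsap", "").strip()
    m = _GENE_CALL_RE.search(first + " ")
    if not m:
        return None
    name = m.group(1)
    # J calls are reported at subgroup level (IGHJ4), D calls at gene level (IGHD6-13)
    if name.startswith("IGHJ"):
        m2 = re.match(r"IGHJ\d+", name)
        return m2.group(0) if m2 else name
    return name


def _finalise(df: pd.DataFrame, provenance: dict, malformed: int = 0) -> RepertoireTable:
    for col in _INT_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "duplicate_count" not in df.columns:
        df["duplicate_count"] = 1
    df["duplicate_count"] = df["duplicate_count"].fillna(1).astype(np.int64)
    if (df["duplicate_count"] < 1).any():
        raise FormatError("duplicate_count must be >= 1")
    log = {"malformed_rows": malformed} if malformed else {}
    return RepertoireTable(df.reset_index(drop=True), provenance=provenance, filter_log=log)


def _parse_airr_bool(series: pd.Series) -> pd.Series:
    return series.map(lambda v: {"T": True, "TRUE": True, "F": False, "FALSE": False}.get(
        str(v).strip().upper(), None))


def read_airr(path: str) -> RepertoireTable:
    """Read an AIRR Rearrangement TSV (provenance '#' header lines allowed)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty or header-less file") from exc
    missing = {"sequence_id", "j_call"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {sorted(missing)}")

    malformed = int(df["sequence_id"].isna().sum())
    df = df[df["sequence_id"].notna()].copy()

    for col in _BOOL_COLUMNS:
        if col in df.columns:
            df[col] = _parse_airr_bool(df[col])
    df["j_call"] = df["j_call"].map(normalize_gene_call)
    if "d_call" in df.columns:
        df["d_call"] = df["d_call"].map(normalize_gene_call)
    if "v_call" in df.columns:
        df["v_call"] = df["v_call"].map(normalize_gene_call)

    if "frame" not in df.columns:
        if "vj_in_frame" in df.columns:
            df["frame"] = df["vj_in_frame"].map(
                {True: FRAME_IN, False: FRAME_OUT}).fillna(FRAME_UNASSIGNED)
        else:
            df["frame"] = FRAME_UNASSIGNED
    if "functionality" not in df.columns:
        df["functionality"] = _derive_functionality(df)
    return _finalise(df, {"source": str(path), "dialect": "airr"}, malformed)


def _derive_functionality(df: pd.DataFrame) -> pd.Series:
    """Annotator-style functionality: no junction → unknown, else by productivity/frame."""
    has_junction = df["junction"].notna() & (df["junction"] != "") if "junction" in df.columns \
        else pd.Series(False, index=df.index)
    has_j = df["j_call"].notna()
    out = pd.Series(FUNC_UNKNOWN, index=df.index, dtype=object)
    usable = has_junction & has_j
    if "productive" in df.columns:
        out[usable & (df["productive"] == True)] = FUNC_PRODUCTIVE  # noqa: E712
        out[usable & (df["productive"] == False)] = FUNC_UNPRODUCTIVE  # noqa: E712
        out[usable & df["productive"].isna()] = FUNC_UNPRODUCTIVE
    else:
        out[usable] = FUNC_PRODUCTIVE
    return out


def write_airr(table: RepertoireTable, path: str) -> None:
    """Write an AIRR Rearrangement TSV; round-trips losslessly through read_airr.

    Provenance is written as '#'-prefixed header lines before the column
    header (seed, tool version, record counts).
    """
    df = table.df.copy()
    for col in _BOOL_COLUMNS:
        if col in df.columns:
            df[col] = df[col].map({True: "T", False: "F"})
    cols = [c for c in AIRR_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols and c not in ("functionality", "frame")]
    with open(path, "w") as fh:
        for line in format_provenance(table.provenance):
            fh.write(line + "\n")
        df[cols].to_csv(fh, sep="\t", index=False)


def format_provenance(provenance: dict) -> list[str]:
    from . import __version__

    lines = [f"# ighjkit={__version__}"]
    lines += [f"# {k}={v}" for k, v in sorted(provenance.items())]
    return lines


# ---------------------------------------------------------------------------
# IMGT HighV-QUEST summary dialect

_IMGT_COLMAP = {
    "Sequence ID": "sequence_id",
    "Functionality": "functionality_raw",
    "V-GENE and allele": "v_call",
    "D-GENE and allele": "d_call",
    "J-GENE and allele": "j_call",
    "JUNCTION": "junction",
}


def _map_imgt_functionality(text: object) -> str:
    t = str(text).strip().lower()
    if t.startswith("productive"):
        return FUNC_PRODUCTIVE
    if t.startswith("unproductive"):
        # "(no junction)" descriptions mean no junction anchors were found
        return FUNC_UNKNOWN if "no junction" in t else FUNC_UNPRODUCTIVE
    if t.startswith("no results"):
        return FUNC_NO_RESULTS
    return FUNC_UNKNOWN


def read_imgt_summary(path: str) -> RepertoireTable:
    """Read an IMGT HighV-QUEST summary TSV into the common record form."""
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty IMGT summary file") from exc
    if "Functionality" not in raw.columns:
        raise FormatError(f"{path}: not an IMGT summary table (no Functionality column)")
    df = pd.DataFrame(index=raw.index)
    for src, dst in _IMGT_COLMAP.items():
        if src in raw.columns:
            df[dst] = raw[src]
    if "sequence_id" not in df.columns:
        df["sequence_id"] = [f"imgt-{i + 1}" for i in range(len(df))]
    df["functionality"] = df.pop("functionality_raw").map(_map_imgt_functionality)
    for col in ("v_call", "d_call", "j_call"):
        if col in df.columns:
            df[col] = df[col].map(normalize_gene_call)
    df["frame"] = df["functionality"].map(
        {FUNC_PRODUCTIVE: FRAME_IN, FUNC_UNPRODUCTIVE: FRAME_OUT}).fillna(FRAME_UNASSIGNED)
    return _finalise(df, {"source": str(path), "dialect": "imgt_summary"})


# ---------------------------------------------------------------------------
# Filtering / stratification / collapsing


def filter_records(table: RepertoireTable) -> RepertoireTable:
    """Drop no-results and unknown-functionality records; idempotent.

    Removal counts per rule are appended to the filter log.
    """
    df = table.df
    n_no_results = int((df["functionality"] == FUNC_NO_RESULTS).sum())
    n_unknown = int((df["functionality"] == FUNC_UNKNOWN).sum())
    kept = df[~df["functionality"].isin((FUNC_NO_RESULTS, FUNC_UNKNOWN))]
    return table.with_df(
        kept,
        removed_no_results=table.filter_log.get("removed_no_results", 0) + n_no_results,
        removed_unknown=table.filter_log.get("removed_unknown", 0) + n_unknown,
    )


def stratify_by_frame(table: RepertoireTable) -> tuple[RepertoireTable, RepertoireTable]:
    """Partition into (in-frame, out-of-frame); unassigned records excluded and counted."""
    df = table.df
    n_unassigned = int((~df["frame"].isin((FRAME_IN, FRAME_OUT))).sum())
    in_t = table.with_df(df[df["frame"] == FRAME_IN], excluded_unassigned_frame=n_unassigned)
    out_t = table.with_df(df[df["frame"] == FRAME_OUT], excluded_unassigned_frame=n_unassigned)
    return in_t, out_t


def collapse_unique(
    table: RepertoireTable, key_fields: tuple[str, ...] = DEFAULT_UNIQUE_KEY
) -> RepertoireTable:
    """Collapse to one record per clonotype key, summing duplicate counts.

    The total sequence count (sum of ``duplicate_count``) is preserved
    exactly.
    """
    if not key_fields:
        raise ParameterError("key_fields must not be empty")
    missing = set(key_fields) - set(table.df.columns)
    if missing:
        raise ParameterError(f"key fields not in table: {sorted(missing)}")
    df = table.df
    if not len(df):
        return table.with_df(df, collapsed_on=key_fields)
    agg = {c: "first" for c in df.columns if c not in key_fields}
    agg["duplicate_count"] = "sum"
    out = (
        df.groupby(list(key_fields), dropna=False, sort=True)
        .agg(agg)
        .reset_index()[list(df.columns)]
    )
    return table.with_df(out, collapsed_on=key_fields)
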