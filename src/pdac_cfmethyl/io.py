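"""Readers and writers for the external formats the pipeline touches.

Internal coordinates are 1-based inclusive everywhere; BED files are the
only 0-based half-open surface, converted at the read/write boundary.
CpG counts are assumed pre-collapsed to the plus-strand cytosine; strand
is ignored throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_GROUPS = ("PDAC", "healthy")
VALID_STAGES = ("0", "I", "II", "III", "IV", "NA")
VALID_SPLITS = ("train", "test", "NA")

GENIC_CATEGORIES = (
    "promoter", "5'UTR", "exon", "intron", "3'UTR", "upstream", "intergenic",
)
CPG_CONTEXTS = ("CGI", "CGI_shore", "open_sea")
TRACK_NAMES = GENIC_CATEGORIES + ("CGI", "CGI_shore", "open_sea", "enhancer")


class FormatError(ValueError):
    """Malformed input file (wrong schema, bad values, duplicates)."""


@dataclass
class CpGCountTable:
    """Per-sample per-CpG methylated/total read counts.

    ``df`` columns: chrom (str), pos (1-based int), n_meth, n_total.
    Positions are unique and sorted within each chromosome.
    """

    sample_id: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["chrom", "pos", "n_meth", "n_total"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise FormatError(f"CpGCountTable missing columns: {missing}")
        df = self.df[required].reset_index(drop=True)
        if len(df):
            if (df["n_meth"] > df["n_total"]).any():
                raise FormatError("n_meth > n_total in count table")
            if (df["n_meth"] < 0).any() or (df["n_total"] < 0).any():
                raise FormatError("negative counts in count table")
            if df.duplicated(["chrom", "pos"]).any():
                dups = df[df.duplicated(["chrom", "pos"], keep=False)]
                raise FormatError(
                    f"duplicate (chrom,pos) in table {self.sample_id}: "
                    f"{dups.head().to_dict('records')}"
                )
            df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_arrays(cls, sample_id: str, chrom: Sequence[str],
                    pos: Sequence[int], n_meth: Sequence[int],
                    n_total: Sequence[int]) -> "CpGCountTable":
        return cls(sample_id, pd.DataFrame({
            "chrom": np.asarray(chrom, dtype=object),
            "pos": np.asarray(pos, dtype=np.int64),
            "n_meth": np.asarray(n_meth, dtype=np.int64),
            "n_total": np.asarray(n_total, dtype=np.int64),
        }))


@dataclass
class AnnotationTrack:
    """Named interval set; intervals stored 0-based half-open as in BED."""

    name: str
    df: pd.DataFrame  # columns chrom, start, end (0-based half-open)

    def __post_init__(self) -> None:
        required = ["chrom", "start", "end"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise FormatError(f"AnnotationTrack missing columns: {missing}")
        df = self.df[required].reset_index(drop=True)
        if len(df) and (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]]
            raise FormatError(f"invalid intervals (start >= end): {bad.head().to_dict('records')}")
        self.df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# coordinate conventions
# ---------------------------------------------------------------------------

def bed_to_internal(start: int, end: int) -> tuple[int, int]:
    """0-based half-open BED interval -> 1-based inclusive."""
    return start + 1, end


def internal_to_bed(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open BED interval."""
    return start - 1, end


# ---------------------------------------------------------------------------
# Bismark coverage dialect
# ---------------------------------------------------------------------------

def read_coverage_table(path: str | Path, sample_id: str | None = None) -> CpGCountTable:
    """Read a Bismark coverage-format table.

    Columns: chrom, start, end, methylation%, count_methylated,
    count_unmethylated. The (1-based) start column is taken as the CpG
    position; n_total = methylated + unmethylated.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.name.split(".")[0]
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", compression="infer",
            names=["chrom", "start", "end", "pct", "count_m", "count_um"],
            dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        logger.warning("coverage file %s is empty", path)
        return CpGCountTable(sample_id, pd.DataFrame(
            columns=["chrom", "pos", "n_meth", "n_total"]))
    bad = df.index[df[["start", "count_m", "count_um"]].isna().any(axis=1)]
    if len(bad):
        lines = [int(i) + 1 for i in bad[:5]]
        raise FormatError(f"{path}: malformed rows at lines {lines}")
    return CpGCountTable(sample_id, pd.DataFrame({
        "chrom": df["chrom"],
        "pos": df["start"].astype(np.int64),
        "n_meth": df["count_m"].astype(np.int64),
        "n_total": (df["count_m"] + df["count_um"]).astype(np.int64),
    }))


def write_coverage_table(table: CpGCountTable, path: str | Path) -> None:
    df = table.df
    n_um = df["n_total"] - df["n_meth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(df["n_total"] > 0, 100.0 * df["n_meth"] / df["n_total"], 0.0)
    out = pd.DataFrame({
        "chrom": df["chrom"], "start": df["pos"], "end": df["pos"],
        "pct": np.round(pct, 6), "count_m": df["n_meth"], "count_um": n_um,
    })
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

_STAGE_PREFIXES = ("IV", "III", "II", "I", "0")


def normalize_stage(value) -> str:
    """Normalize an AJCC stage label to {0, I, II, III, IV, NA}.

    Sub-stage suffixes are dropped by prefix rule (IA -> I, IIB -> II).
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "NA"
    s = str(value).strip().upper()
    if s in ("", "NA", "NAN", "NONE"):
        return "NA"
    for p in _STAGE_PREFIXES:
        if s.startswith(p):
            if s != p:
                logger.info("stage %r normalized to %r", value, p)
            return p
    raise FormatError(f"unrecognized stage label: {value!r}")


def validate_sample_sheet(df: pd.DataFrame) -> pd.DataFrame:
    required = ["sample_id", "group"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"sample sheet missing columns: {missing}")
    df = df.copy()
    for col, default in (("cohort", "NA"), ("stage", "NA"),
                         ("ca19_9", np.nan), ("split", "NA")):
        if col not in df.columns:
            df[col] = default
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample ids: {dup}")
    bad_group = ~df["group"].isin(VALID_GROUPS)
    if bad_group.any():
        row = df[bad_group].iloc[0]
        raise FormatError(
            f"unknown group {row['group']!r} for sample {row['sample_id']!r}")
    df["stage"] = [normalize_stage(v) for v in df["stage"]]
    bad_stage = (df["group"] == "PDAC") & (df["stage"] == "NA")
    # stage NA is allowed only for healthy controls; cases must be staged
    if bad_stage.any():
        raise FormatError(
            f"missing stage for PDAC samples: {df.loc[bad_stage, 'sample_id'].tolist()}")
    df["ca19_9"] = pd.to_numeric(df["ca19_9"], errors="coerce")
    if (df["ca19_9"].dropna() < 0).any():
        raise FormatError("negative CA19-9 values in sample sheet")
    df["split"] = df["split"].fillna("NA")
    bad_split = ~df["split"].isin(VALID_SPLITS)
    if bad_split.any():
        raise FormatError(
            f"unknown split values: {df.loc[bad_split, 'split'].unique().tolist()}")
    return df.reset_index(drop=True)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", compression="infer", dtype={"sample_id": str})
    return validate_sample_sheet(df)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = [
    "sample_id", "gene", "chrom", "pos", "ref", "alt",
    "allele_fraction", "protein_change", "non_synonymous", "wbc_shared",
]


def validate_variant_table(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in ("non_synonymous", "wbc_shared"):
        if col not in df.columns:
            df[col] = col == "non_synonymous"  # default: non-syn True, shared False
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"variant table missing columns: {missing}")
    df = df[VARIANT_COLUMNS].reset_index(drop=True)
    if len(df):
        df["allele_fraction"] = pd.to_numeric(df["allele_fraction"])
        if ((df["allele_fraction"] <= 0) | (df["allele_fraction"] > 1)).any():
            raise FormatError("allele_fraction must be in (0, 1]")
        if (df["ref"] == df["alt"]).any():
            bad = df[df["ref"] == df["alt"]].iloc[0]
            raise FormatError(f"ref == alt at {bad['chrom']}:{bad['pos']}")
        df["non_synonymous"] = df["non_synonymous"].astype(bool)
        df["wbc_shared"] = df["wbc_shared"].astype(bool)
    return df


def read_variant_table(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", compression="infer",
                         dtype={"sample_id": str, "chrom": str})
    except pd.errors.EmptyDataError:
        logger.warning("variant table %s is empty", path)
        df = pd.DataFrame(columns=VARIANT_COLUMNS)
    return validate_variant_table(df)


def write_variant_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_variant_table(df).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED tracks and DMR BED
# ---------------------------------------------------------------------------

def read_bed_track(path: str | Path, name: str | None = None) -> AnnotationTrack:
    path = Path(path)
    if name is None:
        name = path.name.split(".")[0]
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         compression="infer", usecols=[0, 1, 2],
                         names=["chrom", "start", "end"], dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end"])
    return AnnotationTrack(name, df)


DMR_BED_HEADER = "#chrom\tstart\tend\tname\tscore\tstrand"


def write_dmr_bed(dmrs: pd.DataFrame, path: str | Path) -> None:
    """Write called DMRs as BED6.

    Name carries the direction (``hyper_1`` ...), score is
    round(|mean_diff| * 1000) clipped to [0, 1000]. Internal 1-based
    inclusive coordinates are converted to BED convention. Deterministic
    (chrom, start) ordering.
    """
    rows = []
    if len(dmrs):
        d = dmrs.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        for i, r in d.iterrows():
            b_start, b_end = internal_to_bed(int(r["start"]), int(r["end"]))
            score = int(np.clip(round(abs(float(r["mean_diff"])) * 1000), 0, 1000))
            rows.append(f"{r['chrom']}\t{b_start}\t{b_end}\t{r['direction']}_{i + 1}\t{score}\t.")
    Path(path).write_text("\n".join([DMR_BED_HEADER] + rows) + "\n")


def read_dmr_bed(path: str | Path) -> pd.DataFrame:
    """Read a DMR BED6 written by :func:`write_dmr_bed` back to internal form."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         compression="infer",
                         names=["chrom", "start", "end", "name", "score", "strand"],
                         dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
    if not len(df):
        return pd.DataFrame(columns=["chrom", "start", "end", "direction", "mean_diff", "name"])
    starts, ends = zip(*(bed_to_internal(int(s), int(e))
                         for s, e in zip(df["start"], df["end"])))
    direction = df["name"].str.rsplit("_", n=1).str[0]
    sign = np.where(direction == "hypo", -1.0, 1.0)
    return pd.DataFrame({
        "chrom": df["chrom"], "start": starts, "end": ends,
        "direction": direction, "mean_diff": sign * df["score"] / 1000.0,
        "name": df["name"],
    })
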