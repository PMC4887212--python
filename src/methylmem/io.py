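"""Readers and writers for the pipeline's on-disk formats.

All tabular data are carried as :class:`pandas.DataFrame` objects with fixed
column vocabularies:

* **cytosine tables** — per-sample, per-cytosine methylation counts in a
  CX-report-style dialect (tab-separated: chrom, 1-based position, strand,
  methylated reads, unmethylated reads, context, trinucleotide). In memory
  the frame has columns ``chrom, pos, strand, context, meth, total`` (and
  ``tri``); ``total = meth + unmeth``.
* **intervals** — BED6 or GFF3 on disk; in memory always 0-based half-open
  with columns ``chrom, start, end, name, score, strand`` (GFF3 frames carry
  an extra ``feature`` column with the feature type).
* **sample sheets** — tab-separated with header; one row per sequencing
  library of the generation x lineage x treatment grid.

Cytosine positions stay 1-based in memory and on disk (the WGBS reporting
convention); interval coordinates are converted to 0-based half-open at the
I/O boundary so interval arithmetic is BED-compatible throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_CONTEXTS = ("CG", "CHG", "CHH")
VALID_STRANDS = ("+", "-")
VALID_GENERATIONS = ("G1", "G3", "G5")
VALID_LINEAGES = ("P0", "P1", "P2")
VALID_TREATMENTS = ("control", "25", "75")

CYTOSINE_COLUMNS = ["chrom", "pos", "strand", "context", "meth", "total"]
INTERVAL_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class FormatError(ValueError):
    """A malformed line or an invalid field in an input file."""


@dataclass(frozen=True)
class SampleMeta:
    """One sequencing library of the generation x lineage x treatment grid."""

    sample_id: str
    generation: str  # G1 | G3 | G5
    lineage: str  # P0 | P1 | P2
    treatment: str  # control | 25 | 75
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.generation not in VALID_GENERATIONS:
            raise FormatError(f"unknown generation {self.generation!r}")
        if self.lineage not in VALID_LINEAGES:
            raise FormatError(f"unknown lineage {self.lineage!r}")
        if self.treatment not in VALID_TREATMENTS:
            raise FormatError(
                f"unknown treatment {self.treatment!r}; expected one of {VALID_TREATMENTS}"
            )

    @property
    def stressed(self) -> bool:
        return self.treatment != "control"

    def key(self) -> tuple:
        return (self.generation, self.lineage, self.treatment, self.replicate)


@dataclass(frozen=True)
class CytosineRecord:
    """One strand-specific cytosine with context and read counts.

    Tables of these are carried as DataFrames (columns ``chrom, pos, strand,
    context, meth, total``); this dataclass is the record-level contract.
    """

    chrom: str
    pos: int  # 1-based
    strand: str
    context: str
    meth: int
    total: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError("position must be >= 1")
        if self.strand not in VALID_STRANDS:
            raise FormatError(f"strand must be + or -, got {self.strand!r}")
        if self.context not in VALID_CONTEXTS:
            raise FormatError(f"unknown context {self.context!r}")
        if not 0 <= self.meth <= self.total:
            raise FormatError("need 0 <= meth <= total")
        if self.total < 1:
            raise FormatError("total read count must be positive")

    @property
    def frequency(self) -> float:
        return self.meth / self.total


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (start >= end)"
            )

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# cytosine tables
# ---------------------------------------------------------------------------


def read_cytosine_table(path: str | Path) -> pd.DataFrame:
    """Read a CX-report-style cytosine table.

    Returns a frame with columns ``chrom, pos, strand, context, meth, total,
    tri`` sorted by (chrom, pos, strand). Malformed lines raise
    :class:`FormatError` naming the offending line number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "pos", "strand", "meth", "unmeth", "context", "tri"],
            dtype={
                "chrom": str,
                "strand": str,
                "context": str,
                "tri": str,
            },
            comment="#",
        )
    except pd.errors.EmptyDataError:
        return empty_cytosine_table()
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: cannot parse cytosine table: {exc}") from exc

    for col in ("pos", "meth", "unmeth"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise FormatError(f"{path}:{line}: non-numeric value in column {col!r}")
        df[col] = coerced.astype(np.int64)

    _validate_cytosine_frame(df, str(path))
    df["total"] = df["meth"] + df["unmeth"]
    df = df[["chrom", "pos", "strand", "context", "meth", "total", "tri"]]
    return df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)


def _validate_cytosine_frame(df: pd.DataFrame, where: str) -> None:
    def first_bad(mask: pd.Series, msg: str) -> None:
        if mask.any():
            line = int(np.flatnonzero(mask.to_numpy())[0]) + 1
            raise FormatError(f"{where}:{line}: {msg}")

    first_bad(df["pos"] < 1, "position must be >= 1")
    first_bad(~df["strand"].isin(VALID_STRANDS), "strand must be + or -")
    first_bad(~df["context"].isin(VALID_CONTEXTS), "unknown methylation context")
    first_bad(df["meth"] < 0, "negative methylated count")
    first_bad(df["unmeth"] < 0, "negative unmethylated count")
    first_bad(df["meth"] + df["unmeth"] < 1, "total read count must be positive")


def empty_cytosine_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "context": pd.Series(dtype=str),
            "meth": pd.Series(dtype=np.int64),
            "total": pd.Series(dtype=np.int64),
            "tri": pd.Series(dtype=str),
        }
    )


def write_cytosine_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cytosine table in the CX-report-style dialect (sorted)."""
    out = df.copy()
    if "tri" not in out.columns:
        # trinucleotide is informational; fall back to the context class
        out["tri"] = out["context"].map({"CG": "CGN", "CHG": "CHG", "CHH": "CHH"})
    out["unmeth"] = out["total"] - out["meth"]
    out = out.sort_values(["chrom", "pos", "strand"], kind="mergesort")
    out[["chrom", "pos", "strand", "meth", "unmeth", "context", "tri"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def merge_cg_dyads(df: pd.DataFrame) -> pd.DataFrame:
    """Merge the two strands of each CG dyad into one plus-strand record.

    The minus-strand cytosine of a CG dyad sits one base downstream of the
    plus-strand one; counts are summed. Non-CG records pass through. Off by
    default in the pipeline (the upstream convention is strand-specific).
    """
    cg = df[df["context"] == "CG"].copy()
    rest = df[df["context"] != "CG"]
    if cg.empty:
        return df.copy()
    anchor = np.where(cg["strand"] == "-", cg["pos"] - 1, cg["pos"])
    cg["_anchor"] = anchor
    agg = (
        cg.groupby(["chrom", "_anchor"], as_index=False)
        .agg(meth=("meth", "sum"), total=("total", "sum"), tri=("tri", "first"))
        .rename(columns={"_anchor": "pos"})
    )
    agg["strand"] = "+"
    agg["context"] = "CG"
    out = pd.concat([agg[["chrom", "pos", "strand", "context", "meth", "total", "tri"]
                         if "tri" in df.columns else
                         ["chrom", "pos", "strand", "context", "meth", "total"]],
                    rest], ignore_index=True)
    return out.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# intervals (BED6 / GFF3)
# ---------------------------------------------------------------------------


def read_intervals(path: str | Path, format: str = "BED") -> pd.DataFrame:
    """Read an interval file into a 0-based half-open interval frame.

    ``format`` is ``"BED"`` (BED3-BED6, passed through) or ``"GFF3"``
    (1-based closed coordinates, converted). A line that does not fit the
    requested dialect raises :class:`FormatError` naming the line.
    """
    path = Path(path)
    fmt = format.upper()
    if fmt not in ("BED", "GFF3"):
        raise ValueError(f"unknown interval format {format!r}")
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fmt == "BED":
                rows.append(_parse_bed_line(fields, path, lineno))
            else:
                rows.append(_parse_gff3_line(fields, path, lineno))
    cols = INTERVAL_COLUMNS + (["feature"] if fmt == "GFF3" else [])
    df = pd.DataFrame(rows, columns=cols)
    if df.empty:
        df = df.astype({"start": np.int64, "end": np.int64})
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def _parse_bed_line(fields: list[str], path, lineno: int) -> tuple:
    if not 3 <= len(fields) <= 6:
        raise FormatError(f"{path}:{lineno}: expected 3-6 BED columns, got {len(fields)}")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: non-integer BED coordinates") from exc
    if start >= end:
        raise FormatError(f"{path}:{lineno}: start >= end")
    name = fields[3] if len(fields) > 3 else "."
    score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
    strand = fields[5] if len(fields) > 5 else "."
    return (fields[0], start, end, name, score, strand)


def _parse_gff3_line(fields: list[str], path, lineno: int) -> tuple:
    if len(fields) != 9:
        raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
    try:
        start1, end1 = int(fields[3]), int(fields[4])
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: non-integer GFF3 coordinates") from exc
    start, end = start1 - 1, end1  # 1-based closed -> 0-based half-open
    if start >= end:
        raise FormatError(f"{path}:{lineno}: start >= end after coordinate conversion")
    attrs = dict(
        kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
    )
    name = attrs.get("Name", attrs.get("ID", "."))
    score = 0.0 if fields[5] == "." else float(fields[5])
    return (fields[0], start, end, name, score, fields[6], fields[2])


def write_intervals(df: pd.DataFrame, path: str | Path, format: str = "BED") -> None:
    """Write an interval frame as BED6 or GFF3 (deterministic sort order)."""
    fmt = format.upper()
    out = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    with open(path, "w") as fh:
        for row in out.itertuples(index=False):
            name = getattr(row, "name", ".")
            score = getattr(row, "score", 0.0)
            strand = getattr(row, "strand", ".") or "."
            if fmt == "BED":
                fh.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t{score:g}\t{strand}\n"
                )
            elif fmt == "GFF3":
                feature = getattr(row, "feature", "region")
                fh.write(
                    f"{row.chrom}\tmethylmem\t{feature}\t{row.start + 1}\t{row.end}\t"
                    f"{score:g}\t{strand}\t.\tID={name}\n"
                )
            else:
                raise ValueError(f"unknown interval format {format!r}")


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

SAMPLE_SHEET_COLUMNS = ["sample_id", "generation", "lineage", "treatment", "replicate"]


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Read the tab-separated sample sheet and validate the design grid."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: sample sheet missing required column(s): {', '.join(missing)}"
        )
    metas = [
        SampleMeta(
            sample_id=row.sample_id,
            generation=row.generation,
            lineage=row.lineage,
            treatment=row.treatment,
            replicate=int(row.replicate),
        )
        for row in df.itertuples(index=False)
    ]
    validate_design(metas)
    return metas


def validate_design(metas: Sequence[SampleMeta]) -> None:
    seen: dict[tuple, str] = {}
    ids = set()
    for m in metas:
        if m.sample_id in ids:
            raise FormatError(f"duplicate sample_id {m.sample_id!r}")
        ids.add(m.sample_id)
        if m.key() in seen:
            raise FormatError(
                f"duplicate design cell {m.key()} ({seen[m.key()]!r} and {m.sample_id!r})"
            )
        seen[m.key()] = m.sample_id


def write_sample_sheet(metas: Iterable[SampleMeta], path: str | Path) -> None:
    df = pd.DataFrame([asdict(m) for m in metas])[SAMPLE_SHEET_COLUMNS]
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# JSON helpers
# ---------------------------------------------------------------------------


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
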