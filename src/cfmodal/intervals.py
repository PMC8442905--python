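"""Genomic interval utilities: BED parsing, interval merging, half-open overlap.

All coordinates are 0-based half-open (BED convention).  These helpers back the
CpG exclusion masks, enhancer/promoter aggregation and feature-overlap tests;
they deliberately stay minimal — fixed-width windows and desk-scale BED files
do not need an interval tree.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end"]


class BedParseError(ValueError):
    """Malformed BED line; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = path
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file (optionally gzipped) into a chrom/start/end frame.

    Raises :class:`BedParseError` with the offending line number on malformed
    input.  Extra columns beyond the first three are ignored; track lines and
    comments are skipped.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    rows = []
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(path, lineno, "expected at least 3 tab-separated fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(path, lineno, "start/end are not integers") from None
            if start < 0 or end < start:
                raise BedParseError(path, lineno, f"invalid interval [{start}, {end})")
            rows.append((fields[0], start, end))
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def write_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def merge_intervals(df: pd.DataFrame) -> dict[str, np.ndarray]:
    """Merge overlapping/adjacent intervals; returns per-chrom (n, 2) arrays."""
    merged: dict[str, np.ndarray] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        ivals = grp[["start", "end"]].to_numpy(dtype=np.int64)
        ivals = ivals[np.argsort(ivals[:, 0], kind="stable")]
        out = []
        cur_s, cur_e = ivals[0]
        for s, e in ivals[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((cur_s, cur_e))
        merged[str(chrom)] = np.asarray(out, dtype=np.int64)
    return merged


def overlaps_any(
    chroms: pd.Series, starts: np.ndarray, ends: np.ndarray, merged: dict[str, np.ndarray]
) -> np.ndarray:
    """Boolean mask: does each query interval [start, end) overlap any merged interval?

    Half-open semantics: [s1, e1) and [s2, e2) overlap iff s1 < e2 and s2 < e1.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    hit = np.zeros(len(starts), dtype=bool)
    chroms = pd.Series(np.asarray(chroms, dtype=object))
    for chrom, idx in chroms.groupby(chroms).groups.items():
        ivals = merged.get(str(chrom))
        if ivals is None or len(ivals) == 0:
            continue
        idx = np.asarray(idx)
        qs, qe = starts[idx], ends[idx]
        # candidate: last interval with start < query end
        pos = np.searchsorted(ivals[:, 0], qe, side="left") - 1
        valid = pos >= 0
        cand_end = np.where(valid, ivals[np.clip(pos, 0, None), 1], 0)
        hit[idx] = valid & (cand_end > qs)
    return hit


def window_id(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


def parse_window_id(wid: str) -> tuple[str, int, int]:
    chrom, span = wid.rsplit(":", 1)
    start, end = span.split("-")
    return chrom, int(start), int(end)


def windows_frame(window_ids) -> pd.DataFrame:
    """Expand ``chrom:start-end`` ids into a BED3 frame indexed by id."""
    parsed = [parse_window_id(w) for w in window_ids]
    df = pd.DataFrame(parsed, columns=BED_COLUMNS, index=list(window_ids))
    return df
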