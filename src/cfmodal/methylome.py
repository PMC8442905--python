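"""Per-CpG call ingestion, exclusion masks, window methylation matrices, spike-in QC.

Input calls are bedGraph-style tables (chrom, start, end, n_meth, n_unmeth),
0-based half-open, one row per CpG.  ``n_meth`` counts converted (modified)
read bases: the assay reads 5mC/5hmC as T, so conversion at a methylated
control cytosine is evidence of methylation — the polarity is resolved by the
upstream caller and this module treats ``n_meth`` as the modified count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import merge_intervals, overlaps_any, window_id

CALL_COLUMNS = ["chrom", "start", "end", "n_meth", "n_unmeth"]

#: chromosomes removed by default together with the explicit masks
DEFAULT_SEX_CHROMS = frozenset({"chrX", "chrY"})


def read_calls(path) -> pd.DataFrame:
    """Read a bedGraph-style CpG call table (plain or gzipped TSV, no header)."""
    df = pd.read_csv(
        path,
        sep="\t",
        names=CALL_COLUMNS,
        header=None,
        dtype={"chrom": str, "start": np.int64, "end": np.int64,
               "n_meth": np.int64, "n_unmeth": np.int64},
        comment="#",
    )
    validate_calls(df)
    return df


def write_calls(df: pd.DataFrame, path) -> None:
    df[CALL_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def validate_calls(calls: pd.DataFrame) -> None:
    if (calls["n_meth"] < 0).any() or (calls["n_unmeth"] < 0).any():
        raise ValueError("negative counts in call table")
    if (calls["end"] <= calls["start"]).any():
        raise ValueError("non-positive-width CpG interval in call table")


def apply_masks(
    calls: pd.DataFrame,
    masks: list[pd.DataFrame] | None = None,
    sex_chroms=DEFAULT_SEX_CHROMS,
) -> pd.DataFrame:
    """Remove CpG sites overlapping any mask interval or on excluded chromosomes.

    Mirrors the preprocessing exclusion of common SNPs, blacklisted regions,
    centromeres and sex chromosomes.  Overlap is any-bp, half-open.
    """
    validate_calls(calls)
    keep = ~calls["chrom"].isin(set(sex_chroms))
    if masks:
        combined = pd.concat(masks, ignore_index=True)
        if len(combined):
            merged = merge_intervals(combined)
            hit = overlaps_any(calls["chrom"], calls["start"].to_numpy(),
                               calls["end"].to_numpy(), merged)
            keep &= ~hit
    return calls.loc[keep].reset_index(drop=True)


@dataclass
class WindowMethylationMatrix:
    """Sample-by-window methylation levels with per-window coverage.

    ``levels``/``coverage`` are samples x windows frames; window columns are
    ``chrom:start-end`` ids of fixed-width tiles starting at position 0.
    Levels are pooled ratios sum(n_meth)/sum(total) per window; a window with
    zero covered CpGs in a sample is NaN for that sample.
    """

    levels: pd.DataFrame
    coverage: pd.DataFrame
    window_width: int
    n_positions: pd.Series = field(repr=False)  # distinct CpG positions per window

    @property
    def windows(self) -> list[str]:
        return list(self.levels.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.levels.index)

    def to_tsv(self, path) -> None:
        # windows as rows, samples as columns
        self.levels.T.to_csv(path, sep="\t", index_label="window")

    @classmethod
    def from_tsv(cls, path, window_width: int) -> "WindowMethylationMatrix":
        levels = pd.read_csv(path, sep="\t", index_col="window").T
        cov = pd.DataFrame(np.nan, index=levels.index, columns=levels.columns)
        npos = pd.Series(np.nan, index=levels.columns)
        return cls(levels=levels, coverage=cov, window_width=window_width, n_positions=npos)


def window_levels(
    calls_by_sample: dict[str, pd.DataFrame],
    width: int,
    min_mean_cov: float = 2.0,
) -> WindowMethylationMatrix:
    """Aggregate per-CpG calls into fixed-width window methylation levels.

    Per window: level = sum(n_meth) / sum(n_meth + n_unmeth).  Mean CpG
    coverage of a window in a sample is total calls divided by the number of
    distinct CpG positions observed in the window across the cohort; windows
    whose cohort-mean coverage falls below ``min_mean_cov`` are dropped
    (default 2, the standard low-coverage window filter).
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    if not calls_by_sample:
        raise ValueError("no samples provided")

    frames = []
    for sample, calls in calls_by_sample.items():
        validate_calls(calls)
        df = calls[CALL_COLUMNS].copy()
        df["sample"] = sample
        frames.append(df)
    allc = pd.concat(frames, ignore_index=True)
    allc["win_start"] = (allc["start"] // width) * width
    allc["total"] = allc["n_meth"] + allc["n_unmeth"]
    allc["wid"] = [window_id(c, s, s + width)
                   for c, s in zip(allc["chrom"], allc["win_start"])]

    # distinct CpG positions per window (cohort union)
    n_positions = (allc.drop_duplicates(["wid", "chrom", "start"])
                   .groupby("wid").size())

    g = allc.groupby(["sample", "wid"], sort=False)
    agg = g.agg(meth=("n_meth", "sum"), total=("total", "sum")).reset_index()

    meth = agg.pivot(index="sample", columns="wid", values="meth")
    total = agg.pivot(index="sample", columns="wid", values="total")
    meth = meth.reindex(index=list(calls_by_sample)).fillna(0.0)
    total = total.reindex(index=list(calls_by_sample)).fillna(0.0)

    coverage = total.div(n_positions, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        levels = meth / total
    levels = levels.where(total > 0)  # zero covered CpGs -> missing

    keep = coverage.mean(axis=0) >= min_mean_cov
    kept = sorted(keep.index[keep])
    if not kept:
        raise ValueError("no windows pass the coverage filter")
    return WindowMethylationMatrix(
        levels=levels[kept],
        coverage=coverage[kept],
        window_width=width,
        n_positions=n_positions[kept],
    )


@dataclass(frozen=True)
class SpikeInQC:
    """Spike-in control rates: conversion on the methylated control, false
    positives on the unmodified control."""

    conversion_rate: float
    false_positive_rate: float
    n_meth_calls: int
    n_unmod_calls: int

    def to_dict(self) -> dict:
        return {
            "conversion_rate": self.conversion_rate,
            "false_positive_rate": self.false_positive_rate,
            "n_meth_calls": self.n_meth_calls,
            "n_unmod_calls": self.n_unmod_calls,
        }


def spikein_qc(meth_control_calls: pd.DataFrame, unmod_control_calls: pd.DataFrame) -> SpikeInQC:
    """Estimate conversion and false-positive rates from spike-in controls.

    Conversion rate: converted calls / total calls at CpG-methylated control
    sites (e.g. CpG-methylated lambda DNA).  False-positive rate: converted
    calls / total calls at unmodified control cytosines.
    """
    rates = []
    totals = []
    for tbl, name in ((meth_control_calls, "methylated"), (unmod_control_calls, "unmodified")):
        if tbl is None or len(tbl) == 0:
            raise ValueError(f"empty {name}-control call table")
        conv = int(tbl["n_meth"].sum())
        tot = conv + int(tbl["n_unmeth"].sum())
        if tot == 0:
            raise ValueError(f"zero total calls in {name} control; rate undefined")
        rates.append(conv / tot)
        totals.append(tot)
    return SpikeInQC(
        conversion_rate=rates[0],
        false_positive_rate=rates[1],
        n_meth_calls=totals[0],
        n_unmod_calls=totals[1],
    )


def qc_gate(qc: SpikeInQC, min_conversion: float = 0.90) -> bool:
    """Keep a sample iff its conversion rate is >= the threshold (default 90%)."""
    return qc.conversion_rate >= min_conversion
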