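"""cfDNA fragmentomics: length histograms, 10-bp bin fractions, group tests,
and a leave-one-out classifier on the long-fragment (300-500 bp) bins.

Plasma cfDNA is nucleosome-protected, so its length distribution has a
dominant mode at ~167 bp (chromatosome), a dinucleosomal secondary peak near
320 bp and a 10-bp periodicity below the mode; tumours shed shorter fragments,
shifting mass from the long to the short range.  All bins are half-open
[lo, lo+width); fractions are taken over the full considered length window so
that long-bin fractions remain comparable across samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import LOOResult, ModelConfig, loo_predict

logger = logging.getLogger(__name__)

DEFAULT_LENGTH_WINDOW = (1, 1000)
DEFAULT_SHORT_RANGE = (70, 150)
DEFAULT_LONG_RANGE = (300, 500)


def extract_lengths(source, length_window: tuple[int, int] = DEFAULT_LENGTH_WINDOW,
                    exclude_duplicates: bool = True) -> np.ndarray:
    """Fragment lengths from an alignment file or a one-column length table.

    For SAM/BAM, the absolute paired-end template length is used, taken from
    read 1 of each proper pair so pairs are counted once; duplicate-marked
    records are skipped by default, unpaired records are skipped and counted.
    Any other input is read as a one-column TSV of integer lengths.
    """
    path = str(source)
    if path.endswith((".sam", ".bam", ".cram")):
        import pysam
        lengths = []
        skipped = 0
        with pysam.AlignmentFile(path) as fh:
            for rec in fh:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                if exclude_duplicates and rec.is_duplicate:
                    continue
                if not rec.is_paired or not rec.is_proper_pair:
                    skipped += 1
                    continue
                if not rec.is_read1:
                    continue
                lengths.append(abs(rec.template_length))
        if skipped:
            logger.info("skipped %d unpaired/improper records", skipped)
        arr = np.asarray(lengths, dtype=np.int64)
    else:
        arr = pd.read_csv(source, sep="\t", header=None)[0].to_numpy(dtype=np.int64)
    lo, hi = length_window
    arr = arr[(arr >= lo) & (arr <= hi)]
    if arr.size == 0:
        raise ValueError("no fragments in the configured length window")
    return arr


def length_histogram(lengths: np.ndarray, length_window=DEFAULT_LENGTH_WINDOW) -> pd.Series:
    """Count per integer length over the full window (zeros included)."""
    lo, hi = length_window
    lengths = np.asarray(lengths, dtype=np.int64)
    if lengths.size == 0:
        raise ValueError("empty length list")
    counts = np.bincount(lengths - lo, minlength=hi - lo + 1)[: hi - lo + 1]
    return pd.Series(counts, index=np.arange(lo, hi + 1), name="count")


@dataclass
class FragmentProfile:
    histogram: pd.Series        # count per integer length
    bin_fractions: pd.Series    # fraction per 10-bp bin over the full window
    short_fraction: float       # fraction of fragments in the short range
    long_fraction: float        # fraction in the long range

    @property
    def modal_length(self) -> int:
        return int(self.histogram.idxmax())

    def long_bin_fractions(self, long_range=DEFAULT_LONG_RANGE) -> pd.Series:
        lo, hi = long_range
        keep = [b for b in self.bin_fractions.index if lo <= b < hi]
        return self.bin_fractions.loc[keep]


def bin_fractions(
    histogram: pd.Series,
    bin_width: int = 10,
    short_range: tuple[int, int] = DEFAULT_SHORT_RANGE,
    long_range: tuple[int, int] = DEFAULT_LONG_RANGE,
) -> FragmentProfile:
    """10-bp bin fractions plus short/long summary fractions.

    Bins are [lo, lo+width) aligned to multiples of ``bin_width`` (so a
    300-bp fragment falls in [300, 310)); each bin's fraction uses the total
    fragment count over the full length window as denominator, so fractions
    across all bins sum to 1.  Short/long defaults are [70, 150) and
    [300, 500).
    """
    total = int(histogram.sum())
    if total == 0:
        raise ValueError("zero fragments in histogram")
    lengths = histogram.index.to_numpy()
    binstart = (lengths // bin_width) * bin_width
    counts = histogram.groupby(binstart).sum()
    grid = np.arange(binstart.min(), binstart.max() + bin_width, bin_width)
    frac = counts.reindex(grid, fill_value=0) / total

    def range_fraction(rng):
        a, b = rng
        sel = (lengths >= a) & (lengths < b)
        return float(histogram[sel].sum() / total)

    return FragmentProfile(
        histogram=histogram,
        bin_fractions=frac,
        short_fraction=range_fraction(short_range),
        long_fraction=range_fraction(long_range),
    )


def profile_sample(lengths: np.ndarray, length_window=DEFAULT_LENGTH_WINDOW,
                   **kwargs) -> FragmentProfile:
    """Convenience: histogram + bin fractions from raw lengths."""
    hist = length_histogram(lengths, length_window=length_window)
    return bin_fractions(hist, **kwargs)


def group_test(values_by_group: dict[str, np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) across >=2 groups of per-sample values.

    All-identical values return (0, 1) rather than an undefined statistic.
    """
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 groups with >=2 values each")
    flat = np.concatenate(groups)
    if np.ptp(flat) == 0:
        return 0.0, 1.0
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def long_bin_matrix(profiles: dict[str, FragmentProfile],
                    long_range=DEFAULT_LONG_RANGE) -> pd.DataFrame:
    """Sample x bin matrix of long-fragment 10-bp bin fractions (the 20
    features in [300, 500))."""
    rows = {s: p.long_bin_fractions(long_range) for s, p in profiles.items()}
    df = pd.DataFrame(rows).T
    df.columns = [f"frag_{int(b)}_{int(b) + 10}" for b in df.columns]
    return df


def frag_model(
    bin_matrix: pd.DataFrame,
    labels: pd.Series,
    config: ModelConfig = ModelConfig(),
    positive=None,
) -> LOOResult:
    """LOO classifier on the long-fragment bin fractions (no selection step)."""
    cfg = ModelConfig(**{**config.__dict__, "select": False})
    return loo_predict(bin_matrix, labels, config=cfg, positive=positive)
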