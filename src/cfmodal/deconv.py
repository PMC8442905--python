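"""Tissue-of-origin deconvolution from an enhancer-aggregated methylation atlas.

Reference construction follows the one-versus-all tissue-specific DMR scheme
of array/WGBS deconvolution atlases: per tissue, rank regions by the absolute
difference between the tissue median and the median of the remaining tissues,
require consistent methylation across replicates, keep the top k in each
direction, and additionally add the regions that best separate each tissue
from its two most correlated neighbours.  Per-sample tissue contributions x
are then the nonnegative least-squares solution of min ||A x - y||_2, x >= 0,
where A is the region-by-tissue reference and y the sample's observed
methylation ratios over the same regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .intervals import merge_intervals, overlaps_any, window_id
from .classify import LOOResult, ModelConfig, loo_predict


def aggregate_enhancers(
    calls_by_sample: dict[str, pd.DataFrame],
    enhancers: pd.DataFrame,
    min_cpgs: int = 1,
) -> pd.DataFrame:
    """Pool CpG calls within each enhancer region: region x sample levels.

    Level = sum(n_meth) / sum(total) over CpGs contained in the region
    (any-bp overlap, half-open).  Regions with fewer than ``min_cpgs``
    covered CpGs in a sample are missing for that sample.  Overlapping
    enhancers are merged first so every CpG maps to at most one region.
    """
    if enhancers is None or len(enhancers) == 0:
        raise ValueError("empty enhancer set")
    merged = merge_intervals(enhancers)
    region_rows = [(c, s, e) for c, arr in merged.items() for s, e in arr]
    region_ids = [window_id(c, s, e) for c, s, e in region_rows]

    out = {}
    for sample, calls in calls_by_sample.items():
        levels = pd.Series(np.nan, index=region_ids)
        for chrom, grp in calls.groupby("chrom", sort=False):
            ivals = merged.get(str(chrom))
            if ivals is None:
                continue
            starts = grp["start"].to_numpy()
            pos = np.searchsorted(ivals[:, 0], grp["end"].to_numpy(), side="left") - 1
            inside = (pos >= 0) & (ivals[np.clip(pos, 0, None), 1] > starts)
            g = grp.loc[inside].copy()
            g["region"] = [window_id(chrom, *ivals[p]) for p in pos[inside]]
            g["total"] = g["n_meth"] + g["n_unmeth"]
            agg = g.groupby("region").agg(
                meth=("n_meth", "sum"), total=("total", "sum"), ncpg=("start", "nunique"))
            ok = (agg["ncpg"] >= min_cpgs) & (agg["total"] > 0)
            levels.loc[agg.index[ok]] = agg.loc[ok, "meth"] / agg.loc[ok, "total"]
        out[sample] = levels
    return pd.DataFrame(out)


def tissue_specific_dmrs(
    atlas_samples: pd.DataFrame,
    tissue_labels: pd.Series,
    k_per_tissue: int = 100,
    consistency_max_spread: float = 0.25,
    min_diff: float = 0.1,
) -> dict[str, set[str]]:
    """Select tissue-specific regions from a region x replicate-sample matrix.

    Per tissue: one-versus-all |median difference| ranking with a replicate
    consistency filter (within-tissue max - min <= ``consistency_max_spread``)
    and a minimum-difference floor, top ``k_per_tissue`` hyper- and
    hypomethylated regions each; plus the same top-k selection against the
    two most Pearson-correlated tissues.  Returns tissue -> selected regions.
    """
    tissues = sorted(pd.unique(tissue_labels))
    if len(tissues) < 2:
        raise ValueError("need at least 2 tissue groups")
    med = pd.DataFrame({t: atlas_samples[tissue_labels.index[tissue_labels == t]]
                        .median(axis=1) for t in tissues})
    spread = pd.DataFrame({t: atlas_samples[tissue_labels.index[tissue_labels == t]]
                           .pipe(lambda d: d.max(axis=1) - d.min(axis=1)) for t in tissues})
    corr = med.corr()

    def top_by_diff(diff: pd.Series, consistent: pd.Series) -> set[str]:
        picked: set[str] = set()
        for signed in (diff, -diff):
            ok = consistent & (signed >= min_diff)
            picked |= set(signed[ok].sort_values(ascending=False).head(k_per_tissue).index)
        return picked

    selected: dict[str, set[str]] = {}
    for t in tissues:
        others = [u for u in tissues if u != t]
        consistent = spread[t] <= consistency_max_spread
        diff = med[t] - med[others].median(axis=1)
        picked = top_by_diff(diff, consistent)
        # regions separating t from its two most correlated tissues
        neighbours = corr[t].drop(index=t).sort_values(ascending=False).index[:2]
        for u in neighbours:
            picked |= top_by_diff(med[t] - med[u], consistent)
        if not picked:
            import warnings
            warnings.warn(f"no regions passed selection for tissue {t!r}", stacklevel=2)
        selected[t] = picked
    return selected


@dataclass
class TissueReferenceAtlas:
    """Region x tissue-group reference matrix A with selection provenance."""

    A: pd.DataFrame                      # selected regions x tissues, in [0, 1]
    tissue_groups: list[str]
    selected_regions: dict[str, set[str]]
    tissue_correlations: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.A.to_csv(path, sep="\t", index_label="region")


def build_reference(
    atlas_samples: pd.DataFrame,
    tissue_labels: pd.Series,
    selected_regions: dict[str, set[str]],
) -> TissueReferenceAtlas:
    """A = per-tissue median over replicates, restricted to selected regions."""
    tissues = sorted(pd.unique(tissue_labels))
    regions = sorted(set().union(*selected_regions.values()))
    if not regions:
        raise ValueError("no selected regions")
    sub = atlas_samples.loc[regions]
    A = pd.DataFrame({t: sub[tissue_labels.index[tissue_labels == t]].median(axis=1)
                      for t in tissues})
    return TissueReferenceAtlas(
        A=A,
        tissue_groups=tissues,
        selected_regions=selected_regions,
        tissue_correlations=A.corr(),
    )


@dataclass
class TissueContribution:
    """NNLS tissue weights for one sample, raw and sum-normalized."""

    x: pd.Series
    x_normalized: pd.Series
    residual_norm: float
    n_regions_used: int


def nnls_deconv(atlas: TissueReferenceAtlas, y: pd.Series) -> TissueContribution:
    """Estimate tissue contributions: min ||A x - y||_2 subject to x >= 0.

    Regions missing in the sample (or the atlas) are dropped pairwise before
    the fit; the number of regions actually used is recorded.
    """
    common = atlas.A.index.intersection(y.index)
    A = atlas.A.loc[common]
    yv = y.loc[common]
    ok = yv.notna() & A.notna().all(axis=1)
    if not ok.any():
        raise ValueError("no shared non-missing regions between atlas and sample")
    x, rnorm = optimize.nnls(A.loc[ok].to_numpy(), yv.loc[ok].to_numpy())
    x = pd.Series(x, index=atlas.A.columns)
    total = x.sum()
    return TissueContribution(
        x=x,
        x_normalized=x / total if total > 0 else x * 0.0,
        residual_norm=float(rnorm),
        n_regions_used=int(ok.sum()),
    )


def deconvolve_samples(atlas: TissueReferenceAtlas, sample_levels: pd.DataFrame) -> pd.DataFrame:
    """Run NNLS for each column of a region x sample matrix; rows = samples,
    columns = tissue groups (normalized contributions)."""
    rows = {s: nnls_deconv(atlas, sample_levels[s]).x_normalized
            for s in sample_levels.columns}
    return pd.DataFrame(rows).T


def compare_contribution(
    values_by_group: dict[str, np.ndarray],
    test: str = "t",
    paired: bool = False,
) -> tuple[float, float]:
    """Two-group test on one tissue's contribution values.

    ``test='t'`` is a Welch t test by default (``paired=True`` switches to a
    paired t test); ``test='kruskal'`` uses Kruskal-Wallis.  Returns
    (statistic, p).
    """
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    if any(len(g) < 2 for g in groups):
        raise ValueError("need at least 2 values per group")
    # degenerate case: no variation anywhere -> t (or H) is 0, p is 1
    if all(np.ptp(g) == 0 for g in groups) and groups[0][0] == groups[1][0]:
        return 0.0, 1.0
    if test == "t":
        if paired:
            res = stats.ttest_rel(groups[0], groups[1])
        else:
            res = stats.ttest_ind(groups[0], groups[1], equal_var=False)
        return float(res.statistic), float(res.pvalue)
    if test == "kruskal":
        res = stats.kruskal(*groups)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def contribution_model(
    contributions: pd.DataFrame,
    labels: pd.Series,
    config: ModelConfig = ModelConfig(),
    positive=None,
) -> LOOResult:
    """LOO classification using the tissue-contribution matrix as features
    (no feature-selection step)."""
    cfg = ModelConfig(**{**config.__dict__, "select": False})
    return loo_predict(contributions, labels, config=cfg, positive=positive)
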