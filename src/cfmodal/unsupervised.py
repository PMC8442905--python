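"""Unsupervised structure: PCA of window methylation, PC-correlated windows,
and overlap enrichment of window sets in genomic feature classes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .intervals import merge_intervals, overlaps_any, windows_frame
from .methylome import WindowMethylationMatrix


@dataclass
class PCAResult:
    scores: pd.DataFrame           # samples x components
    loadings: pd.DataFrame         # windows x components
    explained_variance: np.ndarray  # variance ratio per component


def pca(matrix: WindowMethylationMatrix, n_components: int = 10, scale: bool = True) -> PCAResult:
    """Principal components of the window methylation matrix.

    Windows with any missing value (and, when scaling, constant windows) are
    dropped before the decomposition.  Columns are centered and by default
    scaled to unit variance.  The sign of each component is fixed by making
    its largest-magnitude loading positive, so results are reproducible.
    """
    X = matrix.levels.dropna(axis=1)
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 samples")
    if scale:
        sd = X.std(axis=0, ddof=0)
        X = X.loc[:, sd > 0]
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X.to_numpy())
    loadings = model.components_.T  # windows x components
    for j in range(loadings.shape[1]):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=X.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=X.columns, columns=comp_names),
        explained_variance=model.explained_variance_ratio_,
    )


def pc_correlates(
    matrix: WindowMethylationMatrix,
    pca_result: PCAResult,
    component: int = 1,
    proba: float = 0.01,
    top_n: int = 200,
) -> pd.DataFrame:
    """Windows most correlated with a principal component.

    Pearson-correlates each window's levels with the sample scores of the
    requested component (1-based), keeps windows whose correlation-test p
    (t-transform of r) is below ``proba``, and returns the ``top_n`` windows
    ranked by absolute correlation — the dimdesc-style contributor list.
    Constant windows have undefined correlation and are excluded.
    """
    name = f"PC{component}"
    if name not in pca_result.scores.columns:
        raise ValueError(f"component {component} not in PCA result")
    y = pca_result.scores[name]
    X = matrix.levels.dropna(axis=1).loc[y.index]
    n = len(y)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    ok = (sx > 0) & (sy > 0)
    r = (xc.loc[:, ok] * yc.to_numpy()[:, None]).sum(axis=0) / (sx[ok] * sy)
    r = r.clip(-1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    out = pd.DataFrame({"window": r.index, "r": r.to_numpy(), "p_value": p})
    out = out[out["p_value"] < proba]
    out = out.reindex(out["r"].abs().sort_values(ascending=False).index)
    return out.head(top_n).reset_index(drop=True)


def fisher_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Sum of hypergeometric probabilities, over the support fixed by the
    margins, that do not exceed the observed table's probability (with the
    customary small relative tolerance for ties).
    """
    from scipy.special import gammaln
    n1, n2, k = a + b, c + d, a + c
    n = n1 + n2
    x = np.arange(max(0, k - n2), min(n1, k) + 1)
    logp = (
        gammaln(n1 + 1) - gammaln(x + 1) - gammaln(n1 - x + 1)
        + gammaln(n2 + 1) - gammaln(k - x + 1) - gammaln(n2 - k + x + 1)
        - (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))
    )
    pmf = np.exp(logp)
    p_obs = pmf[x == a][0]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-9)].sum()))


@dataclass(frozen=True)
class EnrichmentResult:
    feature_name: str
    contingency: tuple[int, int, int, int]  # a, b, c, d
    odds_ratio: float
    p_value: float


def fisher_overlap(
    query: set[str],
    background: set[str],
    feature: pd.DataFrame,
    feature_name: str = "feature",
) -> EnrichmentResult:
    """Two-sided Fisher exact test of window-set overlap with a feature BED.

    Contingency over windows (fixed-width, disjoint, so window counts are
    well-defined): a = query windows overlapping the feature by >=1 bp,
    b = query not overlapping, c = background-minus-query overlapping,
    d = the remainder.  The sample odds ratio (a*d)/(b*c) is reported as
    inf/0 when a margin cell is zero; p remains defined.
    """
    if not query:
        raise ValueError("empty query window set")
    if not set(query) <= set(background):
        raise ValueError("query must be a subset of background")
    if feature is None or len(feature) == 0:
        raise ValueError("empty feature set")
    merged = merge_intervals(feature)

    def n_overlap(wids: list[str]) -> int:
        df = windows_frame(wids)
        hit = overlaps_any(df["chrom"], df["start"].to_numpy(), df["end"].to_numpy(), merged)
        return int(hit.sum())

    q = sorted(query)
    rest = sorted(set(background) - set(query))
    a = n_overlap(q)
    b = len(q) - a
    c = n_overlap(rest) if rest else 0
    d = len(rest) - c
    p = fisher_two_sided_p(a, b, c, d)
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = np.inf
    else:
        odds = np.nan
    return EnrichmentResult(feature_name=feature_name, contingency=(a, b, c, d),
                            odds_ratio=float(odds), p_value=float(p))
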