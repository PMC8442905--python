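"""Two-class prediction from differential methylation with leave-one-out CV.

The core discipline here is that differentially methylated region (DMR)
selection happens *inside* each leave-one-out fold, on training samples only —
selecting features on the full cohort before cross-validation leaks the
held-out label and inflates the apparent AUC.  Within a fold the selected DMR
levels feed an L1-regularized logistic model whose penalty is chosen by
internal cross-validation (a cv.glmnet-style fit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .methylome import WindowMethylationMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelConfig:
    """Knobs for DMR selection and the regularized logistic fit.

    p_thresh/diff_thresh are the standard within-fold DMR cutoffs
    (t-test p < 0.002, |mean methylation difference| > 0.05).  l1_ratio = 1.0
    is a lasso-leaning elastic net; the penalty grid is searched by internal
    stratified CV with at most ``max_cv_folds`` folds (capped at the smallest
    training class size).
    """

    p_thresh: float = 0.002
    diff_thresh: float = 0.05
    equal_var: bool = False      # Welch by default
    l1_ratio: float = 1.0
    n_penalties: int = 10
    max_cv_folds: int = 10
    seed: int = 0
    select: bool = True          # False: use the feature matrix as-is


def find_dmrs(
    levels_a: pd.DataFrame,
    levels_b: pd.DataFrame,
    candidate_windows=None,
    p_thresh: float = 0.002,
    diff_thresh: float = 0.05,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Differentially methylated windows between two sample groups.

    Two-sample t test (Welch by default) per candidate window; a window is a
    DMR when p < ``p_thresh`` and |mean(A) - mean(B)| > ``diff_thresh``.
    Windows with missing values in any used sample are skipped.  Returns a
    frame with window, mean_diff (A - B), p_value and direction (hyper/hypo
    in A), sorted by p.
    """
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("need at least 2 samples per group for a t test")
    if candidate_windows is not None:
        cols = [w for w in levels_a.columns if w in set(candidate_windows)]
    else:
        cols = list(levels_a.columns)
    A = levels_a[cols]
    B = levels_b[cols]
    ok = A.notna().all(axis=0) & B.notna().all(axis=0)
    A, B = A.loc[:, ok], B.loc[:, ok]
    if A.shape[1] == 0:
        return pd.DataFrame(columns=["window", "mean_diff", "p_value", "direction"])
    import warnings
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant windows trigger scipy precision-loss warnings; their
        # p-values are treated as 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(A.to_numpy(), B.to_numpy(), axis=0, equal_var=equal_var)
    diff = A.mean(axis=0).to_numpy() - B.mean(axis=0).to_numpy()
    p = np.where(np.isnan(p), 1.0, p)
    sel = (p < p_thresh) & (np.abs(diff) > diff_thresh)
    out = pd.DataFrame({
        "window": A.columns[sel],
        "mean_diff": diff[sel],
        "p_value": p[sel],
    })
    out["direction"] = np.where(out["mean_diff"] > 0, "hyper", "hypo")
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)


@dataclass
class LOOResult:
    """Held-out scores from leave-one-out cross-validation."""

    scores: pd.Series                      # per-sample P(positive class)
    labels: pd.Series                      # 1 = positive class
    fold_dmr_counts: pd.Series
    dmr_union: set = field(default_factory=set)
    degenerate_folds: list = field(default_factory=list)

    @property
    def auc(self) -> float:
        return roc_auc(self.scores, self.labels).auc


def _binary_labels(labels: pd.Series, positive: str | int | None) -> pd.Series:
    if positive is None:
        uniq = sorted(pd.unique(labels))
        if len(uniq) != 2:
            raise ValueError("labels must have exactly 2 classes (or pass positive=)")
        positive = uniq[1]
    return (labels == positive).astype(int)


def _fit_penalized_logistic(X: np.ndarray, y: np.ndarray, config: ModelConfig):
    n_folds = min(config.max_cv_folds, int(np.bincount(y).min()))
    n_folds = max(n_folds, 2)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=config.seed)
    clf = LogisticRegressionCV(
        Cs=np.logspace(-2, 2, config.n_penalties),
        cv=cv,
        l1_ratios=(config.l1_ratio,),
        solver="liblinear" if config.l1_ratio >= 1.0 else "saga",
        scoring="neg_log_loss",
        max_iter=2000,
        random_state=config.seed,
        use_legacy_attributes=False,
    )
    model = Pipeline([("scale", StandardScaler()), ("logistic", clf)])
    model.fit(X, y)
    return model


def _prepare_features(levels: pd.DataFrame, windows, fill: pd.Series | None = None):
    X = levels[list(windows)]
    means = fill if fill is not None else X.mean(axis=0)
    return X.fillna(means), means


def loo_predict(
    matrix: WindowMethylationMatrix | pd.DataFrame,
    labels: pd.Series,
    candidate_windows=None,
    config: ModelConfig = ModelConfig(),
    positive=None,
) -> LOOResult:
    """Leave-one-out prediction with within-fold DMR selection.

    For each fold the held-out sample is scored by a penalized logistic model
    trained on the remaining samples, using DMRs selected from those samples
    only.  A fold in which no window passes the DMR thresholds is scored by
    the training-set class prior and logged as degenerate.  With
    ``config.select`` False the feature matrix is used as-is (e.g. tissue
    contributions or fragment-length bins).
    """
    levels = matrix.levels if isinstance(matrix, WindowMethylationMatrix) else matrix
    labels = labels.loc[levels.index]
    y = _binary_labels(labels, positive)
    if y.value_counts().min() < 2:
        raise ValueError("need at least 2 samples per class")

    scores = {}
    fold_counts = {}
    union: set = set()
    degenerate = []
    for held in levels.index:
        train_idx = levels.index != held
        tr_levels, tr_y = levels.loc[train_idx], y.loc[train_idx]
        if config.select:
            dmrs = find_dmrs(
                tr_levels[tr_y == 1], tr_levels[tr_y == 0],
                candidate_windows=candidate_windows,
                p_thresh=config.p_thresh, diff_thresh=config.diff_thresh,
                equal_var=config.equal_var,
            )
            feats = list(dmrs["window"])
        else:
            feats = list(levels.columns if candidate_windows is None else candidate_windows)
        fold_counts[held] = len(feats)
        union.update(feats)
        if not feats:
            scores[held] = float(tr_y.mean())
            degenerate.append(held)
            logger.warning("fold %s: no DMRs selected; scored by class prior", held)
            continue
        Xtr, means = _prepare_features(tr_levels, feats)
        model = _fit_penalized_logistic(Xtr.to_numpy(), tr_y.to_numpy(), config)
        Xte, _ = _prepare_features(levels.loc[[held]], feats, fill=means)
        scores[held] = float(model.predict_proba(Xte.to_numpy())[0, 1])

    return LOOResult(
        scores=pd.Series(scores).loc[levels.index],
        labels=y,
        fold_dmr_counts=pd.Series(fold_counts).loc[levels.index],
        dmr_union=union,
        degenerate_folds=degenerate,
    )


def refit_on_all(
    matrix: WindowMethylationMatrix | pd.DataFrame,
    labels: pd.Series,
    features,
    config: ModelConfig = ModelConfig(),
    positive=None,
):
    """Fit one penalized logistic model on all primary samples over ``features``
    (typically the union of per-fold DMRs).  Returns (model, feature_means)."""
    levels = matrix.levels if isinstance(matrix, WindowMethylationMatrix) else matrix
    y = _binary_labels(labels.loc[levels.index], positive)
    X, means = _prepare_features(levels, list(features))
    model = _fit_penalized_logistic(X.to_numpy(), y.to_numpy(), config)
    return model, means


def score_external(
    model,
    feature_means: pd.Series,
    external_levels: pd.DataFrame,
    min_feature_fraction: float = 0.5,
) -> pd.Series:
    """Score an independent sample set with a refit-on-all model.

    Model features absent from the external matrix (or missing per sample)
    are imputed with the training means; if fewer than
    ``min_feature_fraction`` of features are present at all, scoring refuses.
    """
    feats = list(feature_means.index)
    present = [f for f in feats if f in external_levels.columns
               and external_levels[f].notna().any()]
    frac = len(present) / len(feats)
    logger.info("external scoring: %.0f%% of model features present", 100 * frac)
    if frac < min_feature_fraction:
        raise ValueError(
            f"only {frac:.0%} of model features present in external data "
            f"(minimum {min_feature_fraction:.0%})")
    X = external_levels.reindex(columns=feats).fillna(feature_means)
    return pd.Series(model.predict_proba(X.to_numpy())[:, 1], index=external_levels.index)


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpf: np.ndarray   # false-positive fraction
    tpf: np.ndarray   # true-positive fraction
    auc: float


def roc_auc(scores: pd.Series | np.ndarray, labels: pd.Series | np.ndarray) -> ROCCurve:
    """ROC curve and AUC; AUC is the Mann-Whitney probability with ties = 1/2.

    Computed from midranks: AUC = (R+ - n+(n+ + 1)/2) / (n+ n-), identical to
    averaging over all positive-negative score pairs with ties counted half.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    # curve: sweep thresholds from high to low
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(1 - y_sorted)[distinct]
    thresholds = s_sorted[distinct]
    return ROCCurve(
        thresholds=np.r_[np.inf, thresholds],
        fpf=np.r_[0.0, fp / n_neg],
        tpf=np.r_[0.0, tp / n_pos],
        auc=float(auc),
    )


def dmr_stability(ref_dmrs: set, downsampled_dmrs: set) -> float:
    """Fraction of reference DMRs recovered in a down-sampled run:
    |ref ∩ downsampled| / |ref|."""
    if not ref_dmrs:
        raise ValueError("reference DMR set is empty")
    return len(set(ref_dmrs) & set(downsampled_dmrs)) / len(set(ref_dmrs))


def leaky_loo_predict(
    matrix: WindowMethylationMatrix | pd.DataFrame,
    labels: pd.Series,
    candidate_windows=None,
    config: ModelConfig = ModelConfig(),
    positive=None,
    top_k: int = 20,
) -> LOOResult:
    """Deliberately leaky control: DMRs chosen on ALL samples (top ``top_k``
    by t-test p), then LOO over the fixed feature set.

    Exists only to demonstrate selection leakage — on label-free null data it
    produces inflated AUCs whereas :func:`loo_predict` stays near 0.5.  Never
    use for real inference.
    """
    levels = matrix.levels if isinstance(matrix, WindowMethylationMatrix) else matrix
    y = _binary_labels(labels.loc[levels.index], positive)
    dmrs = find_dmrs(levels[y == 1], levels[y == 0], candidate_windows=candidate_windows,
                     p_thresh=1.0, diff_thresh=0.0, equal_var=config.equal_var)
    feats = list(dmrs["window"].head(top_k))
    cfg = ModelConfig(**{**config.__dict__, "select": False})
    return loo_predict(levels, y, candidate_windows=feats, config=cfg, positive=1)
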