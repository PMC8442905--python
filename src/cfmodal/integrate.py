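"""Three-class (control / HCC-like / PDAC-like) prediction per modality and
integration by averaging class probabilities across modalities.

Each modality (methylation DMRs, tissue contributions, fragment-length bins)
is classified independently with a linear SVM in leave-one-out CV — for the
methylation modality the top-k DMRs of each pairwise group comparison are
re-selected inside every fold — and the three per-sample probability vectors
are averaged; the final call is the class with the maximum mean probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


def pairwise_top_dmrs(
    levels: pd.DataFrame,
    labels: pd.Series,
    k: int = 5,
    candidate_windows=None,
) -> list[str]:
    """Union of the top-``k`` windows by t-test p from each pairwise comparison.

    For the three group pairs, every candidate window is t-tested and ranked
    by p; the top ``k`` per pair are kept (pure p-rank, no thresholds), so at
    most 3k features are returned.  Windows with missing values are skipped.
    """
    labels = labels.loc[levels.index]
    groups = sorted(pd.unique(labels))
    if any((labels == g).sum() < 2 for g in groups):
        raise ValueError("need at least 2 samples per group")
    if candidate_windows is not None:
        levels = levels[[w for w in levels.columns if w in set(candidate_windows)]]
    levels = levels.dropna(axis=1)
    feats: list[str] = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            A = levels[labels == ga].to_numpy()
            B = levels[labels == gb].to_numpy()
            import warnings
            with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                _, p = stats.ttest_ind(A, B, axis=0, equal_var=False)
            p = np.where(np.isnan(p), 1.0, p)
            order = np.argsort(p, kind="stable")[:k]
            feats.extend(levels.columns[order])
    seen = set()
    return [f for f in feats if not (f in seen or seen.add(f))]


@dataclass
class ModalityPrediction:
    """Per-sample 3-class probability vectors for one modality."""

    modality: str
    probs: pd.DataFrame     # samples x classes, rows sum to 1
    classes: list[str]

    @property
    def predicted(self) -> pd.Series:
        return self.probs.idxmax(axis=1)

    def accuracy(self, truth: pd.Series) -> float:
        return float((self.predicted == truth.loc[self.probs.index]).mean())


def modality_loo(
    features: pd.DataFrame,
    labels: pd.Series,
    modality: str = "methylation",
    select_k: int | None = None,
    candidate_windows=None,
    seed: int = 0,
) -> ModalityPrediction:
    """Leave-one-out 3-class prediction with a linear SVM.

    With ``select_k`` set, pairwise top-k DMR selection runs on the training
    rows of each fold only; otherwise the feature matrix is used raw (tissue
    and fragmentation modalities).  Probabilities come from the SVM's
    pairwise-coupled Platt calibration, seeded for reproducibility.
    """
    labels = labels.loc[features.index]
    classes = sorted(pd.unique(labels))
    counts = labels.value_counts()
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")

    rows = {}
    for held in features.index:
        tr = features.index != held
        Xtr_full, ytr = features.loc[tr], labels.loc[tr]
        if select_k is not None:
            feats = pairwise_top_dmrs(Xtr_full, ytr, k=select_k,
                                      candidate_windows=candidate_windows)
        else:
            feats = list(features.columns)
        if not feats:
            prior = ytr.value_counts(normalize=True).reindex(classes, fill_value=0.0)
            rows[held] = prior.to_numpy()
            continue
        means = Xtr_full[feats].mean(axis=0)
        Xtr = Xtr_full[feats].fillna(means)
        import warnings
        with warnings.catch_warnings():
            # SVC(probability=True) is the pairwise-coupled Platt calibration
            # this model wants; sklearn 1.9 deprecates the flag in favour of a
            # one-vs-rest wrapper that couples probabilities differently
            warnings.simplefilter("ignore", FutureWarning)
            model = Pipeline([
                ("scale", StandardScaler()),
                ("svm", SVC(kernel="linear", probability=True, random_state=seed)),
            ])
            model.fit(Xtr.to_numpy(), ytr.to_numpy())
        Xte = features.loc[[held], feats].fillna(means)
        proba = model.predict_proba(Xte.to_numpy())[0]
        ordered = pd.Series(proba, index=model.classes_).reindex(classes).to_numpy()
        rows[held] = ordered
    probs = pd.DataFrame(rows, index=classes).T.loc[features.index]
    return ModalityPrediction(modality=modality, probs=probs, classes=classes)


@dataclass
class IntegratedPrediction:
    mean_probs: pd.DataFrame
    final_class: pd.Series
    classes: list[str]

    def accuracy(self, truth: pd.Series) -> float:
        return float((self.final_class == truth.loc[self.final_class.index]).mean())


def integrate(preds: list[ModalityPrediction], control_class: str | None = None) -> IntegratedPrediction:
    """Average class probabilities across modalities; argmax is the call.

    All predictions must cover the same samples and classes.  Exact ties in
    the mean probabilities break toward the control class, then
    lexicographically (a declared, reproducible rule).
    """
    if not preds:
        raise ValueError("no modality predictions to integrate")
    base = preds[0]
    for p in preds[1:]:
        if list(p.probs.index) != list(base.probs.index) or p.classes != base.classes:
            raise ValueError("modality predictions disagree on samples or classes")
    mean_probs = sum(p.probs for p in preds) / len(preds)
    classes = base.classes
    control = control_class if control_class is not None else (
        "control" if "control" in classes else classes[0])
    # tie-break: control first, then lexicographic
    order = [control] + sorted(c for c in classes if c != control)
    ranked = mean_probs[order]
    final = ranked.T.idxmax()  # idxmax takes the first maximum in column order
    return IntegratedPrediction(mean_probs=mean_probs, final_class=final, classes=classes)


def evaluate(pred: IntegratedPrediction, truth: pd.Series,
             control_class: str | None = None) -> dict:
    """Overall accuracy, 3x3 confusion counts, and the binary accuracy after
    collapsing the two cancer classes into one."""
    truth = truth.loc[pred.final_class.index]
    classes = pred.classes
    control = control_class if control_class is not None else (
        "control" if "control" in classes else classes[0])
    confusion = pd.crosstab(truth, pred.final_class).reindex(
        index=classes, columns=classes, fill_value=0)
    overall = float((pred.final_class == truth).mean())
    binary = float(((pred.final_class == control) == (truth == control)).mean())
    return {
        "accuracy": overall,
        "cancer_vs_control_accuracy": binary,
        "confusion": confusion,
        "n_correct": int((pred.final_class == truth).sum()),
        "n_samples": int(len(truth)),
    }
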