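"""Cross-validated classification protocol.

The evaluation mirrors the study design: a stratified 80:20 train/test
split, then repeated (default 1000x) stratified 3-fold cross-validation
inside the training portion.  In every fold, missing features are imputed
and z-normalization refit on fold-train rows only, the consensus top-2
features are selected on fold-train only, and four classifiers (LDA, QDA,
RF, SVM) are fit on those two features and scored on fold-test.  AUC,
accuracy, sensitivity and specificity are pooled as mean +/- sd over all
iteration x fold evaluations; held-out metrics on the 20% split are also
reported (the paper's text is ambiguous about which mode its tables use,
so both are emitted).

The rebounder class is positive throughout; higher scores mean rebounder.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .selection import ConsensusSelection, select_features
from .types import REBOUNDER, ValidationError

logger = logging.getLogger(__name__)

CLASSIFIERS = ("LDA", "QDA", "RF", "SVM")


@dataclass
class EvalProtocol:
    """Protocol constants of the repeated-CV evaluation."""

    train_fraction: float = 0.8
    n_iterations: int = 1000
    n_folds: int = 3
    classifiers: tuple[str, ...] = CLASSIFIERS
    seed: int = 0
    positive_class: str = REBOUNDER
    top_k: int = 15

    def validate(self) -> None:
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        if not 0 < self.train_fraction <= 1:
            raise ValidationError("train_fraction must be in (0, 1]")
        unknown = set(self.classifiers) - set(CLASSIFIERS)
        if unknown:
            raise ValidationError(f"unknown classifiers: {sorted(unknown)}")


@dataclass
class CvResult:
    """Per-classifier metric summary over iterations x folds."""

    classifier: str
    auc: tuple[float, float]
    acc: tuple[float, float]
    sensitivity: tuple[float, float]
    specificity: tuple[float, float]
    n_evaluations: int
    oof_scores: pd.Series  # per-eye mean out-of-fold prediction score
    holdout: dict[str, float] | None = None
    is_best: bool = False


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels).astype(bool)
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC needs both classes present")
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def confusion_metrics(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """ACC / sensitivity / specificity with score >= threshold -> positive."""
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels, dtype=bool)
    if pos.all() or not pos.any():
        raise ValidationError("confusion metrics need both classes present")
    pred = scores >= threshold
    tp = int((pred & pos).sum())
    tn = int((~pred & ~pos).sum())
    return {
        "ACC": (tp + tn) / pos.size,
        "Sens": tp / pos.sum(),
        "Spec": tn / (~pos).sum(),
    }


def _make_classifier(name: str, seed: int):
    if name == "LDA":
        return LinearDiscriminantAnalysis()
    if name == "QDA":
        return QuadraticDiscriminantAnalysis(reg_param=1e-4)
    if name == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "SVM":
        return SVC(kernel="linear")
    raise ValidationError(f"unknown classifier {name!r}")


def _score(clf, X: np.ndarray) -> np.ndarray:
    """Prediction scores in [0, 1], higher = positive class."""
    if hasattr(clf, "predict_proba"):
        proba = clf.predict_proba(X)
        return proba[:, list(clf.classes_).index(1)]
    # linear SVM: logistic squashing of the signed margin
    return 1.0 / (1.0 + np.exp(-clf.decision_function(X)))


def _prepare_fold(train: pd.DataFrame, test: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Impute missing values and z-normalize using fold-train statistics only."""
    Xtr = train.to_numpy(dtype=float, copy=True)
    Xte = test.to_numpy(dtype=float, copy=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-NaN columns
        mean = np.nanmean(Xtr, axis=0)
    mean = np.where(np.isfinite(mean), mean, 0.0)
    for X in (Xtr, Xte):
        bad = ~np.isfinite(X)
        X[bad] = mean[np.nonzero(bad)[1]]
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd[sd == 0] = 1.0  # constant columns normalize to 0
    Xtr = (Xtr - mu) / sd
    Xte = (Xte - mu) / sd
    return (
        pd.DataFrame(Xtr, index=train.index, columns=train.columns),
        pd.DataFrame(Xte, index=test.index, columns=test.columns),
    )


def run_protocol(
    table: pd.DataFrame,
    labels: pd.Series,
    protocol: EvalProtocol,
) -> tuple[list[CvResult], list[ConsensusSelection]]:
    """Run the full repeated-CV evaluation on one feature table.

    Returns per-classifier :class:`CvResult` (best flagged by CV mean AUC)
    and the per-fold selection audit.
    """
    protocol.validate()
    labels = labels.reindex(table.index)
    if labels.isna().any():
        raise ValidationError("labels missing for some eyes in the table")
    y = (labels == protocol.positive_class).astype(int)
    if y.sum() < 3 or (1 - y).sum() < 3:
        raise ValidationError("need >= 3 eyes per class")

    rng = np.random.default_rng(protocol.seed)
    if protocol.train_fraction < 1.0:
        train_idx, hold_idx = train_test_split(
            np.arange(len(table)),
            train_size=protocol.train_fraction,
            stratify=y.to_numpy(),
            random_state=int(rng.integers(2**31)),
        )
    else:
        train_idx, hold_idx = np.arange(len(table)), np.array([], dtype=int)
    X_tr_full = table.iloc[train_idx]
    y_tr_full = y.iloc[train_idx]

    metrics: dict[str, dict[str, list[float]]] = {
        c: {"auc": [], "acc": [], "sens": [], "spec": []} for c in protocol.classifiers
    }
    oof_sum = {c: pd.Series(0.0, index=table.index) for c in protocol.classifiers}
    oof_count = pd.Series(0, index=table.index)
    audit: list[ConsensusSelection] = []

    for iteration in range(protocol.n_iterations):
        fold_seed = int(np.random.SeedSequence((protocol.seed, iteration)).generate_state(1)[0] % 2**31)
        skf = StratifiedKFold(n_splits=protocol.n_folds, shuffle=True, random_state=fold_seed)
        for fold, (tr, te) in enumerate(skf.split(X_tr_full, y_tr_full)):
            y_tr = y_tr_full.iloc[tr]
            y_te = y_tr_full.iloc[te]
            if y_te.nunique() < 2 or y_tr.nunique() < 2:
                logger.warning("degenerate fold (single class) at iteration %d", iteration)
                continue
            f_tr, f_te = _prepare_fold(X_tr_full.iloc[tr], X_tr_full.iloc[te])
            sel = select_features(f_tr, y_tr.to_numpy(), k=protocol.top_k,
                                  iteration=iteration, fold=fold)
            audit.append(sel)
            Xtr = f_tr[sel.selected].to_numpy()
            Xte = f_te[sel.selected].to_numpy()
            for cname in protocol.classifiers:
                clf = _make_classifier(cname, seed=fold_seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    clf.fit(Xtr, y_tr.to_numpy())
                    s = _score(clf, Xte)
                metrics[cname]["auc"].append(auc(s, y_te.to_numpy().astype(bool)))
                cm = confusion_metrics(s, y_te.to_numpy().astype(bool), threshold=0.5)
                metrics[cname]["acc"].append(cm["ACC"])
                metrics[cname]["sens"].append(cm["Sens"])
                metrics[cname]["spec"].append(cm["Spec"])
                oof_sum[cname].iloc[train_idx[te]] += s
            oof_count.iloc[train_idx[te]] += 1

    # held-out evaluation: selection + fit on the full training split
    holdout_scores: dict[str, pd.Series] = {}
    holdout_metrics: dict[str, dict[str, float]] = {}
    if hold_idx.size:
        f_tr, f_ho = _prepare_fold(X_tr_full, table.iloc[hold_idx])
        sel_full = select_features(f_tr, y_tr_full.to_numpy(), k=protocol.top_k)
        y_ho = y.iloc[hold_idx]
        for cname in protocol.classifiers:
            clf = _make_classifier(cname, seed=protocol.seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(f_tr[sel_full.selected].to_numpy(), y_tr_full.to_numpy())
                s = _score(clf, f_ho[sel_full.selected].to_numpy())
            holdout_scores[cname] = pd.Series(s, index=table.index[hold_idx])
            if y_ho.nunique() == 2:
                hm = confusion_metrics(s, y_ho.to_numpy().astype(bool), threshold=0.5)
                holdout_metrics[cname] = {
                    "AUC": auc(s, y_ho.to_numpy().astype(bool)), **hm
                }

    results: list[CvResult] = []
    for cname in protocol.classifiers:
        m = metrics[cname]
        oof = oof_sum[cname].where(oof_count > 0) / oof_count.replace(0, np.nan)
        if cname in holdout_scores:
            oof = oof.fillna(holdout_scores[cname])
        results.append(
            CvResult(
                classifier=cname,
                auc=(float(np.mean(m["auc"])), float(np.std(m["auc"]))),
                acc=(float(np.mean(m["acc"])), float(np.std(m["acc"]))),
                sensitivity=(float(np.mean(m["sens"])), float(np.std(m["sens"]))),
                specificity=(float(np.mean(m["spec"])), float(np.std(m["spec"]))),
                n_evaluations=len(m["auc"]),
                oof_scores=oof,
                holdout=holdout_metrics.get(cname),
            )
        )
    best = max(results, key=lambda r: r.auc[0])
    best.is_best = True
    logger.info("best classifier by CV mean AUC: %s (%.3f)", best.classifier, best.auc[0])
    return results, audit


def results_frame(results: list[CvResult]) -> pd.DataFrame:
    """Tables-style layout: classifier x metric, 'mean +/- sd' floats split out."""
    rows = []
    for r in results:
        rows.append(
            {
                "classifier": r.classifier,
                "AUC_mean": r.auc[0], "AUC_sd": r.auc[1],
                "ACC_mean": r.acc[0], "ACC_sd": r.acc[1],
                "Sens_mean": r.sensitivity[0], "Sens_sd": r.sensitivity[1],
                "Spec_mean": r.specificity[0], "Spec_sd": r.specificity[1],
                "best": r.is_best,
            }
        )
    return pd.DataFrame(rows).set_index("classifier")
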