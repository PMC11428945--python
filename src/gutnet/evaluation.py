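"""Cross-validated ROC evaluation of biomarker panels and synthetic-truth
benchmarks.

``netroc`` asks how well the relative abundances of a biomarker panel
classify samples into the two study conditions: features are the panel taxa's
log relative abundances (scale-free across rarefaction depths; the log tames
the heavy right tail of compositional fractions), standardized and scored
with an out-of-fold logistic model under stratified k-fold cross-validation.
Both the pooled out-of-fold AUC and the per-fold AUCs are reported (the two
differ slightly and published summaries rarely say which was used).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .data_io import CountTable, ResultTable, SampleMetadata, ValidationError
from .preprocess import relative_abundance
from .synthetic import GroundTruth


@dataclass
class RocResult:
    auc: float                 # pooled out-of-fold AUC
    fold_aucs: list[float]
    mean_fold_auc: float
    n_folds: int
    panel: list[str]
    seed: int
    roc_points: pd.DataFrame   # fpr, tpr, threshold on pooled scores


def netroc(table: CountTable, metadata: SampleMetadata, panel: list[str],
           n_folds: int = 10, seed: int = 0) -> RocResult:
    """Stratified k-fold logistic ROC of a biomarker panel.

    The positive class is "stress". Folds are stratified so both classes
    appear in every fold; a class rarer than ``n_folds`` samples makes that
    impossible and raises.
    """
    missing = [t for t in panel if t not in table.taxon_ids]
    if missing:
        raise ValidationError(f"panel taxa not in table: {missing[:5]}")
    if not panel:
        raise ValidationError("empty panel")
    labels = metadata.column("group", table.sample_ids)
    y = (labels == "stress").astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValidationError("both conditions must be present")
    if min(y.sum(), len(y) - y.sum()) < n_folds:
        raise ValidationError(
            f"cannot stratify {n_folds} folds: rarest class has "
            f"{min(y.sum(), len(y) - y.sum())} samples; use fewer folds")
    rel = relative_abundance(table)
    cols = [table.taxon_ids.index(t) for t in panel]
    # log of relative abundance; pseudofraction guards structural zeros
    x = np.log(rel[:, cols] + 1e-6)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pooled_scores = np.empty(len(y))
    fold_aucs = []
    for train, test in skf.split(x, y):
        clf = make_pipeline(StandardScaler(), LogisticRegression(max_iter=1000))
        clf.fit(x[train], y[train])
        s = clf.predict_proba(x[test])[:, 1]
        pooled_scores[test] = s
        if len(np.unique(y[test])) == 2:
            fold_aucs.append(float(roc_auc_score(y[test], s)))
    auc = float(roc_auc_score(y, pooled_scores))
    fpr, tpr, thr = roc_curve(y, pooled_scores)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return RocResult(auc=auc, fold_aucs=fold_aucs,
                     mean_fold_auc=float(np.mean(fold_aucs)) if fold_aucs else auc,
                     n_folds=n_folds, panel=list(panel), seed=seed,
                     roc_points=points)


def benchmark_against_truth(scores: pd.DataFrame, truth: GroundTruth,
                            fdr: float = 0.05) -> ResultTable:
    """Precision/recall of the FDR-significant set against planted drivers,
    plus the rank AUC of the score against the driver indicator."""
    if truth is None or not truth.drivers:
        raise ValidationError("no ground truth available")
    taxa = list(scores.index)
    is_driver = np.array([t in set(truth.drivers) for t in taxa])
    called = (scores["q_value"] < fdr).to_numpy() if "q_value" in scores \
        else np.zeros(len(taxa), dtype=bool)
    tp = int((called & is_driver).sum())
    precision = tp / called.sum() if called.sum() else float("nan")
    recall = tp / is_driver.sum() if is_driver.sum() else float("nan")
    if is_driver.any() and not is_driver.all():
        rank_auc = float(roc_auc_score(is_driver, scores["nmss"].to_numpy()))
    else:
        rank_auc = float("nan")
    frame = pd.DataFrame([{
        "n_taxa": len(taxa),
        "n_drivers": int(is_driver.sum()),
        "n_called": int(called.sum()),
        "precision": precision,
        "recall": recall,
        "rank_auc": rank_auc,
    }])
    return ResultTable(frame)
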