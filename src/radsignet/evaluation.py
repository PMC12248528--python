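"""Benchmark harness: MCC scoring and repeated stratified cross-validation.

Every pipeline variant in the study — clinical-only, radiomic-only and
combined, with either SVM-coefficient feature selection or DNetPRO — is
scored with the Matthews Correlation Coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

a confusion-matrix correlation in [-1, 1] that is robust to the mild class
imbalance of the cohort.  Distributions over repeated stratified k-fold CV
are summarized as median +/- one interquartile range, and variants are
compared with Wilcoxon tests.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, clone
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from ._seeds import derive_seed

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "CVResult",
    "BenchmarkCell",
    "mcc",
    "mcc_score",
    "SVMFeatureSelector",
    "svm_select",
    "make_pipeline",
    "repeated_stratified_cv",
    "summarize",
    "compare_wilcoxon",
    "BenchmarkPlan",
    "run_benchmark",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.fn + self.tn == 0:
            raise ValueError("confusion counts must have a positive total")


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation from confusion counts; 0 when any margin is empty."""
    tp, fp, fn, tn = float(c.tp), float(c.fp), float(c.fn), float(c.tn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def mcc_score(y_true, y_pred) -> float:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    return mcc(ConfusionCounts(tp, fp, fn, tn))


@dataclass
class CVResult:
    """A distribution of per-split MCC scores for one pipeline variant."""

    scores: np.ndarray
    n_repeats: int
    n_folds: int
    pipeline_id: str
    seed: int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)


@dataclass
class BenchmarkCell:
    modality: str
    category: str
    method: str
    source: str
    median_mcc: float
    iqr: float
    n_scores: int
    error: str | None = None


class SVMFeatureSelector(SelectorMixin, BaseEstimator):
    """Select features by the magnitude of linear-SVM coefficients.

    Fits a linear maximum-margin classifier on all (standardized) features
    and retains those whose |coefficient| exceeds the mean |coefficient|
    (default), or the ``top_k`` largest.  At least one feature is always
    retained.
    """

    def __init__(self, top_k: int | None = None, C: float = 1.0):
        self.top_k = top_k
        self.C = C

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            svm = LinearSVC(C=self.C).fit(X, y)
        coef = np.abs(np.asarray(svm.coef_).ravel())
        self.n_features_in_ = X.shape[1]
        if self.top_k is not None:
            k = max(1, min(self.top_k, coef.size))
            keep = np.argsort(-coef, kind="stable")[:k]
            mask = np.zeros(coef.size, dtype=bool)
            mask[keep] = True
        else:
            mask = coef > coef.mean()
            if not mask.any():
                mask[int(np.argmax(coef))] = True
        self.support_mask_ = mask
        return self

    def _get_support_mask(self):
        return self.support_mask_


def svm_select(X_train, y_train, top_k: int | None = None) -> np.ndarray:
    """Indices of features retained by :class:`SVMFeatureSelector`."""
    sel = SVMFeatureSelector(top_k=top_k).fit(np.asarray(X_train, float), y_train)
    return np.flatnonzero(sel.support_mask_)


def make_pipeline(top_k: int | None = None, penalty: float = 1.0,
                  select: bool = True) -> Pipeline:
    """Standard pipeline: z-scoring -> SVM selection -> L2 logistic model."""
    steps = [("scale", StandardScaler())]
    if select:
        steps.append(("select", SVMFeatureSelector(top_k=top_k)))
    steps.append(("clf", LogisticRegression(C=1.0 / penalty, max_iter=2000)))
    return Pipeline(steps)


def repeated_stratified_cv(pipeline, X, y, n_folds: int = 10, n_repeats: int = 100,
                           seed: int = 0, pipeline_id: str = "pipeline") -> CVResult:
    """Repeat a stratified k-fold CV with fresh fold draws per repeat.

    The whole pipeline (scaling, selection, classifier) is cloned and fitted
    inside each training fold only, so no information leaks from the test
    fold.  Degenerate single-class test folds (impossible under
    stratification when each class count >= ``n_folds``, but guarded) are
    skipped with a log entry.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples < n_folds={n_folds}; "
            "reduce the number of folds")
    scores = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=derive_seed(seed, f"repeat{rep}"))
        for train, test in skf.split(X, y):
            if len(np.unique(y[test])) < 2:
                logger.info("skipping degenerate single-class test fold")
                continue
            model = clone(pipeline)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model.fit(X[train], y[train])
            scores.append(mcc_score(y[test], model.predict(X[test])))
    return CVResult(np.array(scores), n_repeats, n_folds, pipeline_id, seed)


def summarize(result: CVResult, modality: str = "", category: str = "",
              source: str = "") -> BenchmarkCell:
    """Median and interquartile range (Q3 - Q1) of the score distribution."""
    s = result.scores
    if s.size == 0:
        raise ValueError("empty score vector")
    q1, med, q3 = np.percentile(s, [25, 50, 75])
    return BenchmarkCell(modality, category, result.pipeline_id, source,
                         float(med), float(q3 - q1), int(s.size))


def compare_wilcoxon(a: CVResult, b: CVResult, alternative: str = "two-sided",
                     paired: bool | None = None) -> float:
    """Wilcoxon comparison of two MCC distributions.

    Paired signed-rank (midranks, zero differences dropped) when the two
    results share the same fold structure, otherwise the unpaired rank-sum
    test.  All-zero differences give p = 1 with a notice.
    """
    alternative = {"two_sided": "two-sided"}.get(alternative, alternative)
    if paired is None:
        paired = (a.scores.size == b.scores.size and a.n_folds == b.n_folds
                  and a.n_repeats == b.n_repeats and a.seed == b.seed)
    if paired:
        diff = a.scores - b.scores
        if np.all(diff == 0):
            logger.info("all paired differences are zero; p = 1")
            return 1.0
        return float(stats.wilcoxon(a.scores, b.scores, alternative=alternative,
                                    zero_method="wilcox").pvalue)
    return float(stats.mannwhitneyu(a.scores, b.scores, alternative=alternative).pvalue)


@dataclass
class BenchmarkPlan:
    """Grid of benchmark cells to evaluate.

    ``sources``: subsets of {clinical, radiomic, combined};
    ``modalities``: modality combinations (e.g. ("CE_T1w",) or
    ("CE_T1w", "T2w")); ``categories``: radiomic filter classes;
    ``methods``: {"svm", "dnetpro_A", "dnetpro_B"}.
    """

    sources: tuple[str, ...] = ("clinical", "radiomic", "combined")
    modalities: tuple[tuple[str, ...], ...] = (("CE_T1w",), ("T2w",), ("CE_T1w", "T2w"))
    categories: tuple[str, ...] = ("Original", "LoG", "Wavelet")
    methods: tuple[str, ...] = ("svm",)
    n_folds: int = 10
    n_repeats: int = 100
    dnetpro_repeats: int = 3
    top_k: int | None = None
    dnetpro: "object | None" = None  # DNetProConfig; resolved lazily

    def cells(self):
        for source in self.sources:
            for mods in self.modalities:
                cats = self.categories if source != "clinical" else ("none",)
                m_id = "+".join(mods) if source != "clinical" else "clinical"
                for cat in cats:
                    for method in self.methods:
                        yield source, m_id, mods, cat, method
                if source == "clinical":
                    break  # clinical-only does not vary with modality


def _cell_matrix(cohort, source, mods, cat, encoder_table):
    from .feature_table import subset_by_category

    parts = []
    if source in ("radiomic", "combined"):
        parts.append(subset_by_category(cohort.features, mods, [cat]))
    if source in ("clinical", "combined"):
        parts.append(encoder_table)
    table = parts[0]
    for extra in parts[1:]:
        table = table.concat(extra)
    return table


def run_benchmark(cohort, plan: BenchmarkPlan, seed: int = 0) -> pd.DataFrame:
    """Evaluate the benchmark grid on a cohort.

    Returns a long-format table with one row per cell (source x modality x
    category x method) holding the median MCC and IQR; failed cells are
    recorded with their error message instead of crashing the grid.  The
    per-modality argmax category among radiomic SVM cells (the rule used to
    pick one filter class before DNetPRO) is flagged in ``is_argmax``.
    """
    from .dnetpro import DNetProConfig, procedure_a, procedure_b
    from .feature_table import ClinicalEncoder

    encoder_table = ClinicalEncoder().fit_transform(cohort.clinical)
    y = np.asarray(cohort.labels).astype(int)
    dn_config = plan.dnetpro if plan.dnetpro is not None else DNetProConfig()

    rows = []
    for source, m_id, mods, cat, method in plan.cells():
        cell_seed = derive_seed(seed, f"{source}|{m_id}|{cat}|{method}")
        try:
            table = _cell_matrix(cohort, source, mods, cat, encoder_table)
            pid = f"{method}"
            if method == "svm":
                result = repeated_stratified_cv(
                    make_pipeline(top_k=plan.top_k), table.values, y,
                    n_folds=plan.n_folds, n_repeats=plan.n_repeats,
                    seed=cell_seed, pipeline_id=pid)
            elif method in ("dnetpro_A", "dnetpro_B"):
                proc = procedure_a if method == "dnetpro_A" else procedure_b
                scores = []
                for rep in range(plan.dnetpro_repeats):
                    import dataclasses as _dc
                    cfg = _dc.replace(dn_config,
                                      seed=derive_seed(cell_seed, f"rep{rep}"))
                    _, res = proc(table.values, y, table.feature_names, cfg)
                    scores.extend(res.scores)
                result = CVResult(np.array(scores), plan.dnetpro_repeats,
                                  plan.n_folds, pid, cell_seed)
            else:
                raise ValueError(f"unknown method {method!r}")
            cell = summarize(result, m_id, cat, source)
            rows.append({"source": source, "modality": m_id, "category": cat,
                         "method": method, "median_mcc": cell.median_mcc,
                         "iqr": cell.iqr, "n_scores": cell.n_scores, "error": None})
        except Exception as exc:  # record NA cell, keep the grid going
            logger.warning("benchmark cell failed (%s %s %s %s): %s",
                           source, m_id, cat, method, exc)
            rows.append({"source": source, "modality": m_id, "category": cat,
                         "method": method, "median_mcc": np.nan, "iqr": np.nan,
                         "n_scores": 0, "error": str(exc)})
    out = pd.DataFrame(rows)

    out["is_argmax"] = False
    svm_rad = out[(out.source == "radiomic") & (out.method == "svm") & out.error.isna()]
    for m_id, grp in svm_rad.groupby("modality"):
        best = grp.median_mcc.idxmax()
        if not np.isnan(out.loc[best, "median_mcc"]):
            out.loc[best, "is_argmax"] = True
    return out
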