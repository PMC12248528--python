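"""Validation experiments and independent oracles.

This module backs the package's self-validation: definition-level oracle
re-implementations of the core statistics (naive double loops, exhaustive
enumeration) and the simulation experiments that probe recovery power, null
calibration and batch-audit operating characteristics at desk-scale problem
sizes.  Oracles are deliberately written in the most literal way possible —
they trade speed for transparency and never share code with the production
paths they check.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings
from dataclasses import replace

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from ._seeds import derive_seed
from .association import associate_clinical
from .audit import audit_report
from .dnetpro import DNetProConfig, procedure_a, procedure_b
from .evaluation import make_pipeline, repeated_stratified_cv
from .feature_table import ClinicalEncoder, subset_by_category
from .simulate import (BlockSpec, ClinicalVariableSpec, SimConfig, generate_cohort)

# ---------------------------------------------------------------------------
# naive oracles


def naive_mcc(tp: int, fp: int, fn: int, tn: int) -> float:
    """MCC as the Pearson correlation of the underlying binary vectors."""
    y_true = [1] * tp + [1] * fn + [0] * fp + [0] * tn
    y_pred = [1] * tp + [0] * fn + [1] * fp + [0] * tn
    if len(set(y_true)) < 2 or len(set(y_pred)) < 2:
        return 0.0
    return float(np.corrcoef(y_true, y_pred)[0, 1])


def naive_chi2(counts: np.ndarray) -> float:
    """Chi-square by the explicit double loop over cells."""
    counts = np.asarray(counts, float)
    n = counts.sum()
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    total = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            expected = rows[i] * cols[j] / n
            if expected > 0:
                total += (counts[i, j] - expected) ** 2 / expected
    return total


def naive_cramers_v(counts: np.ndarray) -> float:
    counts = np.asarray(counts, float)
    r, k = counts.shape
    return math.sqrt(naive_chi2(counts) / counts.sum() / min(r - 1, k - 1))


def naive_couple_scores(X, y, inner_folds: int, seed: int,
                        svm_C: float = 1.0) -> dict[tuple[int, int], float]:
    """Literal double loop over feature pairs with per-pair refitted folds."""
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    out: dict[tuple[int, int], float] = {}
    for i, j in itertools.combinations(range(X.shape[1]), 2):
        skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
        fold_scores = []
        for train, test in skf.split(X, y):
            clf = LinearSVC(C=svm_C).fit(X[train][:, [i, j]], y[train])
            pred = clf.predict(X[test][:, [i, j]])
            tp = sum(1 for a, b in zip(y[test], pred) if a == 1 and b == 1)
            fp = sum(1 for a, b in zip(y[test], pred) if a == 0 and b == 1)
            fn = sum(1 for a, b in zip(y[test], pred) if a == 1 and b == 0)
            tn = sum(1 for a, b in zip(y[test], pred) if a == 0 and b == 0)
            denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            fold_scores.append((tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0)
        out[(i, j)] = sum(fold_scores) / len(fold_scores)
    return out


def naive_components(edges: list[tuple[int, int]]) -> list[frozenset[int]]:
    """Connected components by iterated transitive closure of the adjacency
    relation (no union-find, no graph library)."""
    nodes = sorted({v for e in edges for v in e})
    reach = {v: {v} for v in nodes}
    for i, j in edges:
        reach[i].add(j)
        reach[j].add(i)
    changed = True
    while changed:
        changed = False
        for v in nodes:
            expanded = set(reach[v])
            for w in reach[v]:
                expanded |= reach[w]
            if expanded != reach[v]:
                reach[v] = expanded
                changed = True
    return sorted({frozenset(reach[v]) for v in nodes}, key=lambda s: sorted(s))


def naive_fisher_two_sided(table: np.ndarray) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    row1, col1, n = a + b, a + c, a + b + c + d

    def pmf(k: int) -> float:
        return (math.comb(col1, k) * math.comb(n - col1, row1 - k)
                / math.comb(n, row1))

    p_obs = pmf(a)
    lo, hi = max(0, row1 - (n - col1)), min(row1, col1)
    return min(1.0, sum(pmf(k) for k in range(lo, hi + 1)
                        if pmf(k) <= p_obs * (1 + 1e-9)))


def naive_signed_rank_p(diff: np.ndarray, alternative: str = "greater") -> float:
    """Exact signed-rank p-value by enumerating all 2^n sign patterns."""
    diff = np.asarray(diff, float)
    diff = diff[diff != 0]
    n = diff.size
    ranks = _midranks(np.abs(diff))
    w_obs = float(np.sum(ranks[diff > 0]))
    count = 0
    total = 2 ** n
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if alternative == "greater" and w >= w_obs - 1e-12:
            count += 1
        elif alternative == "less" and w <= w_obs + 1e-12:
            count += 1
        elif alternative == "two-sided":
            mean = n * (n + 1) / 4
            if abs(w - mean) >= abs(w_obs - mean) - 1e-12:
                count += 1
    return count / total


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="stable")
    ranks = np.empty(values.size, float)
    i = 0
    while i < values.size:
        j = i
        while j + 1 < values.size and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


# ---------------------------------------------------------------------------
# simulation experiment configurations


def planted_signature_config(n: int = 150, p: int = 50, d: float = 1.5,
                             seed: int = 0) -> SimConfig:
    """Cohort with one radiomic block holding a planted 3-feature signature
    (independent features, standardized mean difference d) among noise."""
    return SimConfig(
        n_patients=n, class_balance=0.5,
        blocks=(BlockSpec("CE_T1w", "LoG", p, n_informative=3),),
        effect_size=d, block_rho=0.0, batch_shift=0.0,
        clinical_schema={}, seed=seed)


_FAST_DN = DNetProConfig(inner_folds=3, eval_folds=3, outer_folds=3)


def signature_recovery(d: float = 1.5, n: int = 150, p: int = 50,
                       n_seeds: int = 25, seed: int = 0,
                       config: DNetProConfig = _FAST_DN) -> float:
    """Fraction of cohorts where procedure A's signature holds >= 2 of the
    3 planted features."""
    hits = 0
    for s in range(n_seeds):
        cohort = generate_cohort(planted_signature_config(
            n, p, d, derive_seed(seed, f"cohort{s}")))
        cfg = replace(config, seed=derive_seed(seed, f"dnetpro{s}"))
        signature, _ = procedure_a(cohort.features.values, cohort.labels,
                                   cohort.features.feature_names, cfg)
        planted = {t.split("__", 1)[1] for t in cohort.truth}
        hits += len(planted & set(signature.features)) >= 2
    return hits / n_seeds


def recovery_vs_effect_size(d_grid=(0.5, 1.0, 1.5, 2.0), n: int = 150,
                            p: int = 30, n_seeds: int = 10,
                            seed: int = 0) -> dict[float, float]:
    """Recovery rate per effect size, with common random numbers across the
    grid so the monotone tendency is visible at modest seed counts."""
    return {d: signature_recovery(d, n, p, n_seeds, seed) for d in d_grid}


def null_calibration(seed: int = 0, n: int = 150, p: int = 20) -> dict[str, float]:
    """Median MCC of each pipeline variant on a zero-effect cohort."""
    cohort = generate_cohort(SimConfig(
        n_patients=n, class_balance=0.5,
        blocks=(BlockSpec("CE_T1w", "Original", p),),
        effect_size=0.0, block_rho=0.3, batch_shift=0.0,
        clinical_schema={}, seed=derive_seed(seed, "null_cohort")))
    X, y = cohort.features.values, cohort.labels
    names = cohort.features.feature_names
    svm = repeated_stratified_cv(make_pipeline(), X, y, n_folds=10, n_repeats=10,
                                 seed=derive_seed(seed, "null_svm"))
    a_scores, b_scores = [], []
    for rep in range(2):
        cfg = DNetProConfig(inner_folds=3, eval_folds=3, outer_folds=5,
                            seed=derive_seed(seed, f"null_a{rep}"))
        a_scores.extend(procedure_a(X, y, names, cfg)[1].scores)
    for rep in range(3):
        cfg = DNetProConfig(inner_folds=3, eval_folds=3,
                            seed=derive_seed(seed, f"null_b{rep}"))
        b_scores.extend(procedure_b(X, y, names, cfg)[1].scores)
    return {"svm": float(np.median(svm.scores)),
            "dnetpro_A": float(np.median(a_scores)),
            "dnetpro_B": float(np.median(b_scores))}


def _complementary_config(seed: int) -> SimConfig:
    schema = {
        "symptoms": ClinicalVariableSpec(("nonspecific", "red_flags"),
                                         (0.46, 0.54), 0.41),
        "tumor_size": ClinicalVariableSpec(("lt5cm", "ge5cm"), (0.42, 0.58), 0.38),
        "gross_adjacent_involvement": ClinicalVariableSpec(("no", "yes"),
                                                           (0.85, 0.15), 0.38),
    }
    return SimConfig(n_patients=145, class_balance=0.52,
                     blocks=(BlockSpec("CE_T1w", "LoG", 30, n_informative=4),),
                     effect_size=0.7, block_rho=0.3, batch_shift=0.0,
                     clinical_schema=schema, seed=seed)


def complementarity(n_seeds: int = 25, seed: int = 0,
                    n_folds: int = 5, n_repeats: int = 5) -> float:
    """Fraction of cohorts where combining clinical and radiomic features
    gives a median MCC at least as high as either source alone."""
    wins = 0
    for s in range(n_seeds):
        cohort = generate_cohort(_complementary_config(derive_seed(seed, f"c{s}")))
        clinical = ClinicalEncoder().fit_transform(cohort.clinical)
        radiomic = cohort.features
        combined = radiomic.concat(clinical)
        medians = {}
        for name, table in (("clinical", clinical), ("radiomic", radiomic),
                            ("combined", combined)):
            res = repeated_stratified_cv(make_pipeline(), table.values,
                                         cohort.labels, n_folds=n_folds,
                                         n_repeats=n_repeats,
                                         seed=derive_seed(seed, f"cv{s}"))
            medians[name] = float(np.median(res.scores))
        wins += (medians["combined"] >= medians["clinical"]
                 and medians["combined"] >= medians["radiomic"])
    return wins / n_seeds


def argmax_category_recovery(n_seeds: int = 25, seed: int = 0,
                             n_folds: int = 5, n_repeats: int = 10) -> float:
    """Fraction of cohorts whose per-modality best category (by median MCC of
    the standard SVM pipeline) is the block where signal was planted (LoG)."""
    hits = 0
    for s in range(n_seeds):
        cohort = generate_cohort(SimConfig(
            n_patients=145, class_balance=0.52,
            blocks=(BlockSpec("CE_T1w", "Original", 30),
                    BlockSpec("CE_T1w", "LoG", 30, n_informative=5),
                    BlockSpec("CE_T1w", "Wavelet", 30)),
            effect_size=0.8, block_rho=0.3, batch_shift=0.0,
            clinical_schema={}, seed=derive_seed(seed, f"cat{s}")))
        medians = {}
        for cat in ("Original", "LoG", "Wavelet"):
            table = subset_by_category(cohort.features, ["CE_T1w"], [cat])
            res = repeated_stratified_cv(make_pipeline(), table.values,
                                         cohort.labels, n_folds=n_folds,
                                         n_repeats=n_repeats,
                                         seed=derive_seed(seed, f"catcv{s}"))
            medians[cat] = float(np.median(res.scores))
        hits += max(medians, key=medians.get) == "LoG"
    return hits / n_seeds


def procedure_comparison(n_seeds: int = 8, seed: int = 0, n: int = 150,
                         p: int = 30, d: float = 1.5) -> dict[str, float]:
    """Recovery rate and mean median-MCC of procedures A and B on the same
    planted-signature cohorts."""
    rec = {"A": 0, "B": 0}
    med = {"A": [], "B": []}
    for s in range(n_seeds):
        cohort = generate_cohort(planted_signature_config(
            n, p, d, derive_seed(seed, f"ab{s}")))
        planted = {t.split("__", 1)[1] for t in cohort.truth}
        for name, proc in (("A", procedure_a), ("B", procedure_b)):
            cfg = replace(_FAST_DN, seed=derive_seed(seed, f"{name}{s}"))
            signature, res = proc(cohort.features.values, cohort.labels,
                                  cohort.features.feature_names, cfg)
            rec[name] += len(planted & set(signature.features)) >= 2
            med[name].append(float(np.median(res.scores)))
    return {"recovery_A": rec["A"] / n_seeds, "recovery_B": rec["B"] / n_seeds,
            "median_mcc_A": float(np.mean(med["A"])),
            "median_mcc_B": float(np.mean(med["B"]))}


def _audit_config(batch_shift: float, effect_size: float, seed: int) -> SimConfig:
    return SimConfig(n_patients=145, class_balance=0.52,
                     blocks=(BlockSpec("CE_T1w", "Original", 40),
                             BlockSpec("CE_T1w", "LoG", 40),
                             BlockSpec("CE_T1w", "Wavelet", 40)),
                     effect_size=effect_size, block_rho=0.3,
                     batch_shift=batch_shift, clinical_schema={}, seed=seed)


def batch_audit_rate(n_seeds: int = 50, seed: int = 0, batch_shift: float = 2.0,
                     effect_size: float = 0.8) -> float:
    """Fraction of cohorts where some BH-adjusted pairwise Fisher p-value for
    the acquisition center falls below 0.05 (power at shift > 0, false-alarm
    rate at shift = 0)."""
    alarms = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in range(n_seeds):
            cohort = generate_cohort(_audit_config(
                batch_shift, effect_size, derive_seed(seed, f"audit{s}")))
            report = audit_report(cohort.features, cohort.centers, cohort.labels,
                                  seed=derive_seed(seed, f"auditseed{s}"))
            center = report.enrichment[report.enrichment.label_type == "center"]
            alarms += bool(len(center) and (center.p_adjusted < 0.05).any())
    return alarms / n_seeds


def association_calibration(target_v: float = 0.41, n: int = 500,
                            n_replicates: int = 100, seed: int = 0) -> float:
    """Mean empirical bias-corrected V for a binary variable calibrated at
    ``target_v`` (the planted symptoms association), over fresh cohorts."""
    schema = {"symptoms": ClinicalVariableSpec(("nonspecific", "red_flags"),
                                               (0.46, 0.54), target_v)}
    base = SimConfig(n_patients=n, class_balance=0.52,
                     blocks=(BlockSpec("CE_T1w", "Original", 3),),
                     effect_size=0.0, batch_shift=0.0, clinical_schema=schema)
    values = []
    for r in range(n_replicates):
        cohort = generate_cohort(dataclasses.replace(
            base, seed=derive_seed(seed, f"cal{r}")))
        report = associate_clinical(cohort.clinical, cohort.labels)
        values.append(float(report.set_index("variable").loc["symptoms",
                                                             "v_corrected"]))
    return float(np.mean(values))
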