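"""Categorical association screening between clinical variables and outcome.

The association of each categorical clinical variable with the binary tumor
outcome is measured with Cramér's V,

    V = sqrt( (chi2 / n) / min(k - 1, r - 1) ),

and with its bias-corrected variant (Bergsma's correction), which subtracts
the chance-level expectation of phi^2 = chi2 / n before normalizing:

    phi2~ = max(0, phi2 - (k - 1)(r - 1) / (n - 1))
    k~    = k - (k - 1)^2 / (n - 1)
    r~    = r - (r - 1)^2 / (n - 1)
    V~    = sqrt( phi2~ / min(k~ - 1, r~ - 1) )

The plain estimator is upward biased on finite samples (independence yields
V > 0 in expectation); the corrected one removes most of that bias, so
V~ <= V always.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ContingencyTable", "cramers_v", "cramers_v_corrected", "associate_clinical"]


@dataclass
class ContingencyTable:
    """r x k table of non-negative counts."""

    counts: np.ndarray
    row_labels: list[str] | None = None
    col_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValueError("contingency table must be at least 2 x 2")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() < 1:
            raise ValueError("table total must be positive")

    @classmethod
    def from_observations(cls, a, b) -> "ContingencyTable":
        tab = pd.crosstab(pd.Series(a), pd.Series(b))
        return cls(tab.to_numpy(float), [str(x) for x in tab.index],
                   [str(x) for x in tab.columns])


def _effective_counts(table: ContingencyTable) -> np.ndarray:
    """Drop all-zero rows/columns (they carry no information) with a warning."""
    counts = table.counts
    keep_r = counts.sum(axis=1) > 0
    keep_c = counts.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping zero-margin rows/columns before association",
                      stacklevel=3)
        counts = counts[keep_r][:, keep_c]
    return counts


def _phi2(counts: np.ndarray) -> float:
    # chi-square without continuity correction
    chi2 = stats.chi2_contingency(counts, correction=False)[0]
    return float(chi2 / counts.sum())


def cramers_v(table: ContingencyTable) -> float:
    """Plain Cramér's V of an r x k contingency table, in [0, 1]."""
    counts = _effective_counts(table)
    if min(counts.shape) < 2:
        return 0.0
    r, k = counts.shape
    v2 = _phi2(counts) / min(k - 1, r - 1)
    return float(np.sqrt(min(max(v2, 0.0), 1.0)))


def cramers_v_corrected(table: ContingencyTable) -> float:
    """Bias-corrected Cramér's V; always <= the plain statistic."""
    counts = _effective_counts(table)
    if min(counts.shape) < 2:
        return 0.0
    n = counts.sum()
    if n < 2:
        raise ValueError("bias correction needs n >= 2")
    r, k = counts.shape
    phi2_tilde = max(0.0, _phi2(counts) - (k - 1) * (r - 1) / (n - 1))
    k_tilde = k - (k - 1) ** 2 / (n - 1)
    r_tilde = r - (r - 1) ** 2 / (n - 1)
    denom = min(k_tilde - 1, r_tilde - 1)
    if denom <= 0:
        return 0.0
    return float(np.sqrt(min(phi2_tilde / denom, 1.0)))


def associate_clinical(clinical, labels) -> pd.DataFrame:
    """Per-variable bias-corrected Cramér's V against a binary outcome.

    Each variable is evaluated on its own complete cases (missing codes
    dropped for that variable only).  Variables with fewer than two observed
    levels — or a constant outcome — are reported as not computable.
    Returns a report sorted by descending corrected V.

    Parameters
    ----------
    clinical : ClinicalTable
    labels : array-like of 0/1, aligned with ``clinical.patient_ids``
    """
    labels = np.asarray(labels)
    if len(labels) != len(clinical.data):
        raise ValueError("labels must align with the clinical table")
    rows = []
    for var in clinical.variables:
        col = clinical.data[var]
        mask = col.notna().to_numpy()
        obs, lab = col[mask], labels[mask]
        n_levels = obs.nunique()
        if n_levels < 2 or len(np.unique(lab)) < 2:
            rows.append({"variable": var, "v_corrected": np.nan, "v": np.nan,
                         "n_complete": int(mask.sum()), "n_levels": int(n_levels),
                         "computable": False})
            continue
        table = ContingencyTable.from_observations(obs.to_numpy(), lab)
        rows.append({"variable": var, "v_corrected": cramers_v_corrected(table),
                     "v": cramers_v(table), "n_complete": int(mask.sum()),
                     "n_levels": int(n_levels), "computable": True})
    report = pd.DataFrame(rows)
    return report.sort_values(["v_corrected", "variable"], ascending=[False, True],
                              na_position="last").reset_index(drop=True)
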