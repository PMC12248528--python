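"""Data model and I/O for wide radiomic + clinical feature tables.

Radiomic features arrive as patients x features CSV files, one per MRI
modality (contrast-enhanced T1-weighted, T2-weighted), with column names in
the pyRadiomics dialect, e.g. ``log-sigma-1-0-mm-3D_firstorder_Skewness``.
This module parses those names into per-column category metadata
(filter class x feature family), aligns radiomic and clinical tables on
patient ids, slices tables by category, and implements the two
standardization schemes used downstream: z-scoring (mean / population SD)
and robust scaling (median / interquartile range).
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Modality",
    "FilterClass",
    "Family",
    "FeatureDescriptor",
    "FeatureTable",
    "ClinicalTable",
    "ScalingParams",
    "ClinicalEncoder",
    "parse_feature_name",
    "canonical_name",
    "load_tables",
    "subset_by_category",
    "standardize",
    "apply_scaling",
]


class Modality(str, Enum):
    CE_T1w = "CE_T1w"
    T2w = "T2w"
    clinical = "clinical"


class FilterClass(str, Enum):
    Original = "Original"
    LoG = "LoG"
    Wavelet = "Wavelet"
    none = "none"


class Family(str, Enum):
    shape = "shape"
    firstorder = "firstorder"
    glcm = "glcm"
    glrlm = "glrlm"
    glszm = "glszm"
    ngtdm = "ngtdm"
    gldm = "gldm"
    clinical = "clinical"


_RADIOMIC_FAMILIES = {f.value for f in Family} - {"clinical"}

_LOG_RE = re.compile(r"^log-sigma-(\d+)-(\d+)-mm-3D$")
_WAVELET_RE = re.compile(r"^wavelet-([LH]{3})$")


class FeatureNameError(ValueError):
    """Raised for names the parser cannot accept (empty input)."""


@dataclass(frozen=True)
class FeatureDescriptor:
    """Category metadata for one feature column."""

    name: str
    modality: Modality
    filter_class: FilterClass = FilterClass.none
    family: Family = Family.clinical
    filter_param: str | None = None

    def __post_init__(self) -> None:
        if self.filter_class is FilterClass.LoG:
            if self.filter_param is None or float(self.filter_param) <= 0:
                raise ValueError("LoG features need a positive sigma (mm)")
        if self.filter_class is FilterClass.Wavelet:
            if self.filter_param is None or not re.fullmatch("[LH]{3}", self.filter_param):
                raise ValueError("Wavelet features need a 3-letter L/H sub-band code")
        if self.modality is Modality.clinical and self.filter_class is not FilterClass.none:
            raise ValueError("clinical features carry no image filter")


def parse_feature_name(column_name: str, modality: Modality | str) -> FeatureDescriptor:
    """Parse one extractor column name into a :class:`FeatureDescriptor`.

    Recognized prefixes are ``original_``, ``log-sigma-<a>-<b>-mm-3D_`` (sigma
    ``a.b`` mm) and ``wavelet-<XYZ>_`` with ``XYZ`` over ``{L, H}``.  Any other
    name is treated as a clinical variable (``filter_class=none``).
    """
    if not column_name:
        raise FeatureNameError("empty feature name")
    modality = Modality(modality)
    parts = column_name.split("_")
    if len(parts) >= 3 and parts[1] in _RADIOMIC_FAMILIES:
        prefix, family = parts[0], parts[1]
        if prefix == "original":
            return FeatureDescriptor(column_name, modality, FilterClass.Original,
                                     Family(family), None)
        m = _LOG_RE.match(prefix)
        if m:
            sigma = f"{int(m.group(1))}.{m.group(2)}"
            return FeatureDescriptor(column_name, modality, FilterClass.LoG,
                                     Family(family), sigma)
        m = _WAVELET_RE.match(prefix)
        if m:
            return FeatureDescriptor(column_name, modality, FilterClass.Wavelet,
                                     Family(family), m.group(1))
    return FeatureDescriptor(column_name, modality, FilterClass.none, Family.clinical, None)


def canonical_name(descriptor: FeatureDescriptor) -> str:
    """Rebuild the extractor column name from a descriptor (parse round-trip)."""
    fc = descriptor.filter_class
    base = descriptor.name.split("_")[-1]
    if fc is FilterClass.none:
        return descriptor.name
    family = descriptor.family.value
    if fc is FilterClass.Original:
        return f"original_{family}_{base}"
    if fc is FilterClass.LoG:
        a, b = descriptor.filter_param.split(".")
        return f"log-sigma-{a}-{b}-mm-3D_{family}_{base}"
    return f"wavelet-{descriptor.filter_param}_{family}_{base}"


class AlignmentError(ValueError):
    """Patient id sets of the provided tables do not intersect."""


class SchemaError(ValueError):
    """A table violates the expected schema (e.g. non-binary labels)."""


class EmptySelectionError(ValueError):
    """A category subset matched no columns."""


@dataclass
class FeatureTable:
    """Patients x features numeric matrix with per-column category metadata."""

    values: np.ndarray
    descriptors: list[FeatureDescriptor]
    patient_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SchemaError("values must be a 2D matrix")
        if self.values.shape[1] != len(self.descriptors):
            raise SchemaError("one descriptor per column required")
        if self.values.shape[0] != len(self.patient_ids):
            raise SchemaError("one patient id per row required")
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise SchemaError("patient ids must be unique")
        seen: set[tuple[str, str]] = set()
        for d in self.descriptors:
            key = (d.modality.value, d.name)
            if key in seen:
                raise SchemaError(f"duplicate feature {d.name!r} in modality {d.modality.value}")
            seen.add(key)

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    def to_frame(self, prefix_modality: bool = False) -> pd.DataFrame:
        if prefix_modality:
            cols = [f"{d.modality.value}__{d.name}" for d in self.descriptors]
        else:
            cols = self.feature_names
        return pd.DataFrame(self.values, index=pd.Index(self.patient_ids, name="patient_id"),
                            columns=cols)

    def concat(self, other: "FeatureTable") -> "FeatureTable":
        if self.patient_ids != other.patient_ids:
            raise AlignmentError("tables must share an identical patient order")
        return FeatureTable(np.hstack([self.values, other.values]),
                            self.descriptors + other.descriptors, list(self.patient_ids))


@dataclass
class ClinicalTable:
    """Per-patient categorical variables with an explicit missing marker (NaN)."""

    data: pd.DataFrame
    schema: dict[str, list[str]]

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise SchemaError("patient ids must be unique")
        for var, levels in self.schema.items():
            if var not in self.data.columns:
                raise SchemaError(f"schema variable {var!r} absent from table")
            observed = set(self.data[var].dropna().unique())
            extra = observed - set(levels)
            if extra:
                raise SchemaError(f"variable {var!r} has codes outside its level set: {extra}")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.schema)


@dataclass
class ScalingParams:
    """Train-fitted per-column location/scale, re-applicable to held-out data."""

    method: str
    center: np.ndarray
    scale: np.ndarray
    constant_mask: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "method": self.method,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "constant_mask": self.constant_mask.astype(int).tolist(),
            "feature_names": self.feature_names,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalingParams":
        payload = json.loads(Path(path).read_text())
        return cls(payload["method"], np.asarray(payload["center"], float),
                   np.asarray(payload["scale"], float),
                   np.asarray(payload["constant_mask"], bool), payload["feature_names"])


def _fit_scaling(values: np.ndarray, method: str) -> tuple[np.ndarray, np.ndarray]:
    if method == "zscore":
        center = values.mean(axis=0)
        scale = values.std(axis=0)  # population SD
    elif method == "robust":
        center = np.median(values, axis=0)
        q1, q3 = np.percentile(values, [25, 75], axis=0)  # linear interpolation
        scale = q3 - q1
    else:
        raise ValueError(f"unknown standardization method {method!r}")
    return center, scale


def standardize(table: FeatureTable, method: str = "zscore") -> tuple[FeatureTable, ScalingParams]:
    """Standardize every column; constant columns map to zeros (with a warning).

    ``zscore`` subtracts the mean and divides by the population standard
    deviation; ``robust`` subtracts the median and divides by the
    interquartile range (Q3 - Q1, linearly interpolated quantiles).
    """
    center, scale = _fit_scaling(table.values, method)
    constant = scale == 0
    if constant.any():
        names = [table.descriptors[i].name for i in np.flatnonzero(constant)[:5]]
        warnings.warn(f"{int(constant.sum())} constant column(s) mapped to zeros "
                      f"(e.g. {names})", stacklevel=2)
    params = ScalingParams(method, center, np.where(constant, 1.0, scale), constant,
                           table.feature_names)
    return apply_scaling(table, params), params


def apply_scaling(table: FeatureTable, params: ScalingParams) -> FeatureTable:
    """Apply train-fitted :class:`ScalingParams` to a (possibly held-out) table."""
    if table.n_features != params.center.size:
        raise SchemaError("scaling parameters were fitted on a different width")
    out = (table.values - params.center) / params.scale
    out[:, params.constant_mask] = 0.0
    return FeatureTable(out, list(table.descriptors), list(table.patient_ids))


def subset_by_category(table: FeatureTable,
                       modalities: Iterable[Modality | str],
                       filter_classes: Iterable[FilterClass | str]) -> FeatureTable:
    """Columns whose descriptor matches both selection sets, order preserved."""
    modalities = {Modality(m) for m in modalities}
    filter_classes = {FilterClass(f) for f in filter_classes}
    if not modalities or not filter_classes:
        raise EmptySelectionError("selection sets must be non-empty")
    idx = [i for i, d in enumerate(table.descriptors)
           if d.modality in modalities and d.filter_class in filter_classes]
    if not idx:
        raise EmptySelectionError(
            f"no columns match modalities={sorted(m.value for m in modalities)} "
            f"x filter_classes={sorted(f.value for f in filter_classes)}")
    return FeatureTable(table.values[:, idx], [table.descriptors[i] for i in idx],
                        list(table.patient_ids))


def _read_indexed_csv(path: str | Path, id_column: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    if id_column not in df.columns:
        raise SchemaError(f"{path}: id column {id_column!r} not found")
    return df.set_index(df[id_column].astype(str)).drop(columns=[id_column])


def load_tables(radiomic_paths: dict[str, str | Path],
                clinical_path: str | Path,
                label_column: str,
                id_column: str = "patient_id",
                center_column: str | None = None,
                clinical_schema: dict[str, list[str]] | None = None,
                ) -> tuple[FeatureTable, ClinicalTable, np.ndarray, np.ndarray | None]:
    """Load per-modality radiomic CSVs plus a clinical CSV and align them.

    Tables are aligned on the intersection of patient ids (order: as in the
    first radiomic file); unmatched rows are dropped and logged.  Returns
    ``(features, clinical, labels, centers)`` where ``labels`` is the binary
    outcome read from ``label_column`` of the clinical file and ``centers`` is
    the optional acquisition-center vector.
    """
    radiomic_frames = {Modality(m): _read_indexed_csv(p, id_column)
                       for m, p in radiomic_paths.items()}
    clin = _read_indexed_csv(clinical_path, id_column)
    if label_column not in clin.columns:
        raise SchemaError(f"label column {label_column!r} not in clinical file")

    ids: list[str] = []
    common = set(clin.index)
    for df in radiomic_frames.values():
        common &= set(df.index)
    for pid in next(iter(radiomic_frames.values())).index:
        if pid in common:
            ids.append(pid)
    if not ids:
        raise AlignmentError("patient id sets of the input files do not intersect")
    for name, df in {**{m.value: f for m, f in radiomic_frames.items()},
                     "clinical": clin}.items():
        dropped = set(df.index) - set(ids)
        if dropped:
            logger.info("load_tables: dropping %d unmatched patient(s) from %s: %s",
                        len(dropped), name, sorted(dropped)[:5])

    blocks, descriptors = [], []
    for modality, df in radiomic_frames.items():
        df = df.loc[ids]
        blocks.append(df.to_numpy(dtype=float))
        descriptors.extend(parse_feature_name(c, modality) for c in df.columns)
    features = FeatureTable(np.hstack(blocks), descriptors, ids)

    clin = clin.loc[ids]
    labels_raw = clin[label_column]
    uniques = sorted(pd.unique(labels_raw.dropna()))
    if len(uniques) != 2:
        raise SchemaError(f"labels must be binary, got levels {uniques}")
    labels = (labels_raw == uniques[1]).to_numpy(dtype=int)

    centers = None
    drop_cols = [label_column]
    if center_column is not None:
        if center_column not in clin.columns:
            raise SchemaError(f"center column {center_column!r} not in clinical file")
        c_uniques = sorted(pd.unique(clin[center_column].dropna()))
        centers = (clin[center_column] == c_uniques[-1]).to_numpy(dtype=int)
        drop_cols.append(center_column)
    clin_vars = clin.drop(columns=drop_cols)
    if clinical_schema is None:
        clinical_schema = {c: sorted(map(str, pd.unique(clin_vars[c].dropna())))
                           for c in clin_vars.columns}
    clin_vars = clin_vars.astype("object").where(clin_vars.notna(), np.nan)
    for c in clin_vars.columns:
        clin_vars[c] = clin_vars[c].map(lambda v: v if pd.isna(v) else str(v))
    clinical = ClinicalTable(clin_vars, clinical_schema)
    return features, clinical, labels, centers


class ClinicalEncoder:
    """Encode categorical clinical variables as a numeric design matrix.

    Binary variables become a single 0/1 column; variables with three or more
    levels are one-hot encoded (one column per level).  Missing codes are
    imputed with the mode of the fitting split; every imputation is logged.
    """

    def __init__(self) -> None:
        self.modes_: dict[str, str] = {}
        self.schema_: dict[str, list[str]] = {}
        self.columns_: list[str] = []

    def fit(self, clinical: ClinicalTable) -> "ClinicalEncoder":
        self.schema_ = {v: list(lv) for v, lv in clinical.schema.items()}
        self.columns_ = []
        for var, levels in self.schema_.items():
            col = clinical.data[var]
            observed = col.dropna()
            self.modes_[var] = (observed.mode().iloc[0] if len(observed) else levels[0])
            if len(levels) <= 2:
                self.columns_.append(var)
            else:
                self.columns_.extend(f"{var}={lv}" for lv in levels)
        return self

    def transform(self, clinical: ClinicalTable) -> FeatureTable:
        if not self.columns_:
            raise RuntimeError("encoder not fitted")
        out = np.zeros((len(clinical.data), len(self.columns_)))
        j = 0
        for var, levels in self.schema_.items():
            col = clinical.data[var]
            n_missing = int(col.isna().sum())
            if n_missing:
                logger.info("imputed %d missing value(s) of %r with mode %r",
                            n_missing, var, self.modes_[var])
            filled = col.fillna(self.modes_[var])
            if len(levels) <= 2:
                out[:, j] = (filled == levels[-1]).to_numpy(float)
                j += 1
            else:
                for lv in levels:
                    out[:, j] = (filled == lv).to_numpy(float)
                    j += 1
        descriptors = [FeatureDescriptor(c, Modality.clinical) for c in self.columns_]
        return FeatureTable(out, descriptors, clinical.patient_ids)

    def fit_transform(self, clinical: ClinicalTable) -> FeatureTable:
        return self.fit(clinical).transform(clinical)
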