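"""Synthetic two-center radiomic cohort generator.

Emulates the statistical structure of a two-center MRI radiomics study of
sinonasal tumors: ~145 patients in a roughly 52/48 malignant/benign split,
highly redundant radiomic feature blocks (Original / LoG / Wavelet per image
modality) drawn from equicorrelated Gaussians, a small set of discriminative
features with a planted standardized mean difference, categorical clinical
variables whose bias-corrected Cramér's V against the outcome is calibrated
to a target, and an additive acquisition-center batch shift.

The generator does not synthesize images; it produces the wide feature
tables a radiomic extractor would emit, with column names in the extractor
dialect so the parsing layer treats synthetic and real tables identically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _radiomics_names as _names
from .feature_table import (ClinicalTable, FeatureTable, Modality, FilterClass,
                            parse_feature_name)

__all__ = [
    "BlockSpec",
    "ClinicalVariableSpec",
    "SimConfig",
    "SyntheticCohort",
    "calibrate_association",
    "population_cramers_v",
    "generate_cohort",
    "write_cohort",
    "default_clinical_schema",
]


class SimulationConfigError(ValueError):
    """The simulation configuration is infeasible or inconsistent."""


@dataclass(frozen=True)
class BlockSpec:
    """One (modality, filter class) block of correlated radiomic features."""

    modality: str
    filter_class: str
    n_features: int
    n_informative: int = 0
    n_redundant_pairs: int = 0

    def validate(self) -> None:
        if self.n_features < 1:
            raise SimulationConfigError("block must hold at least one feature")
        if self.n_informative > self.n_features:
            raise SimulationConfigError("n_informative exceeds block size")
        if self.n_informative + 2 * self.n_redundant_pairs > self.n_features:
            raise SimulationConfigError(
                "informative + redundant-pair columns exceed block size")


@dataclass(frozen=True)
class ClinicalVariableSpec:
    """A categorical variable, its marginal level frequencies and its
    target bias-corrected Cramér's V against the outcome."""

    levels: tuple[str, ...]
    marginal: tuple[float, ...]
    target_v: float = 0.1
    missing_rate: float = 0.0

    def validate(self) -> None:
        if len(self.levels) < 2 or len(self.levels) != len(self.marginal):
            raise SimulationConfigError("need >= 2 levels with one frequency each")
        if not math.isclose(sum(self.marginal), 1.0, abs_tol=1e-6):
            raise SimulationConfigError("marginal frequencies must sum to 1")
        if not 0.0 <= self.target_v < 1.0:
            raise SimulationConfigError("target V must lie in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SimulationConfigError("missing rate must lie in [0, 1)")


def _study_blocks(scale: float = 1.0) -> tuple[BlockSpec, ...]:
    """Block layout of the emulated extraction protocol: per modality,
    107 Original + 4x93 LoG + 8x93 Wavelet features."""
    blocks = []
    for modality in ("CE_T1w", "T2w"):
        for fc, size in (("Original", 107), ("LoG", 372), ("Wavelet", 744)):
            n = max(3, int(round(size * scale)))
            blocks.append(BlockSpec(modality, fc, n, n_informative=5,
                                    n_redundant_pairs=10 if n >= 25 else 0))
    return tuple(blocks)


def default_clinical_schema() -> dict[str, ClinicalVariableSpec]:
    """Clinical schema mirroring the emulated cohort's composition.

    Marginals are the observed level frequencies; the three variables with a
    documented outcome association (gross adjacent site involvement 0.38,
    symptoms 0.41, tumor size 0.38) carry those corrected-V targets, all
    others default to a weak 0.1.  The five incompletely recorded variables
    get a small missing rate.
    """
    return {
        "sex": ClinicalVariableSpec(("female", "male"), (0.28, 0.72), 0.1),
        "gross_adjacent_involvement": ClinicalVariableSpec(
            ("no", "yes"), (0.85, 0.15), 0.38, missing_rate=0.01),
        "symptoms": ClinicalVariableSpec(
            ("nonspecific", "red_flags"), (0.46, 0.54), 0.41),
        "tumor_size": ClinicalVariableSpec(
            ("lt5cm", "ge5cm"), (0.42, 0.58), 0.38, missing_rate=0.01),
        "side": ClinicalVariableSpec(
            ("left", "right", "bilateral"), (0.47, 0.50, 0.03), 0.1),
        "margins": ClinicalVariableSpec(
            ("well_defined", "ill_defined"), (0.33, 0.67), 0.1),
        "pattern": ClinicalVariableSpec(
            ("homogeneous", "inhomogeneous"), (0.21, 0.79), 0.1),
        "necrosis": ClinicalVariableSpec(("lt10pct", "ge10pct"), (0.41, 0.59), 0.1),
        "t2w_low_signal": ClinicalVariableSpec(("le50pct", "gt50pct"), (0.71, 0.29), 0.1),
        "cystic_component": ClinicalVariableSpec(("no", "yes"), (0.56, 0.44), 0.1),
        "septation": ClinicalVariableSpec(("no", "yes"), (0.92, 0.08), 0.1),
        "bone_involvement": ClinicalVariableSpec(
            ("no", "yes"), (0.43, 0.57), 0.1, missing_rate=0.01),
        "perineural_spread": ClinicalVariableSpec(
            ("no", "yes"), (0.84, 0.16), 0.1, missing_rate=0.01),
        "midline_crossing": ClinicalVariableSpec(("no", "yes"), (0.65, 0.35), 0.1),
        "epicenter": ClinicalVariableSpec(
            ("nasal_cavity", "ethmoid_sinus", "maxillary_sinus", "frontal_sinus",
             "sphenoid_sinus"),
            (0.254, 0.331, 0.331, 0.042, 0.042), 0.1, missing_rate=0.01),
    }


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the synthetic cohort.

    Defaults mirror the emulated study: 145 patients, 52% malignant, an
    82/18 center split, the full Original/LoG/Wavelet block layout per
    modality, a moderate planted effect (d = 0.8 on 5 features per block),
    strong within-block correlation and a mild 0.5-SD center shift.
    """

    n_patients: int = 145
    class_balance: float = 0.52
    blocks: tuple[BlockSpec, ...] = field(default_factory=_study_blocks)
    effect_size: float = 0.8
    block_rho: float = 0.5
    redundant_rho: float = 0.98
    clinical_schema: dict[str, ClinicalVariableSpec] = field(
        default_factory=default_clinical_schema)
    batch_shift: float = 0.5
    center_balance: float = 0.82
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise SimulationConfigError("need at least two patients")
        for frac, name in ((self.class_balance, "class_balance"),
                           (self.center_balance, "center_balance")):
            if not 0.0 < frac < 1.0:
                raise SimulationConfigError(f"{name} must lie in (0, 1)")
        if not 0.0 <= self.block_rho < 1.0:
            raise SimulationConfigError("block_rho must lie in [0, 1)")
        if self.effect_size < 0:
            raise SimulationConfigError("effect_size must be >= 0")
        if not 0.9 <= self.redundant_rho < 1.0:
            raise SimulationConfigError("redundant_rho must lie in [0.9, 1)")
        for blk in self.blocks:
            blk.validate()
        for spec in self.clinical_schema.values():
            spec.validate()

    def scaled(self, feature_scale: float) -> "SimConfig":
        """Config with every block shrunk by ``feature_scale`` (for quick runs)."""
        blocks = []
        for blk in self.blocks:
            n = max(3, int(round(blk.n_features * feature_scale)))
            blocks.append(replace(
                blk, n_features=n,
                n_informative=min(blk.n_informative, n),
                n_redundant_pairs=min(blk.n_redundant_pairs,
                                      (n - blk.n_informative) // 2)))
        return replace(self, blocks=tuple(blocks))


@dataclass
class SyntheticCohort:
    features: FeatureTable
    clinical: ClinicalTable
    labels: np.ndarray
    centers: np.ndarray
    truth: list[str]
    config: SimConfig


# ---------------------------------------------------------------------------
# association calibration

def population_cramers_v(p_pos: np.ndarray, p_neg: np.ndarray, class_balance: float) -> float:
    """Population Cramér's V between a categorical variable and a binary class
    given the class-conditional level distributions."""
    p_pos, p_neg = np.asarray(p_pos, float), np.asarray(p_neg, float)
    b = class_balance
    joint = np.column_stack([(1 - b) * p_neg, b * p_pos])  # levels x class
    pi = joint.sum(axis=1, keepdims=True)
    pc = joint.sum(axis=0, keepdims=True)
    expected = pi @ pc
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = np.where(expected > 0, (joint - expected) ** 2 / expected, 0.0)
    phi2 = float(cells.sum())
    return math.sqrt(phi2 / min(joint.shape[0] - 1, 1))


def calibrate_association(levels: Sequence[str], target_v: float, class_balance: float,
                          marginal: Sequence[float] | None = None,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Class-conditional level distributions with a prescribed population V.

    Returns ``(p_pos, p_neg)`` — the level distributions in the positive
    (malignant) and negative class — such that the population Cramér's V
    equals ``target_v`` (to 1e-6) while the pooled marginal stays at
    ``marginal``.  Binary variables are solved in closed form; for >= 3
    levels a one-parameter exponential tilt of the marginal is rooted
    numerically.  Raises :class:`SimulationConfigError` when the target is
    unreachable for the level set / marginal.
    """
    r = len(levels)
    if r < 2:
        raise SimulationConfigError("need at least two levels")
    if not 0.0 <= target_v <= 1.0:
        raise SimulationConfigError("target V must lie in [0, 1]")
    b = class_balance
    if marginal is None:
        if r == 2 and target_v == 1.0:
            marginal = np.array([1 - b, b])  # the only marginal making V = 1 feasible
        else:
            marginal = np.full(r, 1.0 / r)
    m = np.asarray(marginal, float)
    if target_v == 0.0:
        return m.copy(), m.copy()

    if r == 2:
        delta = target_v * math.sqrt(m[0] * m[1] / (b * (1 - b)))
        p_pos = np.array([m[0] - delta * (1 - b), m[1] + delta * (1 - b)])
        p_neg = np.array([m[0] + delta * b, m[1] - delta * b])
        if (p_pos < -1e-12).any() or (p_neg < -1e-12).any() \
                or (p_pos > 1 + 1e-12).any() or (p_neg > 1 + 1e-12).any():
            raise SimulationConfigError(
                f"target V={target_v} unreachable for binary marginal {m.tolist()} "
                f"at class balance {b}")
        p_pos, p_neg = np.clip(p_pos, 0, 1), np.clip(p_neg, 0, 1)
        return p_pos / p_pos.sum(), p_neg / p_neg.sum()

    from scipy.optimize import brentq

    scores = np.arange(r, dtype=float)
    scores -= scores.mean()

    def conditionals(t: float) -> tuple[np.ndarray, np.ndarray] | None:
        w = m * np.exp(t * scores)
        p_pos = w / w.sum()
        p_neg = (m - b * p_pos) / (1 - b)
        if (p_neg < -1e-12).any():
            return None
        return p_pos, np.clip(p_neg, 0, None) / np.clip(p_neg, 0, None).sum()

    def v_of(t: float) -> float:
        cond = conditionals(t)
        if cond is None:
            return math.nan
        return population_cramers_v(cond[0], cond[1], b)

    # largest feasible tilt (p_neg stays a distribution): bisect from t=0,
    # which is always feasible (both conditionals equal the marginal)
    lo, hi = 0.0, 1.0
    while conditionals(hi) is not None and hi < 512:
        lo, hi = hi, hi * 2
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        lo, hi = (mid, hi) if conditionals(mid) is not None else (lo, mid)
    t_max = lo
    if v_of(t_max) < target_v:
        raise SimulationConfigError(
            f"target V={target_v} unreachable for levels {list(levels)} "
            f"(max feasible V = {v_of(t_max):.4f})")
    t_star = brentq(lambda t: v_of(t) - target_v, 0.0, t_max, xtol=1e-12)
    return conditionals(t_star)


# ---------------------------------------------------------------------------
# cohort generation

def _block_feature_names(block: BlockSpec) -> list[str]:
    fc = FilterClass(block.filter_class)
    names: list[str] = []
    if fc is FilterClass.Original:
        for family in ("shape", *_names.INTENSITY_FAMILIES):
            names.extend(f"original_{family}_{nm}" for nm in _names.FAMILY_NAMES[family])
    elif fc is FilterClass.LoG:
        for sigma in _names.LOG_SIGMAS_MM:
            a, b = sigma.split(".")
            for family in _names.INTENSITY_FAMILIES:
                names.extend(f"log-sigma-{a}-{b}-mm-3D_{family}_{nm}"
                             for nm in _names.FAMILY_NAMES[family])
    elif fc is FilterClass.Wavelet:
        for band in _names.WAVELET_SUBBANDS:
            for family in _names.INTENSITY_FAMILIES:
                names.extend(f"wavelet-{band}_{family}_{nm}"
                             for nm in _names.FAMILY_NAMES[family])
    else:
        raise SimulationConfigError(f"unsupported filter class {block.filter_class!r}")
    if block.n_features > len(names):
        raise SimulationConfigError(
            f"{block.modality}/{block.filter_class}: at most {len(names)} distinct "
            f"feature names available, requested {block.n_features}")
    return names[: block.n_features]


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Draw one fully reproducible synthetic cohort from ``config``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    n_pos = math.ceil(n * config.class_balance)
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)

    # centers stratified by class so center and outcome are unconfounded
    centers = np.zeros(n, dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        n_b = int(round(len(idx) * (1 - config.center_balance)))
        chosen = rng.choice(idx, size=n_b, replace=False)
        centers[chosen] = 1

    blocks_values, descriptors, truth = [], [], []
    rho, d = config.block_rho, config.effect_size
    for block in config.blocks:
        names = _block_feature_names(block)
        shared = rng.normal(size=(n, 1))
        noise = rng.normal(size=(n, block.n_features))
        values = math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * noise
        if block.n_informative and d > 0:
            values[:, : block.n_informative] += d * labels[:, None]
        base = block.n_informative
        for pair in range(block.n_redundant_pairs):
            src, dst = base + 2 * pair, base + 2 * pair + 1
            eps = rng.normal(size=n)
            values[:, dst] = (config.redundant_rho * values[:, src]
                              + math.sqrt(1 - config.redundant_rho ** 2) * eps)
        blocks_values.append(values)
        modality = Modality(block.modality)
        descriptors.extend(parse_feature_name(nm, modality) for nm in names)
        truth.extend(f"{modality.value}__{nm}" for nm in names[: block.n_informative])

    values = np.hstack(blocks_values) if blocks_values else np.empty((n, 0))
    if config.batch_shift and values.size:
        values[centers == 1] += config.batch_shift

    patient_ids = [f"P{i + 1:04d}" for i in range(n)]
    features = FeatureTable(values, descriptors, patient_ids)

    clin_cols: dict[str, np.ndarray] = {}
    schema: dict[str, list[str]] = {}
    for var, spec in config.clinical_schema.items():
        p_pos, p_neg = calibrate_association(spec.levels, spec.target_v,
                                             config.class_balance, spec.marginal)
        u = rng.random(n)
        idx_pos = np.searchsorted(np.cumsum(p_pos), u, side="right")
        idx_neg = np.searchsorted(np.cumsum(p_neg), u, side="right")
        lvl = np.where(labels == 1, idx_pos, idx_neg).clip(max=len(spec.levels) - 1)
        codes = np.array(spec.levels, dtype=object)[lvl]
        if spec.missing_rate:
            miss = rng.random(n) < spec.missing_rate
            codes[miss] = np.nan
        clin_cols[var] = codes
        schema[var] = list(spec.levels)
    clinical = ClinicalTable(pd.DataFrame(clin_cols,
                                          index=pd.Index(patient_ids, name="patient_id")),
                             schema)
    return SyntheticCohort(features, clinical, labels, centers, truth, config)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort as the CSV layout the loader consumes + truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for modality in sorted({d.modality for d in cohort.features.descriptors},
                           key=lambda m: m.value):
        idx = [i for i, d in enumerate(cohort.features.descriptors) if d.modality is modality]
        frame = pd.DataFrame(cohort.features.values[:, idx],
                             index=pd.Index(cohort.features.patient_ids, name="patient_id"),
                             columns=[cohort.features.descriptors[i].name for i in idx])
        path = outdir / f"radiomics_{modality.value}.csv"
        frame.to_csv(path)
        paths[modality.value] = path
    clin = cohort.clinical.data.copy()
    clin["tumor_type"] = np.where(cohort.labels == 1, "malignant", "benign")
    clin["center"] = np.where(cohort.centers == 1, "Como", "Varese")
    paths["clinical"] = outdir / "clinical.csv"
    clin.to_csv(paths["clinical"])
    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(json.dumps(
        {"informative_features": cohort.truth,
         "n_patients": cohort.config.n_patients,
         "seed": cohort.config.seed}, indent=1))
    return paths
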