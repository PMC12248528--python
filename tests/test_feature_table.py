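"""Feature-name parsing, table alignment, category slicing, standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from radsignet import (FeatureDescriptor, FeatureTable, Family, FilterClass,
                       Modality, ScalingParams, apply_scaling, canonical_name,
                       load_tables, parse_feature_name, standardize,
                       subset_by_category)
from radsignet.feature_table import (AlignmentError, ClinicalEncoder,
                                     ClinicalTable, EmptySelectionError,
                                     FeatureNameError, SchemaError)
from radsignet import _radiomics_names as vocab


@pytest.mark.parametrize("name,modality,fc,family,param", [
    ("original_glcm_JointAverage", "CE_T1w", FilterClass.Original, Family.glcm, None),
    ("log-sigma-1-0-mm-3D_firstorder_Skewness", "CE_T1w", FilterClass.LoG,
     Family.firstorder, "1.0"),
    ("wavelet-LLH_glszm_SizeZoneNonUniformityNormalized", "T2w",
     FilterClass.Wavelet, Family.glszm, "LLH"),
    ("log-sigma-0-5-mm-3D_gldm_LowGrayLevelEmphasis", "T2w", FilterClass.LoG,
     Family.gldm, "0.5"),
    ("tumor_size", "clinical", FilterClass.none, Family.clinical, None),
    ("age", "clinical", FilterClass.none, Family.clinical, None),
])
def test_parse_feature_name_dialect(name, modality, fc, family, param):
    d = parse_feature_name(name, modality)
    assert (d.filter_class, d.family, d.filter_param) == (fc, family, param)
    assert d.name == name


def test_parse_rejects_empty_name():
    with pytest.raises(FeatureNameError):
        parse_feature_name("", "CE_T1w")


@given(
    fc=st.sampled_from([FilterClass.Original, FilterClass.LoG, FilterClass.Wavelet]),
    family=st.sampled_from(vocab.INTENSITY_FAMILIES),
    base_idx=st.integers(0, 4),
    sigma=st.sampled_from(vocab.LOG_SIGMAS_MM),
    band=st.sampled_from(vocab.WAVELET_SUBBANDS),
)
def test_parse_canonical_round_trip(fc, family, base_idx, sigma, band):
    """descriptor -> canonical name -> descriptor is the identity."""
    base = vocab.FAMILY_NAMES[family][base_idx]
    param = {FilterClass.Original: None, FilterClass.LoG: sigma,
             FilterClass.Wavelet: band}[fc]
    d = FeatureDescriptor(f"x_{family}_{base}", Modality.T2w, fc, Family(family), param)
    rebuilt = parse_feature_name(canonical_name(d), Modality.T2w)
    assert (rebuilt.filter_class, rebuilt.family, rebuilt.filter_param) == \
        (d.filter_class, d.family, d.filter_param)
    assert canonical_name(rebuilt) == canonical_name(d)


def test_descriptor_invariants_enforced():
    with pytest.raises(ValueError):
        FeatureDescriptor("x", Modality.CE_T1w, FilterClass.LoG, Family.glcm, None)
    with pytest.raises(ValueError):
        FeatureDescriptor("x", Modality.CE_T1w, FilterClass.Wavelet, Family.glcm, "LX")
    with pytest.raises(ValueError):
        FeatureDescriptor("x", Modality.clinical, FilterClass.LoG, Family.glcm, "1.0")


# ---------------------------------------------------------------------------
# loading / alignment


def _write_cohort_csvs(tmp_path, ids_radiomic, ids_clinical):
    rng = np.random.default_rng(0)
    for modality in ("CE_T1w", "T2w"):
        df = pd.DataFrame({
            "patient_id": ids_radiomic,
            "original_glcm_JointAverage": rng.normal(size=len(ids_radiomic)),
            "log-sigma-1-0-mm-3D_firstorder_Mean": rng.normal(size=len(ids_radiomic)),
        })
        df.to_csv(tmp_path / f"radiomics_{modality}.csv", index=False)
    clin = pd.DataFrame({
        "patient_id": ids_clinical,
        "tumor_type": ["malignant" if i % 2 else "benign"
                       for i in range(len(ids_clinical))],
        "symptoms": ["red_flags" if i % 3 else "nonspecific"
                     for i in range(len(ids_clinical))],
    })
    clin.to_csv(tmp_path / "clinical.csv", index=False)
    return {m: tmp_path / f"radiomics_{m}.csv" for m in ("CE_T1w", "T2w")}, \
        tmp_path / "clinical.csv"


def test_load_tables_aligns_on_id_intersection(tmp_path):
    ids = [f"P{i}" for i in range(10)]
    rad, clin = _write_cohort_csvs(tmp_path, ids, ids)
    features, clinical, labels, _ = load_tables(rad, clin, "tumor_type")
    assert features.n_patients == 10
    assert clinical.patient_ids == features.patient_ids == ids
    assert set(labels) == {0, 1}


def test_load_tables_drops_unmatched_patient(tmp_path):
    ids = [f"P{i}" for i in range(10)]
    rad, clin = _write_cohort_csvs(tmp_path, ids, ids + ["P_extra"])
    features, clinical, labels, _ = load_tables(rad, clin, "tumor_type")
    assert features.n_patients == 10
    assert "P_extra" not in clinical.patient_ids


def test_load_tables_disjoint_ids_error(tmp_path):
    rad, clin = _write_cohort_csvs(tmp_path, [f"A{i}" for i in range(5)],
                                   [f"B{i}" for i in range(5)])
    with pytest.raises(AlignmentError):
        load_tables(rad, clin, "tumor_type")


def test_load_tables_nonbinary_labels_error(tmp_path):
    ids = [f"P{i}" for i in range(6)]
    rad, clin = _write_cohort_csvs(tmp_path, ids, ids)
    df = pd.read_csv(clin)
    df.loc[0, "tumor_type"] = "borderline"
    df.to_csv(clin, index=False)
    with pytest.raises(SchemaError):
        load_tables(rad, clin, "tumor_type")


# ---------------------------------------------------------------------------
# category subsetting


def _mixed_table():
    names = [("original_glcm_JointAverage", "CE_T1w"),
             ("log-sigma-1-0-mm-3D_firstorder_Mean", "CE_T1w"),
             ("log-sigma-2-0-mm-3D_glrlm_RunEntropy", "CE_T1w"),
             ("wavelet-HHH_ngtdm_Contrast", "T2w"),
             ("original_firstorder_Median", "T2w")]
    desc = [parse_feature_name(n, m) for n, m in names]
    values = np.arange(15, dtype=float).reshape(3, 5)
    return FeatureTable(values, desc, ["a", "b", "c"])


def test_subset_by_category_filters_and_preserves_order():
    table = _mixed_table()
    log_t1 = subset_by_category(table, ["CE_T1w"], ["LoG"])
    assert log_t1.feature_names == ["log-sigma-1-0-mm-3D_firstorder_Mean",
                                    "log-sigma-2-0-mm-3D_glrlm_RunEntropy"]
    np.testing.assert_array_equal(log_t1.values, table.values[:, [1, 2]])


def test_subset_all_categories_is_identity():
    table = _mixed_table()
    out = subset_by_category(table, ["CE_T1w", "T2w"],
                             ["Original", "LoG", "Wavelet", "none"])
    np.testing.assert_array_equal(out.values, table.values)
    assert out.feature_names == table.feature_names


def test_subset_empty_selection_error():
    table = subset_by_category(_mixed_table(), ["CE_T1w"], ["Original", "LoG"])
    with pytest.raises(EmptySelectionError):
        subset_by_category(table, ["T2w"], ["Original"])


# ---------------------------------------------------------------------------
# standardization


def test_zscore_uses_population_sd():
    table = FeatureTable(np.array([[1.0], [2.0], [3.0]]),
                         [parse_feature_name("original_firstorder_Mean", "T2w")],
                         ["a", "b", "c"])
    out, _ = standardize(table, "zscore")
    np.testing.assert_allclose(out.values.ravel(),
                               [-1.224744871391589, 0.0, 1.224744871391589],
                               atol=1e-12)


def test_robust_scaling_median_iqr():
    # [1,2,3]: median 2, Q1 = 1.5, Q3 = 2.5 under linear-interpolation
    # quantiles, so IQR = 1 and the scaled column is [-1, 0, 1] (its own IQR
    # is then exactly 1, as the robust-scaling contract requires)
    table = FeatureTable(np.array([[1.0], [2.0], [3.0]]),
                         [parse_feature_name("original_firstorder_Mean", "T2w")],
                         ["a", "b", "c"])
    out, _ = standardize(table, "robust")
    np.testing.assert_allclose(out.values.ravel(), [-1.0, 0.0, 1.0], atol=1e-12)


@pytest.mark.parametrize("method", ["zscore", "robust"])
def test_constant_column_maps_to_zeros_with_warning(method):
    table = FeatureTable(np.array([[5.0], [5.0], [5.0]]),
                         [parse_feature_name("original_firstorder_Mean", "T2w")],
                         ["a", "b", "c"])
    with pytest.warns(UserWarning, match="constant"):
        out, params = standardize(table, method)
    np.testing.assert_array_equal(out.values.ravel(), [0.0, 0.0, 0.0])
    assert params.constant_mask.tolist() == [True]


def test_standardization_invariants(rng):
    values = rng.normal(size=(40, 6)) * rng.uniform(0.5, 3, 6) + rng.normal(size=6)
    desc = [parse_feature_name(f"original_firstorder_{n}", "T2w")
            for n in ["Mean", "Median", "Energy", "Entropy", "Maximum", "Minimum"]]
    table = FeatureTable(values, desc, [f"p{i}" for i in range(40)])
    z, _ = standardize(table, "zscore")
    assert np.abs(z.values.mean(axis=0)).max() < 1e-9
    assert np.abs(z.values.std(axis=0) - 1).max() < 1e-9
    r, _ = standardize(table, "robust")
    assert np.abs(np.median(r.values, axis=0)).max() < 1e-9
    q1, q3 = np.percentile(r.values, [25, 75], axis=0)
    assert np.abs((q3 - q1) - 1).max() < 1e-9


def test_scaling_params_reapply_bitwise_and_serialize(tmp_path, rng):
    values = rng.normal(size=(30, 4))
    desc = [parse_feature_name(f"original_firstorder_{n}", "T2w")
            for n in ["Mean", "Median", "Energy", "Entropy"]]
    table = FeatureTable(values, desc, [f"p{i}" for i in range(30)])
    fitted, params = standardize(table, "robust")
    reapplied = apply_scaling(table, params)
    np.testing.assert_array_equal(fitted.values, reapplied.values)

    params.to_json(tmp_path / "scale.json")
    loaded = ScalingParams.from_json(tmp_path / "scale.json")
    np.testing.assert_array_equal(apply_scaling(table, loaded).values, fitted.values)


# ---------------------------------------------------------------------------
# clinical encoding


def test_clinical_encoder_binary_and_onehot():
    data = pd.DataFrame({
        "symptoms": ["red_flags", "nonspecific", np.nan, "red_flags"],
        "side": ["left", "right", "bilateral", np.nan],
    }, index=pd.Index(list("abcd"), name="patient_id"))
    table = ClinicalTable(data, {"symptoms": ["nonspecific", "red_flags"],
                                 "side": ["left", "right", "bilateral"]})
    enc = ClinicalEncoder()
    out = enc.fit_transform(table)
    assert out.feature_names == ["symptoms", "side=left", "side=right",
                                 "side=bilateral"]
    # missing symptoms imputed with the mode (red_flags appears twice)
    np.testing.assert_array_equal(out.values[:, 0], [1, 0, 1, 1])
    # one-hot rows sum to 1 after imputation
    np.testing.assert_array_equal(out.values[:, 1:].sum(axis=1), np.ones(4))


def test_clinical_table_rejects_codes_outside_level_set():
    data = pd.DataFrame({"symptoms": ["weird"]},
                        index=pd.Index(["a"], name="patient_id"))
    with pytest.raises(SchemaError):
        ClinicalTable(data, {"symptoms": ["nonspecific", "red_flags"]})
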