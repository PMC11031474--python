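"""Preprocessing, exclusion criteria and ANOVA feature selection."""

import numpy as np
import pytest
from sklearn.feature_selection import f_classif

from sectorvit.cohort import (EmptyTumorError, PatientRecord, PreprocessConfig,
                              RawSlice, RADIOMIC_SECTORS, anova_f,
                              apply_exclusion_criteria, balance_classes,
                              crop_to_mask_bbox, exclude_small_mask,
                              encode_demographics, resize_to_square,
                              select_top_features, split_by_patient)
from sectorvit.simulate import SimConfig, generate_cohort, make_masked_slice


# -- small-mask exclusion ----------------------------------------------------

def test_small_mask_threshold_is_exact_at_boundary():
    mask = np.zeros((64, 64), dtype=int)
    mask.flat[:255] = 2
    assert exclude_small_mask(mask, 256) is True
    mask.flat[255] = 2  # 256 nonzero pixels: retained
    assert exclude_small_mask(mask, 256) is False


def test_all_zero_mask_always_excluded():
    assert exclude_small_mask(np.zeros((8, 8), dtype=int), 1) is True


def test_empty_mask_grid_rejected():
    with pytest.raises(ValueError):
        exclude_small_mask(np.zeros((0, 0)), 256)


# -- bounding-box crop -------------------------------------------------------

def test_crop_spans_inclusive_bbox():
    img = np.arange(64 * 64, dtype=float).reshape(64, 64)
    mask = np.zeros((64, 64), dtype=int)
    mask[10:21, 5:31] = 1
    out = crop_to_mask_bbox(img, mask)
    assert out.shape == (11, 26)
    assert np.array_equal(out, img[10:21, 5:31])


def test_crop_full_mask_is_identity_and_single_pixel():
    img = np.random.default_rng(0).normal(size=(9, 9))
    assert np.array_equal(crop_to_mask_bbox(img, np.ones((9, 9), int)), img)
    mask = np.zeros((9, 9), int)
    mask[4, 7] = 3
    out = crop_to_mask_bbox(img, mask)
    assert out.shape == (1, 1) and out[0, 0] == img[4, 7]


def test_crop_errors():
    img = np.zeros((4, 4))
    with pytest.raises(EmptyTumorError):
        crop_to_mask_bbox(img, np.zeros((4, 4), int))
    with pytest.raises(ValueError):
        crop_to_mask_bbox(img, np.zeros((4, 5), int))


# -- resize ------------------------------------------------------------------

def test_resize_shapes_and_constant_preservation():
    rng = np.random.default_rng(1)
    out = resize_to_square(rng.normal(size=(11, 26)), 128)
    assert out.shape == (128, 128) and np.all(np.isfinite(out))
    const = resize_to_square(np.full((128, 128), 3.25), 128)
    assert np.allclose(const, 3.25)
    tiny = resize_to_square(np.array([[7.0]]), 4)
    assert tiny.shape == (4, 4) and np.allclose(tiny, 7.0)


def test_resize_rejects_bad_target():
    with pytest.raises(ValueError):
        resize_to_square(np.ones((4, 4)), 0)


# -- exclusion criteria ------------------------------------------------------

def _raw_patient(pid, age=60.0, sex=1, label=1):
    return PatientRecord(pid, age, sex, label, [])


def _raw_slices(pid, n, rng, bad_sector=None):
    out = []
    for k in range(n):
        img, mask = make_masked_slice(1, 0.0, rng)
        rad = {s: rng.normal(size=105) for s in RADIOMIC_SECTORS}
        if bad_sector:
            rad[bad_sector] = None
        out.append(RawSlice(pid, f"{pid}_s{k}", img, img.copy(), mask, rad))
    return out


def test_criteria_i_to_iii_drop_and_log(rng):
    patients = [_raw_patient("A"), _raw_patient("B", sex=None),
                _raw_patient("C", label=None), _raw_patient("D")]
    slices = (_raw_slices("A", 3, rng) + _raw_slices("B", 3, rng)
              + _raw_slices("C", 3, rng) + _raw_slices("D", 3, rng, bad_sector="T2WI-ED"))
    cohort, log = apply_exclusion_criteria(patients, slices, PreprocessConfig())
    assert [p.patient_id for p in cohort.patients] == ["A"]
    assert log["i_missing_age_sex"] == 1
    assert log["ii_missing_label"] == 1
    assert log["iii_unextractable_radiomics"] == 1
    assert log["excluded_patient_ids"] == {"B": "i", "C": "ii", "D": "iii"}


def test_criterion_iv_image_count_outlier(rng):
    # counts {10,10,10,10,100}: mean 28, SD ~40.2; with k=1 the 100-image
    # patient lies above mean + SD and is excluded
    patients = [_raw_patient(p) for p in "ABCDE"]
    slices = []
    for pid, n in zip("ABCDE", [10, 10, 10, 10, 100]):
        slices += _raw_slices(pid, n, rng)
    cfg = PreprocessConfig(image_count_sd_multiplier=1.0)
    cohort, log = apply_exclusion_criteria(patients, slices, cfg)
    assert log["iv_image_count_outlier"] == 1
    assert log["excluded_patient_ids"] == {"E": "iv"}
    # with a huge k nobody is excluded
    cohort2, log2 = apply_exclusion_criteria(
        patients, slices, PreprocessConfig(image_count_sd_multiplier=100.0))
    assert log2["iv_image_count_outlier"] == 0
    assert len(cohort2.patients) == 5


def test_slices_below_pixel_floor_removed_before_criteria(rng):
    patients = [_raw_patient("A")]
    good = _raw_slices("A", 2, rng)
    img, mask = make_masked_slice(1, 0.0, rng, excludable=True)
    small = RawSlice("A", "A_tiny", img, img.copy(), mask,
                     {s: rng.normal(size=105) for s in RADIOMIC_SECTORS})
    cohort, log = apply_exclusion_criteria(patients, good + [small], PreprocessConfig())
    assert log["small_mask_slices"] == 1
    assert len(cohort) == 2
    assert all(s.image_ce_t1.shape == (128, 128) for s in cohort.samples)


# -- balancing and splitting -------------------------------------------------

def test_balance_classes_properties(tiny_cohort):
    cohort, _ = tiny_cohort
    labels = cohort.labels
    if (labels == 1).sum() == (labels == 0).sum():
        balanced = balance_classes(cohort, seed=3)
        assert len(balanced) == len(cohort)
    else:
        minority = int((labels == 1).sum() <= (labels == 0).sum())
        balanced = balance_classes(cohort, seed=3)
        b = balanced.labels
        assert (b == 1).sum() == (b == 0).sum() == (labels == minority).sum()
        ids = {(s.patient_id, s.slice_id) for s in cohort.samples}
        assert {(s.patient_id, s.slice_id) for s in balanced.samples} <= ids
    # determinism
    again = balance_classes(cohort, seed=3)
    assert [s.slice_id for s in again.samples] == [s.slice_id for s in balanced.samples]


def test_balance_requires_both_classes(tiny_cohort):
    cohort, _ = tiny_cohort
    one_class = cohort.subset_patients(
        [p.patient_id for p in cohort.patients if p.mgmt_label == 1])
    with pytest.raises(ValueError):
        balance_classes(one_class, seed=0)


def test_split_by_patient_partition(tiny_cohort):
    cohort, _ = tiny_cohort
    train, test = split_by_patient(cohort, test_count=2, seed=5)
    train_ids = {p.patient_id for p in train.patients}
    test_ids = {p.patient_id for p in test.patients}
    assert not (train_ids & test_ids)
    assert len(test_ids) == 2
    assert len(train.samples) + len(test.samples) == len(cohort.samples)
    with pytest.raises(ValueError):
        split_by_patient(cohort, test_fraction=0.0)


def test_encode_demographics_uses_training_statistics(tiny_cohort):
    cohort, _ = tiny_cohort
    train, test = split_by_patient(cohort, test_count=2, seed=5)
    encode_demographics(train, test)
    ages = np.array([p.age for p in train.patients])
    got = {s.patient_id: s.demographics[0] for s in train.samples}
    expect = (ages - ages.mean()) / ages.std(ddof=1)
    for p, e in zip(train.patients, expect):
        assert got[p.patient_id] == pytest.approx(e)
    assert all(s.demographics[1] in (0.0, 1.0) for s in test.samples)


# -- ANOVA -------------------------------------------------------------------

def test_anova_f_hand_example():
    # SSB = 1.5 (df 1), SSW = 4 (df 4) -> F = 1.5
    assert anova_f([1, 2, 3], [2, 3, 4]) == pytest.approx(1.5)
    assert anova_f([2, 3, 4], [1, 2, 3]) == pytest.approx(1.5)  # symmetry


def test_anova_f_degenerate_cases():
    assert anova_f([1, 2, 3], [3, 2, 1]) == 0.0            # equal means
    assert anova_f([1.0, 1.0], [1.0, 1.0]) == 0.0          # all identical
    assert anova_f([1.0, 1.0], [2.0, 2.0]) == np.inf       # zero within-variance
    with pytest.raises(ValueError):
        anova_f([1.0], [2.0, 3.0])


def test_select_top_features_matches_sklearn_on_random_tables(rng):
    for trial in range(5):
        X = rng.normal(size=(20, 50))
        y = rng.integers(0, 2, size=20)
        while len(np.unique(y)) < 2 or min((y == 0).sum(), (y == 1).sum()) < 2:
            y = rng.integers(0, 2, size=20)
        ours = select_top_features(X, y, k=10)
        f_sklearn, _ = f_classif(X, y)
        expected = [f"f{j}" for j in np.argsort(-f_sklearn, kind="stable")[:10]]
        assert ours == expected


def test_select_top_features_edges(rng):
    X = rng.normal(size=(10, 5))
    y = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
    assert len(select_top_features(X, y, k=5)) == 5
    with pytest.raises(ValueError):
        select_top_features(X, y, k=6)


def test_planted_feature_ranks_first(rng):
    y = np.repeat([0, 1], 15)
    X = rng.normal(size=(30, 20))
    X[:, 13] += 5.0 * y  # huge effect on one feature
    assert select_top_features(X, y, k=1) == ["f13"]
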