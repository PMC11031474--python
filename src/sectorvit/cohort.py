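"""Cohort construction: exclusion criteria, image preprocessing and
ANOVA-based radiomic feature selection.

The analysis unit is the 2-D tumor slice.  Each retained slice carries two
128x128 MR images (contrast-enhanced T1-weighted and T2-weighted), six
radiomic vectors (one per modality x tumor-compartment sector) and the
patient's encoded demographics; the label is the patient's MGMT promoter
methylation status.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from PIL import Image

RADIOMIC_SECTORS = (
    "CE-T1WI-ET", "CE-T1WI-NCR", "CE-T1WI-ED",
    "T2WI-ET", "T2WI-NCR", "T2WI-ED",
)
IMAGE_SECTORS = ("CE-T1WI", "T2WI")
DEMOGRAPHIC_SECTOR = "demographics"
#: the nine data sectors, in canonical order
SECTOR_ORDER = (DEMOGRAPHIC_SECTOR,) + RADIOMIC_SECTORS + IMAGE_SECTORS


class EmptyTumorError(ValueError):
    """Mask contains no tumor pixels where at least one is required."""


class EmptyCohortError(ValueError):
    """No patients survive the exclusion criteria."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PatientRecord:
    patient_id: str
    age: float | None
    sex: int | None          # 0/1 encoding; None = missing
    mgmt_label: int | None   # 1 = methylated, 0 = unmethylated; None = missing
    slice_ids: list[str] = field(default_factory=list)


@dataclass
class SliceSample:
    patient_id: str
    slice_id: str
    image_ce_t1: np.ndarray        # 2-D, target_size x target_size
    image_t2: np.ndarray
    radiomics: dict[str, np.ndarray]  # sector name -> feature vector
    demographics: np.ndarray          # [encoded age, sex]
    label: int


@dataclass
class CohortDataset:
    samples: list[SliceSample]
    patients: list[PatientRecord]
    split_tag: str = "unsplit"

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=int)

    @property
    def patient_ids(self) -> np.ndarray:
        return np.array([s.patient_id for s in self.samples])

    def patient_by_id(self, pid: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == pid:
                return p
        raise KeyError(pid)

    def subset_patients(self, keep_ids: Sequence[str], split_tag: str | None = None) -> "CohortDataset":
        keep = set(keep_ids)
        samples = [s for s in self.samples if s.patient_id in keep]
        patients = [p for p in self.patients if p.patient_id in keep]
        return CohortDataset(samples, patients, split_tag or self.split_tag)


@dataclass
class PreprocessConfig:
    min_mask_pixels: int = 256
    target_size: int = 128
    resample_method: str = "lanczos"
    image_count_sd_multiplier: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_mask_pixels < 1:
            raise ValueError("min_mask_pixels must be >= 1")
        if self.target_size < 8:
            raise ValueError("target_size must be >= 8")


# raw inputs, before exclusion -------------------------------------------------

@dataclass
class RawSlice:
    """One axial slice as delivered by segmentation + feature extraction.

    ``radiomics`` maps each of the six sectors to the full candidate feature
    vector; a value of ``None`` (or any non-finite entry) marks a sector whose
    features could not be extracted.
    """
    patient_id: str
    slice_id: str
    image_ce_t1: np.ndarray
    image_t2: np.ndarray
    mask: np.ndarray  # integer compartment labels, 0 = background
    radiomics: dict[str, np.ndarray | None]


# ---------------------------------------------------------------------------
# image-level operations
# ---------------------------------------------------------------------------

_RESAMPLE = {
    "lanczos": Image.Resampling.LANCZOS,
    "bilinear": Image.Resampling.BILINEAR,
    "nearest": Image.Resampling.NEAREST,
    "bicubic": Image.Resampling.BICUBIC,
}


def exclude_small_mask(mask: np.ndarray, min_pixels: int = 256) -> bool:
    """True iff the segmentation covers fewer than ``min_pixels`` pixels."""
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("empty mask grid")
    return int(np.count_nonzero(mask)) < min_pixels


def mask_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Inclusive (row0, row1, col0, col1) bounds of nonzero mask pixels."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise EmptyTumorError("mask contains no tumor pixels")
    return int(rows[0]), int(rows[-1]), int(cols[0]), int(cols[-1])


def crop_to_mask_bbox(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Crop to the minimal axis-aligned rectangle containing the tumor."""
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError(f"image shape {image.shape} != mask shape {mask.shape}")
    r0, r1, c0, c1 = mask_bbox(mask)
    return image[r0:r1 + 1, c0:c1 + 1]


def resize_to_square(image: np.ndarray, target_size: int = 128,
                     method: str = "lanczos") -> np.ndarray:
    """Resample a 2-D grid to target_size x target_size (default Lanczos)."""
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("empty image")
    pil = Image.fromarray(image.astype(np.float32), mode="F")
    out = pil.resize((target_size, target_size), resample=_RESAMPLE[method.lower()])
    arr = np.asarray(out, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite intensities after resize")
    return arr


def preprocess_slice_image(image: np.ndarray, mask: np.ndarray,
                           config: PreprocessConfig) -> np.ndarray:
    """Bounding-box crop around the tumor followed by the square resize."""
    return resize_to_square(crop_to_mask_bbox(image, mask),
                            config.target_size, config.resample_method)


# ---------------------------------------------------------------------------
# patient-level exclusion criteria
# ---------------------------------------------------------------------------

def _slice_radiomics_ok(raw: RawSlice) -> bool:
    for sector in RADIOMIC_SECTORS:
        vec = raw.radiomics.get(sector)
        if vec is None:
            return False
        vec = np.asarray(vec, dtype=float)
        if not np.all(np.isfinite(vec)):
            return False
    return True


def apply_exclusion_criteria(
    raw_patients: Sequence[PatientRecord],
    raw_slices: Sequence[RawSlice],
    config: PreprocessConfig | None = None,
) -> tuple[CohortDataset, dict]:
    """Apply the four patient-level exclusion criteria and preprocess images.

    Criteria (counted in the returned log):
      (i)   missing age or sex;
      (ii)  missing MGMT methylation label;
      (iii) any retained slice with an unextractable radiomic sector;
      (iv)  per-patient image count outside mean +/- k*SD of the per-patient
            counts among patients surviving (i)-(iii).

    Slices whose segmentation covers fewer than ``min_mask_pixels`` pixels are
    dropped before the patient-level criteria; surviving images are cropped to
    the tumor bounding box and resized.  Demographics are attached raw
    (age unscaled) — standardize with :func:`encode_demographics` after the
    train/test split.
    """
    config = config or PreprocessConfig()
    log: dict = {"small_mask_slices": 0,
                 "i_missing_age_sex": 0, "ii_missing_label": 0,
                 "iii_unextractable_radiomics": 0, "iv_image_count_outlier": 0,
                 "excluded_patient_ids": {}}

    slices_by_patient: dict[str, list[RawSlice]] = {}
    for raw in raw_slices:
        if exclude_small_mask(raw.mask, config.min_mask_pixels):
            log["small_mask_slices"] += 1
            continue
        slices_by_patient.setdefault(raw.patient_id, []).append(raw)

    survivors: list[PatientRecord] = []
    for pat in raw_patients:
        if pat.age is None or pat.sex is None or not np.isfinite(pat.age):
            log["i_missing_age_sex"] += 1
            log["excluded_patient_ids"][pat.patient_id] = "i"
            continue
        if pat.mgmt_label is None:
            log["ii_missing_label"] += 1
            log["excluded_patient_ids"][pat.patient_id] = "ii"
            continue
        kept = slices_by_patient.get(pat.patient_id, [])
        if not kept or not all(_slice_radiomics_ok(s) for s in kept):
            log["iii_unextractable_radiomics"] += 1
            log["excluded_patient_ids"][pat.patient_id] = "iii"
            continue
        survivors.append(pat)

    if not survivors:
        raise EmptyCohortError("no patients survive criteria (i)-(iii)")

    counts = np.array([len(slices_by_patient[p.patient_id]) for p in survivors], dtype=float)
    mean, sd = counts.mean(), counts.std(ddof=1) if len(counts) > 1 else 0.0
    k = config.image_count_sd_multiplier
    retained: list[PatientRecord] = []
    for pat, n in zip(survivors, counts):
        if sd > 0 and abs(n - mean) > k * sd:
            log["iv_image_count_outlier"] += 1
            log["excluded_patient_ids"][pat.patient_id] = "iv"
            continue
        retained.append(pat)
    if not retained:
        raise EmptyCohortError("no patients survive criterion (iv)")

    samples: list[SliceSample] = []
    patients: list[PatientRecord] = []
    for pat in retained:
        slice_ids = []
        for raw in slices_by_patient[pat.patient_id]:
            img1 = preprocess_slice_image(raw.image_ce_t1, raw.mask, config)
            img2 = preprocess_slice_image(raw.image_t2, raw.mask, config)
            samples.append(SliceSample(
                patient_id=pat.patient_id,
                slice_id=raw.slice_id,
                image_ce_t1=img1,
                image_t2=img2,
                radiomics={k_: np.asarray(v, dtype=float)
                           for k_, v in raw.radiomics.items()},
                demographics=np.array([pat.age, pat.sex], dtype=float),
                label=int(pat.mgmt_label),
            ))
            slice_ids.append(raw.slice_id)
        patients.append(replace(pat, slice_ids=slice_ids))

    return CohortDataset(samples, patients, "unsplit"), log


def balance_classes(cohort: CohortDataset, seed: int = 0) -> CohortDataset:
    """Equalize image counts per class by subsampling the majority class.

    The minority class is untouched; majority-class images are dropped
    uniformly at random without replacement (seeded, deterministic).
    """
    labels = cohort.labels
    n1, n0 = int((labels == 1).sum()), int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to balance")
    if n1 == n0:
        return CohortDataset(list(cohort.samples), list(cohort.patients), cohort.split_tag)
    majority = 1 if n1 > n0 else 0
    target = min(n1, n0)
    rng = np.random.default_rng(seed)
    maj_idx = np.flatnonzero(labels == majority)
    keep_maj = set(rng.choice(maj_idx, size=target, replace=False).tolist())
    samples = [s for i, s in enumerate(cohort.samples)
               if labels[i] != majority or i in keep_maj]
    kept_pids = {s.patient_id for s in samples}
    kept_slices = {(s.patient_id, s.slice_id) for s in samples}
    patients = []
    for p in cohort.patients:
        if p.patient_id in kept_pids:
            patients.append(replace(
                p, slice_ids=[sid for sid in p.slice_ids
                              if (p.patient_id, sid) in kept_slices]))
    return CohortDataset(samples, patients, cohort.split_tag)


def split_by_patient(cohort: CohortDataset,
                     test_fraction: float | None = None,
                     test_count: int | None = None,
                     seed: int = 0) -> tuple[CohortDataset, CohortDataset]:
    """Patient-level train/test partition (no patient straddles the split)."""
    pids = [p.patient_id for p in cohort.patients]
    if len(pids) < 2:
        raise ValueError("need at least two patients to split")
    if test_count is None:
        if test_fraction is None or not (0.0 < test_fraction < 1.0):
            raise ValueError("test_fraction must lie in (0, 1)")
        test_count = max(1, round(test_fraction * len(pids)))
    if not (0 < test_count < len(pids)):
        raise ValueError("test_count must leave both splits nonempty")
    rng = np.random.default_rng(seed)
    test_ids = set(rng.choice(pids, size=test_count, replace=False).tolist())
    train = cohort.subset_patients([p for p in pids if p not in test_ids], "train")
    test = cohort.subset_patients(sorted(test_ids), "test")
    return train, test


def encode_demographics(train: CohortDataset, *others: CohortDataset,
                        standardize_age: bool = True) -> None:
    """Z-score age in place using training-split statistics; sex stays 0/1."""
    if not standardize_age:
        return
    ages = np.array([p.age for p in train.patients], dtype=float)
    mu = float(ages.mean())
    sd = float(ages.std(ddof=1)) if len(ages) > 1 else 1.0
    sd = sd if sd > 0 else 1.0
    for cohort in (train, *others):
        for s in cohort.samples:
            raw_age = cohort.patient_by_id(s.patient_id).age
            s.demographics = np.array([(raw_age - mu) / sd,
                                       s.demographics[1]], dtype=float)


# ---------------------------------------------------------------------------
# ANOVA feature selection
# ---------------------------------------------------------------------------

def anova_f(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """One-way two-group ANOVA F statistic (between MS / within MS)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least two values")
    grand = np.concatenate([a, b]).mean()
    ssb = len(a) * (a.mean() - grand) ** 2 + len(b) * (b.mean() - grand) ** 2
    ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    df_between, df_within = 1, len(a) + len(b) - 2
    if ssw == 0.0:
        return 0.0 if ssb == 0.0 else np.inf
    return float((ssb / df_between) / (ssw / df_within))


def select_top_features(feature_table: np.ndarray, labels: np.ndarray,
                        k: int, feature_names: Sequence[str] | None = None) -> list[str]:
    """Rank features by two-group ANOVA F and keep the top ``k``.

    Computed on the training split only; the same selection is then applied to
    the test split.  Ties break by stable input order.
    """
    X = np.asarray(feature_table, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("feature_table must be 2-D (samples x features)")
    n_feat = X.shape[1]
    if k > n_feat:
        raise ValueError(f"k={k} exceeds feature count {n_feat}")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(n_feat)]
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    fvals = np.array([anova_f(X[y == classes[0], j], X[y == classes[1], j])
                      for j in range(n_feat)])
    # stable sort on -F keeps input order among ties
    order = np.argsort(-fvals, kind="stable")
    return [feature_names[j] for j in order[:k]]


def select_sector_features(cohort_train: CohortDataset, k: int = 64) -> dict[str, list[int]]:
    """Per-sector ANOVA top-k selection on the training split.

    Returns, for each radiomic sector, the column indices of the selected
    features in decreasing-F order.
    """
    y = cohort_train.labels
    selected: dict[str, list[int]] = {}
    for sector in RADIOMIC_SECTORS:
        X = np.stack([s.radiomics[sector] for s in cohort_train.samples])
        names = [str(i) for i in range(X.shape[1])]
        chosen = select_top_features(X, y, k, names)
        selected[sector] = [int(n) for n in chosen]
    return selected


def apply_feature_selection(cohort: CohortDataset,
                            selected: Mapping[str, Sequence[int]]) -> None:
    """Restrict every sample's radiomic vectors to the selected columns, in place."""
    for s in cohort.samples:
        for sector, idx in selected.items():
            s.radiomics[sector] = np.asarray(s.radiomics[sector], dtype=float)[list(idx)]
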