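"""Synthetic multimodal cohorts with planted per-sector class signal.

Emulates the structure the analysis assumes: patients with a variable number
of axial tumor slices, demographics resembling an adult glioma cohort
(mean age ~62, ~70% male, ~72% methylated), per-slice radiomic candidate
vectors (105 features per modality x compartment, an informative subset
shifted by the sector's effect size), and two MR-like images per slice with a
three-compartment elliptical "tumor" whose intensity shifts with the label.
Everything is driven by one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .cohort import (CohortDataset, PatientRecord, PreprocessConfig, RawSlice,
                     RADIOMIC_SECTORS, SECTOR_ORDER, apply_exclusion_criteria)

#: BraTS-style compartment codes in the segmentation mask
MASK_CODES = {"NCR": 1, "ED": 2, "ET": 4}


def default_sector_effects() -> dict[str, float]:
    """Planted effect sizes (standardized mean shifts), strongest in the
    edema-region radiomics of the T2-weighted image, mirroring the relative
    ordering the method is meant to recover."""
    return {
        "T2WI-ED": 1.2, "T2WI-NCR": 1.0, "T2WI-ET": 0.9,
        "CE-T1WI-ED": 0.6, "CE-T1WI-ET": 0.55, "CE-T1WI-NCR": 0.5,
        "demographics": 0.3, "CE-T1WI": 0.2, "T2WI": 0.2,
    }


@dataclass
class SimConfig:
    n_patients: int = 152
    images_per_patient_mean: float = 12.86
    images_per_patient_sd: float = 6.0
    class_prevalence: float = 0.72          # P(methylated)
    sector_effects: dict[str, float] = field(default_factory=default_sector_effects)
    n_radiomic_features: int = 105
    n_informative: int = 8                  # informative features per radiomic sector
    noise_sd: float = 1.0
    image_size: int = 128
    age_mean: float = 62.0
    age_sd: float = 10.0
    male_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 4:
            raise ValueError("n_patients must be >= 4")
        if not (0.0 < self.class_prevalence < 1.0):
            raise ValueError("class_prevalence must lie in (0, 1)")
        if self.images_per_patient_mean < 1.0:
            raise ValueError("mean images per patient must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for name, d in self.sector_effects.items():
            if name not in SECTOR_ORDER:
                raise ValueError(f"unknown sector {name!r} in sector_effects")
            if not np.isfinite(d):
                raise ValueError(f"effect size for {name} must be finite")


def make_masked_slice(label: int, effect: float, rng: np.random.Generator,
                      size: int = 128, noise_sd: float = 1.0,
                      excludable: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """One synthetic slice: (image, compartment-labelled mask).

    The tumor is three nested ellipses (ED outer, ET ring, NCR core) with a
    guaranteed mask area of at least 256 pixels; ``excludable=True`` instead
    emits a known-excludable slice with exactly 255 mask pixels, for testing
    the small-mask filter.
    """
    if not np.isfinite(effect):
        raise ValueError("effect must be finite")
    image = rng.normal(0.0, noise_sd, size=(size, size))
    mask = np.zeros((size, size), dtype=np.int16)
    if excludable:
        r0, c0 = size // 4, size // 4
        block = np.zeros(256, dtype=np.int16)
        block[:255] = MASK_CODES["ED"]
        mask[r0:r0 + 16, c0:c0 + 16] = block.reshape(16, 16)
        image[mask > 0] += 1.0 + effect * label
        return image, mask

    cy = rng.uniform(0.35, 0.65) * size
    cx = rng.uniform(0.35, 0.65) * size
    a = rng.uniform(0.14, 0.22) * size   # semi-axes; area >= pi*18*14 > 256 at size 128
    b = rng.uniform(0.12, 0.18) * size
    yy, xx = np.mgrid[0:size, 0:size]
    r2 = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2
    mask[r2 <= 1.0] = MASK_CODES["ED"]
    mask[r2 <= 0.55] = MASK_CODES["ET"]
    mask[r2 <= 0.2] = MASK_CODES["NCR"]
    # intensity contrast grows with the label by the image-sector effect;
    # speckle texture makes the blob detectable by patch embeddings
    blob = mask > 0
    image[blob] += 1.5 + effect * label
    image[blob] += rng.normal(0.0, 0.3 * (1.0 + 0.5 * effect * label),
                              size=int(blob.sum()))
    return image, mask


def _truncated_age(rng: np.random.Generator, mean: float, sd: float) -> float:
    for _ in range(100):
        age = rng.normal(mean, sd)
        if age >= 18.0:
            return float(age)
    raise ValueError("age truncation at 18 is effectively impossible "
                     f"for mean={mean}, sd={sd}")


def generate_raw_cohort(config: SimConfig) -> tuple[list[PatientRecord], list[RawSlice], dict]:
    """Raw patients + slices (pre-exclusion layout), and the ground truth."""
    rng = np.random.default_rng(config.seed)
    effects: Mapping[str, float] = config.sector_effects
    informative = {
        sector: np.sort(rng.choice(config.n_radiomic_features,
                                   size=config.n_informative, replace=False))
        for sector in RADIOMIC_SECTORS
    }
    patients: list[PatientRecord] = []
    slices: list[RawSlice] = []
    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        label = int(rng.random() < config.class_prevalence)
        d_demo = effects.get("demographics", 0.0)
        age = _truncated_age(rng, config.age_mean + d_demo * config.age_sd * label,
                             config.age_sd)
        sex = int(rng.random() < config.male_fraction)
        n_img = max(1, int(round(rng.normal(config.images_per_patient_mean,
                                            config.images_per_patient_sd))))
        slice_ids = []
        for k in range(n_img):
            sid = f"{pid}_s{k:03d}"
            img1, mask = make_masked_slice(label, effects.get("CE-T1WI", 0.0), rng,
                                           config.image_size, config.noise_sd)
            img2, _ = make_masked_slice(label, effects.get("T2WI", 0.0), rng,
                                        config.image_size, config.noise_sd)
            radiomics: dict[str, np.ndarray] = {}
            for sector in RADIOMIC_SECTORS:
                vec = rng.normal(0.0, config.noise_sd,
                                 size=config.n_radiomic_features)
                vec[informative[sector]] += effects.get(sector, 0.0) * label
                radiomics[sector] = vec
            slices.append(RawSlice(pid, sid, img1, img2, mask, radiomics))
            slice_ids.append(sid)
        patients.append(PatientRecord(pid, age, sex, label, slice_ids))
    truth = {
        "labels": {p.patient_id: p.mgmt_label for p in patients},
        "informative_features": {k: v.tolist() for k, v in informative.items()},
        "sector_effects": dict(effects),
        "seed": config.seed,
    }
    return patients, slices, truth


def generate_cohort(config: SimConfig,
                    preprocess: PreprocessConfig | None = None
                    ) -> tuple[CohortDataset, dict]:
    """Analysis-ready synthetic cohort (exclusions + crop/resize applied)."""
    patients, slices, truth = generate_raw_cohort(config)
    preprocess = preprocess or PreprocessConfig(seed=config.seed)
    cohort, log = apply_exclusion_criteria(patients, slices, preprocess)
    truth["exclusion_log"] = log
    return cohort, truth
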