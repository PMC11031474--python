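"""On-disk cohort layouts.

Raw layout (what segmentation + feature extraction deliver, and what the
``simulate`` command writes):

    cohort_dir/
      manifest.csv            patient_id, age, sex, mgmt_label
      radiomics.csv           patient_id, slice_id, sector, f0..f{n-1}
      volumes/{pid}_CE-T1WI.nii.gz, {pid}_T2WI.nii.gz, {pid}_seg.nii.gz

Volumes stack a patient's axial slices along the third axis; the segmentation
uses BraTS-style codes (1 = NCR, 2 = ED, 4 = ET).  Missing demographics or
labels are empty cells in the manifest; an unextractable sector is a missing
(or all-NaN) radiomics row.

Processed cohorts (post exclusion/balancing/splitting) are stored as a single
``.npz`` of stacked arrays plus a JSON manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import (CohortDataset, PatientRecord, RawSlice, RADIOMIC_SECTORS,
                     SliceSample)


# ---------------------------------------------------------------------------
# raw layout
# ---------------------------------------------------------------------------

def write_raw_cohort(out_dir: str | Path, patients: list[PatientRecord],
                     slices: list[RawSlice]) -> None:
    out = Path(out_dir)
    (out / "volumes").mkdir(parents=True, exist_ok=True)
    pd.DataFrame([{
        "patient_id": p.patient_id,
        "age": "" if p.age is None else p.age,
        "sex": "" if p.sex is None else p.sex,
        "mgmt_label": "" if p.mgmt_label is None else p.mgmt_label,
    } for p in patients]).to_csv(out / "manifest.csv", index=False)

    rows = []
    by_patient: dict[str, list[RawSlice]] = {}
    for s in slices:
        by_patient.setdefault(s.patient_id, []).append(s)
        for sector in RADIOMIC_SECTORS:
            vec = s.radiomics.get(sector)
            if vec is None:
                continue
            row = {"patient_id": s.patient_id, "slice_id": s.slice_id,
                   "sector": sector}
            row.update({f"f{i}": v for i, v in enumerate(np.asarray(vec, dtype=float))})
            rows.append(row)
    pd.DataFrame(rows).to_csv(out / "radiomics.csv", index=False)

    affine = np.eye(4)
    for pid, plist in by_patient.items():
        ce = np.stack([s.image_ce_t1 for s in plist], axis=2)
        t2 = np.stack([s.image_t2 for s in plist], axis=2)
        seg = np.stack([s.mask for s in plist], axis=2).astype(np.int16)
        nib.save(nib.Nifti1Image(ce.astype(np.float32), affine),
                 out / "volumes" / f"{pid}_CE-T1WI.nii.gz")
        nib.save(nib.Nifti1Image(t2.astype(np.float32), affine),
                 out / "volumes" / f"{pid}_T2WI.nii.gz")
        nib.save(nib.Nifti1Image(seg, affine),
                 out / "volumes" / f"{pid}_seg.nii.gz")
    with open(out / "slice_ids.json", "w") as fh:
        json.dump({pid: [s.slice_id for s in plist]
                   for pid, plist in by_patient.items()}, fh)


def read_raw_cohort(cohort_dir: str | Path) -> tuple[list[PatientRecord], list[RawSlice]]:
    root = Path(cohort_dir)
    manifest = pd.read_csv(root / "manifest.csv")

    def _opt(v, cast):
        return None if pd.isna(v) else cast(v)

    patients = [PatientRecord(str(r.patient_id), _opt(r.age, float),
                              _opt(r.sex, int), _opt(r.mgmt_label, int), [])
                for r in manifest.itertuples()]

    rad = pd.read_csv(root / "radiomics.csv")
    feat_cols = [c for c in rad.columns if c.startswith("f")]
    rad_map: dict[tuple[str, str], np.ndarray] = {}
    for r in rad.itertuples():
        rad_map[(str(r.slice_id), r.sector)] = np.array(
            [getattr(r, c) for c in feat_cols], dtype=float)

    with open(root / "slice_ids.json") as fh:
        slice_ids = json.load(fh)

    slices: list[RawSlice] = []
    for p in patients:
        vol_dir = root / "volumes"
        ce_path = vol_dir / f"{p.patient_id}_CE-T1WI.nii.gz"
        if not ce_path.exists():
            continue
        ce = np.asarray(nib.load(ce_path).dataobj, dtype=float)
        t2 = np.asarray(nib.load(vol_dir / f"{p.patient_id}_T2WI.nii.gz").dataobj,
                        dtype=float)
        seg = np.asarray(nib.load(vol_dir / f"{p.patient_id}_seg.nii.gz").dataobj)
        sids = slice_ids[p.patient_id]
        for k, sid in enumerate(sids):
            radiomics = {sector: rad_map.get((sid, sector))
                         for sector in RADIOMIC_SECTORS}
            slices.append(RawSlice(p.patient_id, sid, ce[:, :, k], t2[:, :, k],
                                   seg[:, :, k], radiomics))
    return patients, slices


# ---------------------------------------------------------------------------
# processed cohorts
# ---------------------------------------------------------------------------

def save_cohort(path: str | Path, cohort: CohortDataset) -> None:
    path = Path(path)
    arrays = {
        "image_ce_t1": np.stack([s.image_ce_t1 for s in cohort.samples]),
        "image_t2": np.stack([s.image_t2 for s in cohort.samples]),
        "demographics": np.stack([s.demographics for s in cohort.samples]),
        "labels": cohort.labels,
    }
    for sector in RADIOMIC_SECTORS:
        arrays[f"rad_{sector}"] = np.stack(
            [s.radiomics[sector] for s in cohort.samples])
    np.savez_compressed(path, **arrays)
    meta = {
        "split_tag": cohort.split_tag,
        "sample_ids": [[s.patient_id, s.slice_id] for s in cohort.samples],
        "patients": [{"patient_id": p.patient_id, "age": p.age, "sex": p.sex,
                      "mgmt_label": p.mgmt_label, "slice_ids": p.slice_ids}
                     for p in cohort.patients],
    }
    with open(str(path).removesuffix(".npz") + ".json", "w") as fh:
        json.dump(meta, fh)


def load_cohort(path: str | Path) -> CohortDataset:
    path = str(path)
    base = path.removesuffix(".npz")
    with open(base + ".json") as fh:
        meta = json.load(fh)
    with np.load(base + ".npz") as z:
        samples = []
        for i, (pid, sid) in enumerate(meta["sample_ids"]):
            samples.append(SliceSample(
                patient_id=pid, slice_id=sid,
                image_ce_t1=z["image_ce_t1"][i], image_t2=z["image_t2"][i],
                radiomics={sector: z[f"rad_{sector}"][i]
                           for sector in RADIOMIC_SECTORS},
                demographics=z["demographics"][i],
                label=int(z["labels"][i])))
    patients = [PatientRecord(**p) for p in meta["patients"]]
    return CohortDataset(samples, patients, meta["split_tag"])
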