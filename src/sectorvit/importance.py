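"""Sector-level permutation importance.

One sector's data is reassigned between patients by a uniformly random
permutation of patient identities (labels and all other sectors stay put),
the fixed trained model re-scores the permuted cohort, and the drop in
accuracy (original minus permuted) is the permutation importance.  The
procedure is repeated (default 100 times) per sector; sectors are then ranked
by mean importance and compared pairwise with the Mann-Whitney U test.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .cohort import (CohortDataset, DEMOGRAPHIC_SECTOR, IMAGE_SECTORS,
                     RADIOMIC_SECTORS, SECTOR_ORDER, SliceSample)
from .metrics import PairedTestResult, aggregate_patient

#: predictor contract: cohort -> (binary calls, probabilities) per sample
PredictFn = Callable[[CohortDataset], tuple[np.ndarray, np.ndarray]]


@dataclass
class ImportanceResult:
    sector: str
    pi_samples: list[float]
    pi_mean: float
    ci_low: float
    ci_high: float
    original_accuracy: float


@dataclass
class SectorRanking:
    sectors: list[str]                      # decreasing pi_mean
    pi_means: dict[str, float]
    p_matrix: "np.ndarray"                  # pairwise Mann-Whitney p, unit diag
    results: dict[str, ImportanceResult] = field(default_factory=dict)


def _copy_sample(s: SliceSample) -> SliceSample:
    return SliceSample(
        patient_id=s.patient_id, slice_id=s.slice_id,
        image_ce_t1=s.image_ce_t1, image_t2=s.image_t2,
        radiomics=dict(s.radiomics), demographics=s.demographics,
        label=s.label)


def permute_sector(cohort: CohortDataset, sector: str,
                   seed: int | np.random.Generator = 0,
                   derangement: bool = False) -> CohortDataset:
    """Reassign one sector's data between patients.

    A uniformly random permutation ``pi`` over patients is drawn (identity
    mappings allowed unless ``derangement``); patient ``p``'s slices receive
    the sector data of patient ``pi(p)``, donor slices being cycled in order
    when the two patients contribute different slice counts.  Labels and all
    other sectors are untouched.
    """
    if sector not in SECTOR_ORDER:
        raise ValueError(f"unknown sector {sector!r}; expected one of {SECTOR_ORDER}")
    if len(cohort.patients) < 2:
        raise ValueError("need at least two patients to permute")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pids = [p.patient_id for p in cohort.patients]
    perm = rng.permutation(len(pids))
    if derangement:
        while np.any(perm == np.arange(len(pids))):
            perm = rng.permutation(len(pids))
    donor_of = {pids[i]: pids[perm[i]] for i in range(len(pids))}

    slices_by_patient: dict[str, list[SliceSample]] = {}
    for s in cohort.samples:
        slices_by_patient.setdefault(s.patient_id, []).append(s)

    new_samples: list[SliceSample] = []
    counters: dict[str, int] = {}
    for s in cohort.samples:
        donor = donor_of[s.patient_id]
        donor_slices = slices_by_patient[donor]
        j = counters.get(s.patient_id, 0)
        counters[s.patient_id] = j + 1
        src = donor_slices[j % len(donor_slices)]
        ns = _copy_sample(s)
        if sector == DEMOGRAPHIC_SECTOR:
            ns.demographics = src.demographics
        elif sector in RADIOMIC_SECTORS:
            ns.radiomics[sector] = src.radiomics[sector]
        elif sector == "CE-T1WI":
            ns.image_ce_t1 = src.image_ce_t1
        elif sector == "T2WI":
            ns.image_t2 = src.image_t2
        new_samples.append(ns)
    return CohortDataset(new_samples, copy.deepcopy(cohort.patients), cohort.split_tag)


def _accuracy(calls: np.ndarray, probs: np.ndarray, labels: np.ndarray,
              patient_ids: np.ndarray, level: str) -> float:
    if level == "patient":
        order, pc, _ = aggregate_patient(calls, probs, list(patient_ids))
        plab = {pid: None for pid in order}
        for pid, lab in zip(patient_ids, labels):
            plab[pid] = lab
        y = np.array([plab[pid] for pid in order])
        return float((pc == y).mean())
    return float((calls == labels).mean())


def permutation_importance(predict_fn: PredictFn, cohort: CohortDataset,
                           sector: str, n_rep: int = 100, base_seed: int = 0,
                           level: str = "image",
                           derangement: bool = False) -> ImportanceResult:
    """Accuracy drop from permuting one sector, repeated ``n_rep`` times.

    The trained model is fixed throughout; repetition ``r`` permutes with seed
    ``base_seed + r``.  ``level`` selects image-based or patient-based
    accuracy.  The CI is the percentile interval over the repetition samples.
    """
    if n_rep < 2:
        raise ValueError("n_rep must be >= 2")
    labels = cohort.labels
    pids = cohort.patient_ids
    calls0, probs0 = predict_fn(cohort)
    acc0 = _accuracy(np.asarray(calls0), np.asarray(probs0), labels, pids, level)
    samples = []
    for r in range(n_rep):
        permuted = permute_sector(cohort, sector, seed=base_seed + r,
                                  derangement=derangement)
        calls, probs = predict_fn(permuted)
        acc = _accuracy(np.asarray(calls), np.asarray(probs), labels, pids, level)
        samples.append(acc0 - acc)
    lo, hi = np.percentile(samples, [2.5, 97.5])
    return ImportanceResult(sector=sector, pi_samples=[float(x) for x in samples],
                            pi_mean=float(np.mean(samples)),
                            ci_low=float(lo), ci_high=float(hi),
                            original_accuracy=acc0)


def compare_sectors(res_a: ImportanceResult | Sequence[float],
                    res_b: ImportanceResult | Sequence[float]) -> PairedTestResult:
    """Two-sided Mann-Whitney U test on two sectors' importance samples.

    Exact enumeration for small tie-free samples (both n < 20), otherwise the
    normal approximation with tie correction.
    """
    a = np.asarray(res_a.pi_samples if isinstance(res_a, ImportanceResult) else res_a,
                   dtype=float)
    b = np.asarray(res_b.pi_samples if isinstance(res_b, ImportanceResult) else res_b,
                   dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 values")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    small = max(len(a), len(b)) < 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return PairedTestResult(float(res.statistic), float(res.pvalue), "mann-whitney")


def rank_sectors(results: Sequence[ImportanceResult]) -> SectorRanking:
    """Descending ranking by mean importance, with the pairwise p matrix."""
    if len(results) < 2:
        raise ValueError("need at least two sectors to rank")
    names = [r.sector for r in results]
    if len(set(names)) != len(names):
        raise ValueError("duplicate sector names")
    by_name = {r.sector: r for r in results}
    # ties in pi_mean break alphabetically
    ordered = sorted(names, key=lambda nm: (-by_name[nm].pi_mean, nm))
    k = len(ordered)
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pij = compare_sectors(by_name[ordered[i]], by_name[ordered[j]]).p_value
            p[i, j] = p[j, i] = pij
    return SectorRanking(sectors=ordered,
                         pi_means={nm: by_name[nm].pi_mean for nm in ordered},
                         p_matrix=p, results=by_name)
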