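"""Patient-level, grade-stratified data partitioning without leakage.

Whole patients (groups) are assigned to train/validation/test partitions or
to cross-validation folds so that no patient's samples ever straddle a
boundary, while per-grade sample fractions track the requested targets.
Also provides SMOTE-style minority oversampling by convex interpolation in
feature space, intended for training partitions only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "SampleRecord",
    "SplitAssignment",
    "stratified_split",
    "stratified_group_kfold",
    "smote_oversample",
    "select_subset",
    "PARTITIONS",
]

PARTITIONS = ("train", "val", "test")


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    patient_id: str
    grade: str
    features: Optional[tuple] = None
    synthetic: bool = False


@dataclass(frozen=True)
class SplitAssignment:
    """Mapping sample_id -> partition name or fold index."""

    assignment: dict
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def samples_in(self, part) -> list:
        return [sid for sid, p in self.assignment.items() if p == part]

    def counts(self) -> dict:
        out: dict = {}
        for p in self.assignment.values():
            out[p] = out.get(p, 0) + 1
        return out


def _check_records(records: Sequence[SampleRecord]) -> None:
    if len(records) == 0:
        raise ValueError("no records to split")
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("sample_id values must be unique")


def _patient_strata(records: Sequence[SampleRecord], rng: np.random.Generator) -> dict:
    """Group records by patient; stratum = patient's modal grade (seeded tie-break)."""
    by_patient: dict = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    strata: dict = {}
    for pid, recs in by_patient.items():
        grades: dict = {}
        for r in recs:
            grades[r.grade] = grades.get(r.grade, 0) + 1
        top = max(grades.values())
        modal = sorted(g for g, c in grades.items() if c == top)
        strata[pid] = modal[0] if len(modal) == 1 else modal[int(rng.integers(len(modal)))]
    return strata


def stratified_split(
    records: Sequence[SampleRecord],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> SplitAssignment:
    """Patient-level stratified train/val/test split.

    Within each grade stratum, whole patients are assigned greedily
    (largest patient first, seeded tie-breaking) to the partition with the
    largest remaining sample deficit relative to the target fractions.
    Realized fractions land within one patient of target per stratum.
    """
    _check_records(records)
    if len(fractions) != len(PARTITIONS):
        raise ValueError("need one fraction per partition")
    if abs(sum(fractions) - 1.0) > 1e-9 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    strata = _patient_strata(records, rng)
    by_patient: dict = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)

    assignment: dict = {}
    warns: list[str] = []
    for stratum in sorted(set(strata.values())):
        pids = sorted(p for p, s in strata.items() if s == stratum)
        if len(pids) == 1:
            warns.append(
                f"stratum {stratum}: single patient {pids[0]}; all its samples in one partition"
            )
        order = rng.permutation(len(pids))
        sizes = np.array([len(by_patient[pids[i]]) for i in order])
        # largest first; the prior shuffle breaks ties among equal sizes
        ranked = [pids[order[i]] for i in np.argsort(-sizes, kind="stable")]
        total = int(sizes.sum())
        targets = np.array(fractions) * total
        assigned = np.zeros(len(PARTITIONS))
        for pid in ranked:
            deficit = targets - assigned
            k = int(np.argmax(deficit))
            for r in by_patient[pid]:
                assignment[r.sample_id] = PARTITIONS[k]
            assigned[k] += len(by_patient[pid])
    return SplitAssignment(assignment=assignment, warnings=tuple(warns))


def stratified_group_kfold(
    records: Sequence[SampleRecord],
    k: int = 5,
    seed: int = 0,
) -> SplitAssignment:
    """Patient-disjoint, grade-balanced k-fold assignment.

    Backed by scikit-learn's StratifiedGroupKFold with the patient id as
    the group key and the grade as the stratification label. The returned
    assignment maps each sample to its held-out fold index (0..k-1); a
    fold's training set is the complement.
    """
    _check_records(records)
    if k < 2:
        raise ValueError("k must be >= 2")
    n_patients = len({r.patient_id for r in records})
    if k > n_patients:
        raise ValueError(f"k={k} exceeds number of patients ({n_patients})")
    y = np.array([r.grade for r in records])
    groups = np.array([r.patient_id for r in records])
    sgkf = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment: dict = {}
    for fold, (_, val_idx) in enumerate(sgkf.split(np.zeros(len(y)), y, groups)):
        for i in val_idx:
            assignment[records[i].sample_id] = fold
    return SplitAssignment(assignment=assignment)


def select_subset(
    records: Sequence[SampleRecord],
    fraction: float,
    of_n: Optional[int] = None,
    seed: int = 0,
) -> list[SampleRecord]:
    """Seeded sample of round(fraction * of_n) records (without replacement).

    ``of_n`` defaults to the number of records, but can name a different
    reference denominator (e.g. a fraction of the full dataset drawn from a
    challenge pool).
    """
    _check_records(records)
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = int(round(fraction * (of_n if of_n is not None else len(records))))
    if n > len(records):
        raise ValueError(f"subset of {n} exceeds available {len(records)} records")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(records), size=n, replace=False)
    return [records[i] for i in sorted(idx)]


def smote_oversample(
    records: Sequence[SampleRecord],
    target_counts: dict,
    k_neighbors: int = 5,
    seed: int = 0,
) -> list[SampleRecord]:
    """SMOTE-style minority oversampling by convex feature interpolation.

    For each class below its target count, synthetic samples are created
    on the segment between a random class member and one of its k nearest
    same-class neighbors (Euclidean distance on z-scored features;
    interpolation in the original feature space). Classes with a single
    sample are duplicated with a warning. Synthetic records are flagged
    and inherit the parent's patient id. Apply to training data only.
    """
    _check_records(records)
    feats = [r.features for r in records]
    if any(f is None for f in feats):
        raise ValueError("all records need feature vectors for oversampling")
    x_all = np.asarray(feats, dtype=float)
    mu = x_all.mean(axis=0)
    sigma = x_all.std(axis=0)
    sigma[sigma == 0] = 1.0

    rng = np.random.default_rng(seed)
    out = list(records)
    by_class: dict = {}
    for i, r in enumerate(records):
        by_class.setdefault(r.grade, []).append(i)

    for grade in sorted(target_counts):
        idx = by_class.get(grade, [])
        need = target_counts[grade] - len(idx)
        if need <= 0 or not idx:
            continue
        xs = x_all[idx]
        if len(idx) == 1:
            warnings.warn(f"class {grade} has one sample; duplicating it")
            parent = records[idx[0]]
            for j in range(need):
                out.append(
                    SampleRecord(
                        sample_id=f"{parent.sample_id}_syn{j}",
                        patient_id=parent.patient_id,
                        grade=grade,
                        features=parent.features,
                        synthetic=True,
                    )
                )
            continue
        nn = NearestNeighbors(n_neighbors=min(k_neighbors, len(idx) - 1) + 1)
        nn.fit((xs - mu) / sigma)
        _, neigh = nn.kneighbors((xs - mu) / sigma)
        for j in range(need):
            i_local = int(rng.integers(len(idx)))
            # skip self at position 0
            j_local = int(neigh[i_local][1 + rng.integers(neigh.shape[1] - 1)])
            u = rng.uniform()
            new = xs[i_local] + u * (xs[j_local] - xs[i_local])
            parent = records[idx[i_local]]
            out.append(
                SampleRecord(
                    sample_id=f"{parent.sample_id}_syn{j}",
                    patient_id=parent.patient_id,
                    grade=grade,
                    features=tuple(new.tolist()),
                    synthetic=True,
                )
            )
    return out
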