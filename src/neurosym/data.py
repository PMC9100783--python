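"""Cohort data structures and long-table readers/writers.

A cohort couples, per subject, a complete 68 x 3 x 5 feature tensor of
baseline-corrected spectral source amplitudes (ROI x frequency band x
cognitive task; values may be negative) with four integer symptom
self-report scores (anxiety, depression, inattention, hyperactivity) and
their binarized labels.  The flattening order of a tensor is fixed:
ROI-major, then band (theta, alpha, beta), then task (1..5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import AtlasMap, default_atlas

__all__ = [
    "BANDS",
    "TASKS",
    "TASK_NAMES",
    "SYMPTOMS",
    "FeatureTensor",
    "SymptomScores",
    "SymptomLabels",
    "CohortDataset",
    "binarize_labels",
    "read_cohort",
    "write_cohort",
]

BANDS: tuple[str, ...] = ("theta", "alpha", "beta")
TASKS: tuple[int, ...] = (1, 2, 3, 4, 5)
#: Task codes 1..5 in the order the study administers/plots them.
TASK_NAMES: dict[int, str] = {
    1: "Go Green I",
    2: "Go Green II",
    3: "Lost Star",
    4: "Middle Fish",
    5: "Face Off",
}
SYMPTOMS: tuple[str, ...] = ("anxiety", "depression", "inattention", "hyperactivity")

#: Score ceilings of the self-report instruments (GAD-7, PHQ-9, ADHD-RS halves).
SCORE_CEILINGS: dict[str, int] = {
    "anxiety": 21,
    "depression": 27,
    "inattention": 27,
    "hyperactivity": 27,
}

_BAND_ALIASES = {
    "theta": "theta", "alpha": "alpha", "beta": "beta",
    "θ": "theta", "α": "alpha", "β": "beta",
}


def canonical_band(token: str) -> str:
    """Normalize a band token (case-insensitive; Greek letters accepted)."""
    key = str(token).strip().lower()
    if key not in _BAND_ALIASES:
        raise ValueError(f"unknown band token {token!r}; expected one of {BANDS}")
    return _BAND_ALIASES[key]


@dataclass(frozen=True)
class FeatureTensor:
    """One subject's (n_roi, n_band, n_task) feature array."""

    subject_id: str
    values: np.ndarray  # shape (R, B, T), float

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError("tensor must be 3-dimensional (roi, band, task)")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite values in tensor for {self.subject_id}")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def flatten(self) -> np.ndarray:
        """ROI-major, then band, then task (C order)."""
        return self.values.reshape(-1)


@dataclass(frozen=True)
class SymptomScores:
    subject_id: str
    anxiety: int
    depression: int
    inattention: int
    hyperactivity: int

    def __post_init__(self):
        for s in SYMPTOMS:
            v = getattr(self, s)
            if int(v) != v or v < 0:
                raise ValueError(
                    f"{s} score must be a non-negative integer, got {v!r} "
                    f"for {self.subject_id}"
                )
            object.__setattr__(self, s, int(v))

    def as_dict(self) -> dict[str, int]:
        return {s: getattr(self, s) for s in SYMPTOMS}


@dataclass(frozen=True)
class SymptomLabels:
    subject_id: str
    anxiety: int
    depression: int
    inattention: int
    hyperactivity: int

    def __post_init__(self):
        for s in SYMPTOMS:
            if getattr(self, s) not in (0, 1):
                raise ValueError(f"label for {s} must be 0 or 1")

    def as_dict(self) -> dict[str, int]:
        return {s: getattr(self, s) for s in SYMPTOMS}


def binarize_labels(scores: SymptomScores, threshold: int = 5) -> SymptomLabels:
    """Label = 1 iff score >= threshold, independently per symptom.

    The evaluation sections of the source analysis define a positive case as
    a self-report score of no less than 5; that operational rule is the
    default here.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return SymptomLabels(
        scores.subject_id,
        **{s: int(getattr(scores, s) >= threshold) for s in SYMPTOMS},
    )


@dataclass
class CohortDataset:
    """Subjects' tensors plus scores/labels; the pipeline's root input."""

    tensors: list[FeatureTensor]
    scores: list[SymptomScores]
    labels: list[SymptomLabels]
    atlas: AtlasMap = field(default_factory=default_atlas)
    bands: tuple[str, ...] = BANDS
    tasks: tuple[int, ...] = TASKS

    def __post_init__(self):
        ids = [t.subject_id for t in self.tensors]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject_ids in cohort")
        if ids != [s.subject_id for s in self.scores] or ids != [
            l.subject_id for l in self.labels
        ]:
            raise ValueError("tensors, scores and labels must align by subject_id")
        shapes = {t.shape for t in self.tensors}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent tensor shapes: {shapes}")

    @property
    def n_subjects(self) -> int:
        return len(self.tensors)

    @property
    def subject_ids(self) -> list[str]:
        return [t.subject_id for t in self.tensors]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensors[0].shape

    def tensor_array(self) -> np.ndarray:
        """Stacked (n_subjects, R, B, T) array."""
        return np.stack([t.values for t in self.tensors])

    def feature_matrix(self) -> np.ndarray:
        """(n_subjects, R*B*T) identity-feature matrix, ROI-major order."""
        return np.stack([t.flatten() for t in self.tensors])

    def label_vector(self, symptom: str) -> np.ndarray:
        if symptom not in SYMPTOMS:
            raise ValueError(f"unknown symptom {symptom!r}; expected one of {SYMPTOMS}")
        return np.array([getattr(l, symptom) for l in self.labels], dtype=int)

    def score_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"subject_id": s.subject_id, **s.as_dict()} for s in self.scores]
        )

    def with_labels(self, symptom: str, labels: np.ndarray) -> "CohortDataset":
        """Copy of the cohort with one symptom's labels replaced (used by the
        permutation null)."""
        labels = np.asarray(labels, dtype=int)
        new = []
        for lab, v in zip(self.labels, labels):
            d = lab.as_dict()
            d[symptom] = int(v)
            new.append(SymptomLabels(lab.subject_id, **d))
        return CohortDataset(
            self.tensors, self.scores, new, self.atlas, self.bands, self.tasks
        )


def _read_table(path: str | Path) -> pd.DataFrame:
    # header required; comma or tab delimited, sniffed from the header line
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    return pd.read_csv(path, sep=sep)


def read_cohort(
    features_path: str | Path,
    scores_path: str | Path,
    *,
    threshold: int = 5,
    atlas: AtlasMap | None = None,
    n_roi: int | None = None,
) -> CohortDataset:
    """Read a cohort from a long features table and a scores table.

    The features table must have columns ``subject_id, roi_id, band, task,
    value`` with one row per (subject, roi, band, task) cell; the scores
    table has ``subject_id`` plus the four symptom columns.  Every subject
    must have a complete tensor; gaps, duplicates and unknown band/task
    tokens are errors.
    """
    feats = _read_table(features_path)
    required = {"subject_id", "roi_id", "band", "task", "value"}
    missing_cols = required - set(feats.columns)
    if missing_cols:
        raise ValueError(f"features table missing columns: {sorted(missing_cols)}")

    feats = feats.copy()
    feats["subject_id"] = feats["subject_id"].astype(str)
    feats["band"] = feats["band"].map(canonical_band)
    feats["roi_id"] = feats["roi_id"].astype(int)
    feats["task"] = feats["task"].astype(int)

    rois = np.sort(feats["roi_id"].unique())
    R = n_roi if n_roi is not None else int(rois.max())
    if rois.min() < 1 or rois.max() > R:
        raise ValueError(f"roi_id values must lie in 1..{R}")
    bad_task = set(feats["task"].unique()) - set(TASKS)
    if bad_task:
        raise ValueError(f"unknown task codes {sorted(bad_task)}; expected 1..5")
    tasks_present = tuple(sorted(feats["task"].unique()))
    bands_present = tuple(b for b in BANDS if b in set(feats["band"]))

    dup = feats.duplicated(["subject_id", "roi_id", "band", "task"])
    if dup.any():
        row = feats[dup].iloc[0]
        raise ValueError(
            "duplicate feature cell for subject "
            f"{row.subject_id!r} (roi={row.roi_id}, band={row.band}, task={row.task})"
        )

    band_idx = {b: i for i, b in enumerate(bands_present)}
    task_idx = {t: i for i, t in enumerate(tasks_present)}
    B, T = len(bands_present), len(tasks_present)

    scores_df = _read_table(scores_path)
    need = {"subject_id", *SYMPTOMS}
    if need - set(scores_df.columns):
        raise ValueError(
            f"scores table missing columns: {sorted(need - set(scores_df.columns))}"
        )
    scores_df = scores_df.copy()
    scores_df["subject_id"] = scores_df["subject_id"].astype(str)
    if scores_df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id in scores table")
    score_map = {
        r.subject_id: SymptomScores(
            r.subject_id,
            **{s: getattr(r, s) for s in SYMPTOMS},
        )
        for r in scores_df.itertuples()
    }

    tensors, scores, labels = [], [], []
    for sid, grp in sorted(feats.groupby("subject_id"), key=lambda kv: kv[0]):
        arr = np.full((R, B, T), np.nan)
        arr[
            grp["roi_id"].to_numpy() - 1,
            grp["band"].map(band_idx).to_numpy(),
            grp["task"].map(task_idx).to_numpy(),
        ] = grp["value"].to_numpy()
        if np.isnan(arr).any():
            gaps = [
                f"(roi={r + 1}, band={bands_present[b]}, task={tasks_present[t]})"
                for r, b, t in zip(*np.nonzero(np.isnan(arr)))
            ]
            shown = ", ".join(gaps[:5]) + (" ..." if len(gaps) > 5 else "")
            raise ValueError(
                f"subject {sid!r} missing {len(gaps)} feature cell(s): {shown}"
            )
        if sid not in score_map:
            raise ValueError(f"subject {sid!r} has features but no scores row")
        tensors.append(FeatureTensor(sid, arr))
        scores.append(score_map[sid])
        labels.append(binarize_labels(score_map[sid], threshold))

    if not tensors:
        raise ValueError("features table contains no subjects")
    return CohortDataset(
        tensors,
        scores,
        labels,
        atlas if atlas is not None else default_atlas(),
        bands=bands_present,
        tasks=tasks_present,
    )


def write_cohort(
    dataset: CohortDataset,
    features_path: str | Path,
    scores_path: str | Path,
    *,
    sep: str = "\t",
) -> None:
    """Write the long features table and the scores table read by
    :func:`read_cohort` (row order: subject, roi, band, task)."""
    rows = []
    for t in dataset.tensors:
        R, B, T = t.shape
        for r in range(R):
            for b in range(B):
                for k in range(T):
                    rows.append(
                        (
                            t.subject_id,
                            r + 1,
                            dataset.bands[b],
                            dataset.tasks[k],
                            t.values[r, b, k],
                        )
                    )
    pd.DataFrame(
        rows, columns=["subject_id", "roi_id", "band", "task", "value"]
    ).to_csv(features_path, sep=sep, index=False, float_format="%.10g")
    dataset.score_frame().to_csv(scores_path, sep=sep, index=False)
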