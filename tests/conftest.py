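"""Shared fixtures: small synthetic cohorts and hand-built datasets."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from neurosym.data import (
    BANDS,
    SYMPTOMS,
    CohortDataset,
    FeatureTensor,
    SymptomScores,
    binarize_labels,
)
from neurosym.simulate import PlantedEffect, SyntheticConfig, generate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def make_cohort(
    values: np.ndarray,
    scores: np.ndarray | None = None,
    bands: tuple[str, ...] = BANDS,
    tasks: tuple[int, ...] | None = None,
    threshold: int = 5,
) -> CohortDataset:
    """Build a cohort directly from an (n, R, B, T) array; ``scores`` is
    (n, 4) integer or None (alternating 0/9 labels)."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if scores is None:
        scores = np.tile([[0, 0, 0, 0], [9, 9, 9, 9]], (n // 2 + 1, 1))[:n]
    tasks = tasks or tuple(range(1, values.shape[3] + 1))
    tensors, score_objs, labels = [], [], []
    for i in range(n):
        sid = f"S{i + 1:03d}"
        tensors.append(FeatureTensor(sid, values[i]))
        sc = SymptomScores(sid, **dict(zip(SYMPTOMS, map(int, scores[i]))))
        score_objs.append(sc)
        labels.append(binarize_labels(sc, threshold))
    return CohortDataset(
        tensors, score_objs, labels, bands=bands[: values.shape[2]], tasks=tasks
    )


@pytest.fixture(scope="session")
def toy_cohort() -> CohortDataset:
    """30 subjects, 4 ROIs x 3 bands x 2 tasks, one planted cross-ROI
    interaction on the anxiety label."""
    cfg = SyntheticConfig(
        n_subjects=30,
        n_roi=4,
        n_tasks=2,
        seed=7,
        effects=(
            PlantedEffect(
                "anxiety",
                "interaction",
                ((1, "alpha", 1), (3, "beta", 2)),
                3.0,
            ),
        ),
    )
    dataset, _ = generate_cohort(cfg)
    return dataset


@pytest.fixture(scope="session")
def tiny_cohort() -> CohortDataset:
    """12 subjects, 2 ROIs x 2 bands x 2 tasks of reproducible noise."""
    rng = np.random.default_rng(3)
    return make_cohort(rng.standard_normal((12, 2, 2, 2)))
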