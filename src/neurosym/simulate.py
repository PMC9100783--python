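"""Synthetic cohort generator with planted ground truth.

The generator emulates the statistical shape of the study cohort the
pipeline was designed for — 97 subjects, a 68 x 3 x 5 tensor of zero-mean
(possibly negative) baseline-corrected spectral amplitudes per subject, and
four correlated integer symptom scores binarized at a threshold of 5 —
while planting configurable signal so parameter-recovery tests have a known
answer.

Signal model: each symptom has a latent score

    latent = sum_main beta * z(cell) + sum_inter beta * z(cell1) * z(cell2)
             + logistic noise,

where ``z`` is the standardized tensor cell.  Latent scores are mapped to
integer self-report scores by rank-based binning calibrated so the
"score >= 5" rule yields the target prevalence — prevalence control without
distributional assumptions.  With all betas zero the labels are independent
of the features (the permutation-null world).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .data import (
    BANDS,
    SCORE_CEILINGS,
    SYMPTOMS,
    CohortDataset,
    FeatureTensor,
    SymptomScores,
    binarize_labels,
)

__all__ = [
    "PlantedEffect",
    "SyntheticConfig",
    "GroundTruthManifest",
    "generate_cohort",
    "generate_null_cohort",
]


@dataclass(frozen=True)
class PlantedEffect:
    """One planted association between tensor cells and a symptom.

    ``loci`` holds one (roi, band, task) cell for a main effect and two
    cells with distinct ROIs for an interaction (cross-ROI product) effect;
    ``beta`` is in log-odds-like latent units.
    """

    symptom: str
    kind: str  # "main" | "interaction"
    loci: tuple[tuple[int, str, int], ...]
    beta: float

    def __post_init__(self):
        if self.symptom not in SYMPTOMS:
            raise ValueError(f"unknown symptom {self.symptom!r}")
        if self.kind not in ("main", "interaction"):
            raise ValueError("kind must be 'main' or 'interaction'")
        want = 1 if self.kind == "main" else 2
        if len(self.loci) != want:
            raise ValueError(f"{self.kind} effect needs {want} locus/loci")
        if self.kind == "interaction" and self.loci[0][0] == self.loci[1][0]:
            raise ValueError("interaction loci must have distinct ROIs")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters of the generator.

    Defaults mirror the emulated cohort: 97 subjects, 68 ROIs x 3 bands x
    5 tasks, unit-variance zero-mean amplitudes with mild within-ROI
    correlation, labeling threshold 5.  Per-symptom prevalence is
    configurable (the emulated study reports none); 0.4 is the default.
    """

    n_subjects: int = 97
    n_roi: int = 68
    bands: tuple[str, ...] = BANDS
    n_tasks: int = 5
    noise_sd: float = 1.0
    roi_corr: float = 0.8
    latent_noise: float = 0.25  # scale of the logistic noise on the latent score
    effects: tuple[PlantedEffect, ...] = ()
    prevalence: dict[str, float] | float = 0.4
    ceilings: dict[str, int] = field(default_factory=lambda: dict(SCORE_CEILINGS))
    label_threshold: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.roi_corr < 1:
            raise ValueError("roi_corr must be in [0, 1)")
        if self.latent_noise < 0:
            raise ValueError("latent_noise must be >= 0")
        for s in SYMPTOMS:
            p = self.prevalence_for(s)
            if not 0 < p < 1:
                raise ValueError(f"prevalence for {s} must be in (0, 1), got {p}")
            if self.ceilings[s] < self.label_threshold:
                raise ValueError(f"score ceiling for {s} below labeling threshold")
        for e in self.effects:
            for roi, band, task in e.loci:
                if not 1 <= roi <= self.n_roi:
                    raise ValueError(f"effect roi {roi} outside 1..{self.n_roi}")
                if band not in self.bands:
                    raise ValueError(f"effect band {band!r} not in {self.bands}")
                if not 1 <= task <= self.n_tasks:
                    raise ValueError(f"effect task {task} outside 1..{self.n_tasks}")

    def prevalence_for(self, symptom: str) -> float:
        if isinstance(self.prevalence, dict):
            return self.prevalence[symptom]
        return float(self.prevalence)


@dataclass
class GroundTruthManifest:
    """What was planted, and what was realized."""

    seed: int
    effects: tuple[PlantedEffect, ...]
    realized_prevalence: dict[str, float]
    n_subjects: int
    shape: tuple[int, int, int]

    def to_text(self) -> str:
        lines = [
            f"seed = {self.seed}",
            f"n_subjects = {self.n_subjects}",
            f"shape = {self.shape[0]}x{self.shape[1]}x{self.shape[2]}",
        ]
        for s in SYMPTOMS:
            lines.append(f"prevalence.{s} = {self.realized_prevalence[s]:.6f}")
        for e in self.effects:
            loci = ";".join(f"{r}:{b}:{t}" for r, b, t in e.loci)
            lines.append(f"effect = {e.symptom} {e.kind} {loci} beta={e.beta}")
        return "\n".join(lines) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text(), encoding="utf-8")


def _scores_from_latent(
    latent: np.ndarray, prevalence: float, ceiling: int, threshold: int
) -> np.ndarray:
    """Monotone rank-based binning of latent scores to integers 0..ceiling
    such that the fraction with score >= threshold equals the (rounded)
    target prevalence."""
    n = latent.size
    if np.std(latent) == 0:
        raise ValueError(
            "latent score has zero variance; prevalence target unsatisfiable"
        )
    n_pos = int(round(n * prevalence))
    if n_pos == 0 or n_pos == n:
        raise ValueError(
            f"prevalence {prevalence} unreachable with n={n} subjects"
        )
    order = np.argsort(latent, kind="stable")  # ascending
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    n_neg = n - n_pos
    scores = np.empty(n, dtype=int)
    neg = ranks < n_neg
    # negatives spread over 0..threshold-1, positives over threshold..ceiling
    scores[neg] = (ranks[neg] * threshold) // n_neg
    pos_rank = ranks[~neg] - n_neg
    scores[~neg] = threshold + (pos_rank * (ceiling - threshold + 1)) // n_pos
    return scores


def _cell_index(
    loc: tuple[int, str, int], bands: tuple[str, ...]
) -> tuple[int, int, int]:
    roi, band, task = loc
    return roi - 1, bands.index(band), task - 1


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[CohortDataset, GroundTruthManifest]:
    """Draw a cohort under ``config``; byte-identical for equal seeds."""
    rng = np.random.default_rng(config.seed)
    n, R, B, T = (
        config.n_subjects,
        config.n_roi,
        len(config.bands),
        config.n_tasks,
    )
    rho = config.roi_corr
    eps = rng.standard_normal((n, R, B, T))
    shared = rng.standard_normal((n, R, 1, 1))  # within-ROI common factor
    z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps  # unit variance
    tensor = config.noise_sd * z

    scores = np.empty((n, len(SYMPTOMS)), dtype=int)
    for si, symptom in enumerate(SYMPTOMS):
        latent = np.zeros(n)
        for e in config.effects:
            if e.symptom != symptom:
                continue
            if e.kind == "main":
                r, b, t = _cell_index(e.loci[0], config.bands)
                latent += e.beta * z[:, r, b, t]
            else:
                (r1, b1, t1), (r2, b2, t2) = (
                    _cell_index(l, config.bands) for l in e.loci
                )
                latent += e.beta * z[:, r1, b1, t1] * z[:, r2, b2, t2]
        if config.latent_noise > 0:
            latent = latent + rng.logistic(scale=config.latent_noise, size=n)
        scores[:, si] = _scores_from_latent(
            latent,
            config.prevalence_for(symptom),
            config.ceilings[symptom],
            config.label_threshold,
        )

    tensors, score_objs, labels = [], [], []
    width = len(str(n))
    for i in range(n):
        sid = f"S{i + 1:0{width}d}"
        tensors.append(FeatureTensor(sid, tensor[i]))
        sc = SymptomScores(sid, *(int(v) for v in scores[i]))
        score_objs.append(sc)
        labels.append(binarize_labels(sc, config.label_threshold))
    dataset = CohortDataset(
        tensors,
        score_objs,
        labels,
        bands=config.bands,
        tasks=tuple(range(1, T + 1)),
    )
    realized = {
        s: float(dataset.label_vector(s).mean()) for s in SYMPTOMS
    }
    manifest = GroundTruthManifest(
        config.seed, config.effects, realized, n, (R, B, T)
    )
    return dataset, manifest


def generate_null_cohort(config: SyntheticConfig) -> CohortDataset:
    """A cohort with every planted effect removed: labels are independent
    of the features by construction."""
    dataset, _ = generate_cohort(replace(config, effects=()))
    return dataset
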