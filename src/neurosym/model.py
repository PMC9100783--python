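"""Model/Results front-end.

Two model classes organize the analysis the way statistical modelling
packages do: construct a model from data, call ``fit()``, inspect a
Results object.

* :class:`SymptomClassifier` — predicts one symptom's binary label from
  the neural feature tensor under a chosen pipeline variant
  (``original``, ``os`` or ``da_fs_os``); ``fit()`` runs the repeated
  stratified cross-validation and a final whole-cohort fit.
* :class:`HubAnalysis` — aggregates chi-squared strength over ROI pairs,
  builds the thresholded hub graph and computes current-flow centralities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .augment import FeatureDescriptor, pair_unrank, stage1_features
from .classify import LogisticModel, fit_logistic_l2
from .config import PipelineParams, canonical_variant
from .data import CohortDataset, read_cohort
from .evaluate import (
    CVResult,
    PermutationNull,
    evaluate_cv,
    permutation_null,
)
from .hubs import (
    CentralityScores,
    StrengthMatrix,
    build_graph,
    centrality_table,
    current_flow_centralities,
)
from .resample import GaussianAugmentConfig, oversample
from .scoring import materialize_positions, scan_universe
from .augment import descriptor_meta

__all__ = [
    "SymptomClassifier",
    "SymptomClassifierResults",
    "HubAnalysis",
    "HubAnalysisResults",
]


def _position_descriptor(
    pos: int, descriptors: list[FeatureDescriptor]
) -> FeatureDescriptor:
    """Decode a universe stream position into a feature descriptor."""
    m = len(descriptors)
    base, is_log = divmod(int(pos), 2)  # positions are 2*base + log
    if base < m:
        d = descriptors[base]
    else:
        i, j = pair_unrank(np.int64(base - m), m)
        d = FeatureDescriptor(
            "product", product=(descriptors[int(i)], descriptors[int(j)])
        )
    return d.with_log() if is_log else d


class SymptomClassifier:
    """L2 logistic classification of one symptom from the feature tensor.

    Parameters
    ----------
    dataset
        The cohort (tensors + scores/labels).
    symptom
        One of anxiety, depression, inattention, hyperactivity.
    variant
        ``original`` (raw features), ``os`` (raw + oversampling) or
        ``da_fs_os`` (augmentation + chi-squared selection + oversampling).
    params
        :class:`~neurosym.config.PipelineParams`; defaults are the
        reference analysis settings (k = 40,000, lambda = 1, 5 x 5 CV).
    """

    def __init__(
        self,
        dataset: CohortDataset,
        symptom: str,
        variant: str = "da_fs_os",
        params: PipelineParams | None = None,
    ):
        self.dataset = dataset
        self.symptom = symptom
        self.variant = canonical_variant(variant)
        self.params = params or PipelineParams()
        self._stage1 = None

    @classmethod
    def from_tables(
        cls,
        features_path: str | Path,
        scores_path: str | Path,
        symptom: str,
        variant: str = "da_fs_os",
        params: PipelineParams | None = None,
    ) -> "SymptomClassifier":
        params = params or PipelineParams()
        dataset = read_cohort(
            features_path, scores_path, threshold=params.label_threshold
        )
        return cls(dataset, symptom, variant, params)

    def _stage1_values(self) -> np.ndarray:
        if self._stage1 is None:
            self._stage1 = stage1_features(self.dataset)
        return self._stage1.values

    def fit(self, seed: int = 0) -> "SymptomClassifierResults":
        """Run the cross-validated evaluation plus a final whole-cohort
        fit (selection on the full cohort for the augmented variant)."""
        p = self.params
        stage1 = (
            self._stage1_values() if self.variant == "da_fs_os" else None
        )
        cv = evaluate_cv(
            self.dataset,
            self.symptom,
            self.variant,
            folds=p.folds,
            repeats=p.repeats,
            seed=seed,
            params=p,
            stage1=stage1,
        )
        y = self.dataset.label_vector(self.symptom)
        selection_frame = None
        if self.variant == "da_fs_os":
            m = stage1.shape[1]
            k = min(p.k, 2 * (m + m * (m - 1) // 2))
            (chi, pos), = scan_universe(
                stage1, y, k=k, block_size=p.block_size, nonneg=p.nonneg
            )
            X = materialize_positions(stage1, pos, nonneg=p.nonneg)
            descs = self._stage1.descriptors
            selection_frame = pd.DataFrame(
                {
                    "rank": np.arange(1, len(pos) + 1),
                    "chi2": chi,
                    "feature": [
                        _position_descriptor(q, descs).encode() for q in pos
                    ],
                }
            )
        else:
            X = self.dataset.feature_matrix()

        Xf, yf = X, y
        if self.variant in ("os", "da_fs_os"):
            Xf, yf = oversample(
                X,
                y,
                smote_k=p.smote_k,
                gaussian=GaussianAugmentConfig(
                    p.gaussian_factor, p.gaussian_scale
                ),
                order=p.oversample_order,
                seed=np.random.default_rng(abs(int(seed))),
            )
        mu = Xf.mean(axis=0)
        sd = np.where(Xf.std(axis=0) == 0, 1.0, Xf.std(axis=0))
        final = fit_logistic_l2(
            (Xf - mu) / sd, yf, lam=p.lam, fit_intercept=p.fit_intercept
        )
        return SymptomClassifierResults(self, cv, final, selection_frame, seed)

    def permutation_null(
        self, n_perm: int | None = None, seed: int = 0
    ) -> PermutationNull:
        p = self.params
        return permutation_null(
            self.dataset,
            self.symptom,
            self.variant,
            n_perm=n_perm or p.null_permutations,
            folds=p.folds,
            repeats=p.null_repeats,
            seed=seed,
            params=p,
        )


@dataclass
class SymptomClassifierResults:
    """CV metrics, the final fitted coefficients and (for the augmented
    variant) the selected-feature table."""

    model: SymptomClassifier
    cv: CVResult
    final_model: LogisticModel
    selection: pd.DataFrame | None
    seed: int

    @property
    def accuracy(self) -> float:
        return float(self.cv.accuracies.mean())

    @property
    def sensitivity(self) -> float:
        return float(self.cv.sensitivities.mean())

    @property
    def specificity(self) -> float:
        return float(self.cv.specificities.mean())

    def summary(self) -> str:
        cv = self.cv
        lines = [
            "Symptom classification results",
            "==============================",
            f"symptom:           {self.model.symptom}",
            f"variant:           {self.model.variant}",
            f"subjects:          {self.model.dataset.n_subjects}",
            f"positive labels:   "
            f"{int(self.model.dataset.label_vector(self.model.symptom).sum())}",
            f"CV scheme:         {len(cv.counts)} x {len(cv.counts[0])} "
            f"stratified folds ({cv.n_evaluations} evaluations), seed {self.seed}",
            f"lambda (L2):       {self.model.params.lam}",
        ]
        if self.selection is not None:
            lines.append(f"selected features: {len(self.selection)}")
        lines.append("")
        lines.append(
            cv.summary_frame()
            .assign(
                mean=lambda d: d["mean"].round(4), sd=lambda d: d["sd"].round(4)
            )
            .to_string(index=False)
        )
        if self.selection is not None:
            lines += [
                "",
                "Top selected features (chi-squared):",
                self.selection.head(10).to_string(index=False),
            ]
        return "\n".join(lines)


class HubAnalysis:
    """Chi-squared strength aggregation over ROI pairs for one symptom.

    ``fit()`` scores the full augmented universe against the symptom's
    labels (whole cohort — strength is a descriptive aggregate, not a
    predictive model), accumulates pair strengths and dominance
    sub-accumulators in one pass, thresholds the graph and computes
    current-flow centralities.
    """

    def __init__(
        self,
        dataset: CohortDataset,
        symptom: str,
        params: PipelineParams | None = None,
    ):
        self.dataset = dataset
        self.symptom = symptom
        self.params = params or PipelineParams()

    def fit(self) -> "HubAnalysisResults":
        p = self.params
        block = stage1_features(self.dataset)
        meta = descriptor_meta(
            block.descriptors, self.dataset.bands, self.dataset.tasks
        )
        n_roi = self.dataset.shape[0]
        strength = StrengthMatrix(
            n_roi,
            self.dataset.bands,
            self.dataset.tasks,
            symptom=self.symptom,
            stage1_meta=meta,
        )
        y = self.dataset.label_vector(self.symptom)
        scan_universe(
            block.values,
            y,
            k=None,
            block_size=p.block_size,
            nonneg=p.nonneg,
            strength_sink=strength,
        )
        graph = build_graph(strength, p.strength_threshold)
        centralities = current_flow_centralities(graph)
        return HubAnalysisResults(self, strength, graph, centralities)


@dataclass
class HubAnalysisResults:
    model: HubAnalysis
    strength: StrengthMatrix
    graph: "object"
    centralities: CentralityScores

    def dominance_frame(self, top: int = 10) -> pd.DataFrame:
        """Dominant band/task of the strongest ROI pairs."""
        rows = []
        for (i, j), s in self.strength.ranked_pairs()[:top]:
            if s == 0:
                break
            rows.append(
                {
                    "roi_i": i,
                    "roi_j": j,
                    "strength": s,
                    "dominant_band": self.strength.dominant("band", pair=(i, j)),
                    "dominant_task": self.strength.dominant("task", pair=(i, j)),
                }
            )
        return pd.DataFrame(rows)

    def centrality_frame(self, top: int = 5) -> pd.DataFrame:
        return centrality_table(
            self.centralities, self.model.dataset.atlas, top=top
        )

    def summary(self) -> str:
        strength = self.strength
        pairs = strength.ranked_pairs()
        lines = [
            "Hub-graph analysis",
            "==================",
            f"symptom:            {self.model.symptom}",
            f"features scored:    {strength.n_records} "
            f"(skipped, no ROI pair: {strength.skipped})",
            f"edge threshold:     {self.model.params.strength_threshold}",
            f"edges:              {self.graph.number_of_edges()}",
            "",
            "Strongest ROI pairs:",
        ]
        for (i, j), s in pairs[:5]:
            if s == 0:
                break
            lines.append(
                f"  ({i:2d}, {j:2d})  strength {s:10.3f}  "
                f"band {strength.dominant('band', pair=(i, j))}  "
                f"task {strength.dominant('task', pair=(i, j))}"
            )
        top = self.centrality_frame()
        if len(top):
            lines += ["", "Top ROIs by current-flow centrality:",
                      top.round(4).to_string(index=False)]
        return "\n".join(lines)
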