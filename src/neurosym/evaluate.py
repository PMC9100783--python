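"""Cross-validated evaluation, sensitivity/specificity, and the
label-permutation null.

Evaluation is 5 repeats of stratified 5-fold cross-validation (25
fold-evaluations) per symptom and pipeline variant.  All data-dependent
fitting — feature selection, calibration, oversampling, standardization —
happens on training partitions only in the default fold-safe mode; the
paper-faithful mode instead selects features on the whole cohort before
splitting, as the reference analysis describes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold

from .augment import stage1_features
from .classify import fit_logistic_l2
from .config import PipelineParams, canonical_variant
from .data import CohortDataset
from .resample import GaussianAugmentConfig, oversample
from .scoring import materialize_positions, scan_universe

__all__ = [
    "ConfusionCounts",
    "CVResult",
    "PermutationNull",
    "sensitivity_specificity",
    "accuracy",
    "evaluate_cv",
    "permutation_null",
    "proportion_ci_halfwidth",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def sensitivity_specificity(c: ConfusionCounts) -> tuple[float, float]:
    """(TP/(TP+FN), TN/(TN+FP)); a zero denominator is an explicit error,
    never a silent 0."""
    if c.TP + c.FN == 0:
        raise ZeroDivisionError("sensitivity undefined: no positive cases")
    if c.TN + c.FP == 0:
        raise ZeroDivisionError("specificity undefined: no negative cases")
    return c.TP / (c.TP + c.FN), c.TN / (c.TN + c.FP)


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise ZeroDivisionError("accuracy undefined on empty test set")
    return (c.TP + c.TN) / c.total


@dataclass
class CVResult:
    """All fold-evaluations for one (symptom, variant)."""

    symptom: str
    variant: str
    counts: list[list[ConfusionCounts]]  # [repeat][fold]

    def _metric(self, fn) -> np.ndarray:
        return np.array([fn(c) for rep in self.counts for c in rep])

    @property
    def n_evaluations(self) -> int:
        return sum(len(r) for r in self.counts)

    @property
    def accuracies(self) -> np.ndarray:
        return self._metric(accuracy)

    @property
    def sensitivities(self) -> np.ndarray:
        return self._metric(lambda c: sensitivity_specificity(c)[0])

    @property
    def specificities(self) -> np.ndarray:
        return self._metric(lambda c: sensitivity_specificity(c)[1])

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name, vals in (
            ("sensitivity", self.sensitivities),
            ("specificity", self.specificities),
            ("accuracy", self.accuracies),
        ):
            rows.append(
                {
                    "symptom": self.symptom,
                    "variant": self.variant,
                    "metric": name,
                    "mean": vals.mean(),
                    "sd": vals.std(ddof=1),
                }
            )
        return pd.DataFrame(rows)

    def __repr__(self) -> str:
        a = self.accuracies
        return (
            f"CVResult({self.symptom}, {self.variant}, "
            f"accuracy {a.mean():.3f} +/- {a.std(ddof=1):.3f}, "
            f"{self.n_evaluations} fold-evaluations)"
        )


def _check_stratifiable(y: np.ndarray, folds: int) -> None:
    for cls in (0, 1):
        n_cls = int((y == cls).sum())
        if n_cls < folds:
            raise ValueError(
                f"class {cls} has only {n_cls} members; cannot stratify "
                f"into {folds} folds"
            )


def _fold_rng(seed: int, repeat: int, fold: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([abs(int(seed)), repeat, fold])
    )


def _standardize(train: np.ndarray, other: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (other - mu) / sd


def _cv_loop(
    design_fn,
    y: np.ndarray,
    *,
    folds: int,
    repeats: int,
    seed: int,
    do_oversample: bool,
    params: PipelineParams,
) -> list[list[ConfusionCounts]]:
    """Generic stratified CV loop.

    ``design_fn(train_idx)`` returns the full (n x p) design for a given
    training partition (so fold-safe selection can depend on it); static
    designs just ignore the argument.
    """
    counts: list[list[ConfusionCounts]] = []
    gauss = GaussianAugmentConfig(params.gaussian_factor, params.gaussian_scale)
    for rep in range(repeats):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=abs(int(seed)) + rep
        )
        rep_counts = []
        for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
            X = design_fn(tr)
            Xtr, ytr = X[tr], y[tr]
            if do_oversample:
                Xtr, ytr = oversample(
                    Xtr,
                    ytr,
                    smote_k=params.smote_k,
                    gaussian=gauss,
                    order=params.oversample_order,
                    seed=_fold_rng(seed, rep, fold),
                )
            Xtr_s, Xte_s = _standardize(Xtr, X[te])
            model = fit_logistic_l2(
                Xtr_s,
                ytr,
                lam=params.lam,
                fit_intercept=params.fit_intercept,
            )
            pred = model.predict(Xte_s)
            yte = y[te]
            rep_counts.append(
                ConfusionCounts(
                    TP=int(((pred == 1) & (yte == 1)).sum()),
                    TN=int(((pred == 0) & (yte == 0)).sum()),
                    FP=int(((pred == 1) & (yte == 0)).sum()),
                    FN=int(((pred == 0) & (yte == 1)).sum()),
                )
            )
        counts.append(rep_counts)
    return counts


def _augmented_design_fn(dataset: CohortDataset, y, params, stage1=None):
    """Design provider for the DA+FS(+OS) variant."""
    S = stage1 if stage1 is not None else stage1_features(dataset).values
    k = min(params.k, 2 * (S.shape[1] + S.shape[1] * (S.shape[1] - 1) // 2))

    if params.leakage_mode == "paper_faithful":
        (chi, pos), = scan_universe(
            S, y, k=k, block_size=params.block_size, nonneg=params.nonneg
        )
        X = materialize_positions(S, pos, nonneg=params.nonneg)
        return lambda tr: X

    def fold_safe(tr):
        rows = np.zeros(len(y), dtype=bool)
        rows[tr] = True
        (chi, pos), = scan_universe(
            S,
            y,
            k=k,
            rows=rows,
            block_size=params.block_size,
            nonneg=params.nonneg,
        )
        return materialize_positions(S, pos, rows=rows, nonneg=params.nonneg)

    return fold_safe


def evaluate_cv(
    dataset: CohortDataset,
    symptom: str,
    variant: str = "da_fs_os",
    *,
    folds: int = 5,
    repeats: int = 5,
    seed: int = 0,
    params: PipelineParams | None = None,
    stage1: np.ndarray | None = None,
) -> CVResult:
    """Repeated stratified cross-validation of one pipeline variant.

    Folds preserve the cohort's label ratio to within one subject; with the
    default 5 x 5 scheme the result carries 25 fold-evaluations.
    """
    params = params or PipelineParams()
    variant = canonical_variant(variant)
    y = dataset.label_vector(symptom)
    _check_stratifiable(y, folds)

    if variant in ("original", "os"):
        X0 = dataset.feature_matrix()
        design_fn = lambda tr: X0  # noqa: E731
        do_os = variant == "os"
    else:
        design_fn = _augmented_design_fn(dataset, y, params, stage1)
        do_os = True

    counts = _cv_loop(
        design_fn,
        y,
        folds=folds,
        repeats=repeats,
        seed=seed,
        do_oversample=do_os,
        params=params,
    )
    return CVResult(symptom, variant, counts)


@dataclass
class PermutationNull:
    """Null distribution of mean CV accuracy under label shuffling."""

    symptom: str
    variant: str
    accuracies: np.ndarray  # one mean accuracy per permutation

    @property
    def n_permutations(self) -> int:
        return len(self.accuracies)

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.accuracies, q))

    @property
    def p95(self) -> float:
        """The 95th-percentile randomized-control accuracy."""
        return self.percentile(95.0)

    def band(self, level: float = 0.95) -> tuple[float, float]:
        alpha = 100.0 * (1.0 - level) / 2.0
        return self.percentile(alpha), self.percentile(100.0 - alpha)


def permutation_null(
    dataset: CohortDataset,
    symptom: str,
    variant: str = "da_fs_os",
    *,
    n_perm: int = 100,
    folds: int = 5,
    repeats: int = 1,
    seed: int = 0,
    params: PipelineParams | None = None,
) -> PermutationNull:
    """Re-run the full pipeline on label-shuffled cohorts.

    Each permutation preserves the class counts (it is a shuffle, not a
    redraw); the returned distribution of mean CV accuracies yields the
    95th-percentile randomized-control threshold.  For the paper-faithful
    augmented variant all permutations are scored in a single pass over the
    feature universe (identical results to the one-at-a-time loop, which
    the other variants use).
    """
    params = params or PipelineParams()
    variant = canonical_variant(variant)
    y = dataset.label_vector(symptom)
    _check_stratifiable(y, folds)
    rng = np.random.default_rng(seed)
    perms = [y[rng.permutation(len(y))] for _ in range(n_perm)]

    accs = np.empty(n_perm)
    if variant == "da_fs_os" and params.leakage_mode == "fold_safe":
        accs = _null_fold_safe_augmented(
            dataset, symptom, perms, folds, repeats, seed, params
        )
    elif variant == "da_fs_os" and params.leakage_mode == "paper_faithful":
        S = stage1_features(dataset).values
        m = S.shape[1]
        k = min(params.k, 2 * (m + m * (m - 1) // 2))
        Y = np.column_stack(perms)
        results = scan_universe(
            S, Y, k=k, block_size=params.block_size, nonneg=params.nonneg
        )
        for p, (chi, pos) in enumerate(results):
            X = materialize_positions(S, pos, nonneg=params.nonneg)
            counts = _cv_loop(
                lambda tr: X,
                perms[p],
                folds=folds,
                repeats=repeats,
                seed=seed,
                do_oversample=True,
                params=params,
            )
            accs[p] = CVResult(symptom, variant, counts).accuracies.mean()
    else:
        for p, yp in enumerate(perms):
            shuffled = dataset.with_labels(symptom, yp)
            res = evaluate_cv(
                shuffled,
                symptom,
                variant,
                folds=folds,
                repeats=repeats,
                seed=seed,
                params=params,
            )
            accs[p] = res.accuracies.mean()
    return PermutationNull(symptom, variant, accs)


def _null_fold_safe_augmented(
    dataset: CohortDataset,
    symptom: str,
    perms: list[np.ndarray],
    folds: int,
    repeats: int,
    seed: int,
    params: PipelineParams,
) -> np.ndarray:
    """Fold-safe permutation null for the augmented variant.

    The fold partition is stratified on the *original* labels and held
    fixed across permutations (under the null a permuted label vector is
    exchangeable with the original, so the fixed partition remains
    approximately stratified); selection + calibration are then refit on
    each training partition for every permuted label vector, all
    permutations scored in a single pass per fold.  A training partition
    that loses a class under some permutation falls back to the
    majority-class predictor for that fold.
    """
    y0 = dataset.label_vector(symptom)
    n = len(y0)
    S = stage1_features(dataset).values
    m = S.shape[1]
    k = min(params.k, 2 * (m + m * (m - 1) // 2))
    gauss = GaussianAugmentConfig(params.gaussian_factor, params.gaussian_scale)
    Y = np.column_stack(perms)
    accs = np.zeros(len(perms))
    n_eval = folds * repeats
    for rep in range(repeats):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=abs(int(seed)) + rep
        )
        for fold, (tr, te) in enumerate(skf.split(np.zeros(n), y0)):
            rows = np.zeros(n, dtype=bool)
            rows[tr] = True
            degenerate = [
                p
                for p in range(Y.shape[1])
                if len(np.unique(Y[tr, p])) < 2
            ]
            ok = [p for p in range(Y.shape[1]) if p not in degenerate]
            results = scan_universe(
                S,
                Y[:, ok],
                k=k,
                rows=rows,
                block_size=params.block_size,
                nonneg=params.nonneg,
            )
            for p in degenerate:
                maj = int(round(Y[tr, p].mean()))
                accs[p] += (Y[te, p] == maj).mean() / n_eval
            for idx, (chi, pos) in zip(ok, results):
                yp = Y[:, idx]
                X = materialize_positions(
                    S, pos, rows=rows, nonneg=params.nonneg
                )
                Xtr, ytr = oversample(
                    X[tr],
                    yp[tr],
                    smote_k=params.smote_k,
                    gaussian=gauss,
                    order=params.oversample_order,
                    seed=_fold_rng(seed, rep, fold),
                )
                Xtr_s, Xte_s = _standardize(Xtr, X[te])
                model = fit_logistic_l2(
                    Xtr_s, ytr, lam=params.lam, fit_intercept=params.fit_intercept
                )
                accs[idx] += (model.predict(Xte_s) == yp[te]).mean() / n_eval
    return accs


def proportion_ci_halfwidth(
    n: int, p: float = 0.5, level: float = 0.95
) -> float:
    """Normal-approximation CI half-width of a proportion, in percent:
    ``100 * z * sqrt(p (1 - p) / n)`` (9.95 for n = 97, p = 1/2, 95%)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = sps.norm.ppf(0.5 + level / 2.0)
    return float(100.0 * z * np.sqrt(p * (1.0 - p) / n))
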