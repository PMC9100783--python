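"""Continuous chi-squared feature scoring and bounded-memory top-k selection.

The selection statistic is the chi-squared measure extended to non-negative
continuous features: with ``S_c`` the sum of a feature's values over class
``c`` and ``E_c = (S_0 + S_1) * P_c`` the expected sum under the class
proportions ``P_c``,

    chi2(D, c) = sum_c (S_c - E_c)^2 / E_c .

It is used purely as a ranking score (no p-values).  Because
baseline-corrected amplitudes and products of them can be negative while the
statistic requires non-negative sums, features containing negative values
are min-max rescaled to [0, 1] before scoring ("auto" mode, the default);
already non-negative features pass through unchanged.

Two scoring surfaces are provided:

* a descriptor-level surface (:func:`select_top_k`,
  :func:`score_all_for_strength`) that consumes ``FeatureBlock`` streams and
  emits :class:`ChiSquareRecord` objects — convenient at toy scale and for
  oracle tests;
* a position-level engine (:func:`scan_universe`,
  :func:`materialize_positions`) that works on stage-1 column indices and
  vectorizes over blocks (and over many permuted label vectors at once),
  used by cross-validation, the permutation null and strength aggregation
  at realistic scale.

Both walk the same universe in the same order: base column ``p`` (singleton
or product) occupies stream positions ``2p`` (plain) and ``2p + 1``
(calibrated log).  Ties in chi-squared break toward the earlier stream
position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Iterator

import numpy as np
import pandas as pd

from .augment import (
    FeatureBlock,
    FeatureDescriptor,
    iter_base_blocks,
    pair_unrank,
)

__all__ = [
    "ChiSquareRecord",
    "TopKSelection",
    "nonneg_calibrate",
    "chi_square",
    "chi_square_components",
    "select_top_k",
    "score_all_for_strength",
    "scan_universe",
    "materialize_positions",
]


@dataclass(frozen=True)
class ChiSquareRecord:
    """A feature descriptor paired with its chi-squared score."""

    descriptor: FeatureDescriptor
    chi2: float
    position: int = -1  # stream position (tie-break key); -1 if unknown
    symptom: str | None = None

    def __post_init__(self):
        if not (np.isfinite(self.chi2) and self.chi2 >= 0):
            raise ValueError(f"chi2 must be finite and >= 0, got {self.chi2}")


def nonneg_calibrate(
    values: np.ndarray, passthrough_nonnegative: bool = False
) -> np.ndarray:
    """Min-max rescale a per-subject feature vector to [0, 1].

    A constant feature maps to all zeros.  With ``passthrough_nonnegative``
    a feature that is already non-negative is returned unchanged (the
    pipeline's default treatment: only features containing negative values
    are rescaled).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("nonneg_calibrate needs at least 2 subjects")
    mn, mx = x.min(), x.max()
    if passthrough_nonnegative and mn >= 0:
        return x
    if mx == mn:
        return np.zeros_like(x)
    return (x - mn) / (mx - mn)


def _validate_labels(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return y.astype(float)


def chi_square_components(
    values: np.ndarray, labels: np.ndarray
) -> dict[str, float]:
    """Observed and expected class sums (S_e0, S_e1, E_e0, E_e1) of the
    worked-example form of the statistic."""
    x = np.asarray(values, dtype=float)
    if np.any(x < 0):
        raise ValueError(
            "chi_square requires non-negative values; apply nonneg_calibrate first"
        )
    y = _validate_labels(labels)
    if x.shape != y.shape:
        raise ValueError("values and labels must have the same length")
    n = y.size
    p1 = y.sum() / n
    S1 = float(x[y == 1].sum())
    S0 = float(x[y == 0].sum())
    total = S0 + S1
    return {
        "S_e0": S0,
        "S_e1": S1,
        "E_e0": total * (1 - p1),
        "E_e1": total * p1,
    }


def chi_square(values: np.ndarray, labels: np.ndarray) -> float:
    """Chi-squared score of one non-negative feature against binary labels.

    All-zero values carry no evidence and score 0.  The statistic is
    invariant to subject order and scales linearly: ``chi2(a*x, y) =
    a * chi2(x, y)`` for a > 0.
    """
    c = chi_square_components(values, labels)
    total = c["S_e0"] + c["S_e1"]
    if total == 0:
        return 0.0
    return (c["S_e0"] - c["E_e0"]) ** 2 / c["E_e0"] + (
        c["S_e1"] - c["E_e1"]
    ) ** 2 / c["E_e1"]


# ---------------------------------------------------------------------------
# vectorized block scoring
# ---------------------------------------------------------------------------


def _chi2_from_class_sums(S0, S1, p0, p1):
    """Vectorized chi2 from per-class sums (any shape); zero total -> 0."""
    T = S0 + S1
    with np.errstate(divide="ignore", invalid="ignore"):
        E0 = T * p0
        E1 = T * p1
        chi = (S0 - E0) ** 2 / E0 + (S1 - E1) ** 2 / E1
    return np.where(T > 0, chi, 0.0)


def _block_chi2(V, Y, nonneg: str):
    """chi2 of every column of ``V`` (rows x cols) against every label
    column of ``Y`` (rows x n_lab), for the plain and log variants.

    Returns ``(chi_plain, chi_log)``, each (n_lab, cols).  Calibration
    statistics (per-column min/max) are computed from ``V`` itself, i.e.
    from whatever row subset the caller passes.
    """
    n = V.shape[0]
    n1 = Y.sum(axis=0)  # (n_lab,)
    p1 = (n1 / n)[:, None]
    p0 = 1.0 - p1

    mn = V.min(axis=0)
    mx = V.max(axis=0)
    rng = mx - mn
    const = rng == 0

    S1_raw = Y.T @ V  # (n_lab, cols)
    T_raw = V.sum(axis=0)[None, :]
    S0_raw = T_raw - S1_raw

    if nonneg == "off":
        calib = np.zeros_like(const)
    elif nonneg == "always":
        calib = ~const
    else:  # "auto": only columns containing negatives
        calib = (mn < 0) & ~const

    with np.errstate(divide="ignore", invalid="ignore"):
        safe_rng = np.where(rng == 0, 1.0, rng)
        S1_cal = (S1_raw - n1[:, None] * mn[None, :]) / safe_rng[None, :]
        S0_cal = (S0_raw - (n - n1)[:, None] * mn[None, :]) / safe_rng[None, :]
    S1 = np.where(calib[None, :], S1_cal, S1_raw)
    S0 = np.where(calib[None, :], S0_cal, S0_raw)
    chi_plain = _chi2_from_class_sums(S0, S1, p0, p1)
    chi_plain[:, const] = 0.0

    # log variant: W = log1p((V - mn)/rng); constant columns -> all zeros -> 0
    W = (V - mn[None, :]) / safe_rng[None, :]
    np.log1p(W, out=W)
    S1l = Y.T @ W
    S0l = W.sum(axis=0)[None, :] - S1l
    chi_log = _chi2_from_class_sums(S0l, S1l, p0, p1)
    chi_log[:, const] = 0.0
    return chi_plain, chi_log


class _TopK:
    """Running exact top-k under descending chi2, ties to earlier stream
    position.  Candidates always arrive in increasing position order, so a
    candidate tying the current threshold can never displace an incumbent
    and a strict threshold filter is exact."""

    def __init__(self, k: int):
        self.k = k
        self.scores = np.empty(0)
        self.positions = np.empty(0, dtype=np.int64)

    def offer(self, scores: np.ndarray, positions: np.ndarray) -> None:
        if len(self.scores) >= self.k:
            thr = self.scores.min()
            keep = scores > thr
            if not keep.any():
                return
            scores, positions = scores[keep], positions[keep]
        s = np.concatenate([self.scores, scores])
        p = np.concatenate([self.positions, positions])
        order = np.lexsort((p, -s))[: self.k]
        self.scores, self.positions = s[order], p[order]

    def result(self) -> tuple[np.ndarray, np.ndarray]:
        order = np.lexsort((self.positions, -self.scores))
        return self.scores[order], self.positions[order]


def scan_universe(
    stage1_values: np.ndarray,
    labels: np.ndarray,
    *,
    k: int | None = None,
    rows: np.ndarray | None = None,
    block_size: int = 20000,
    nonneg: str = "auto",
    strength_sink=None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Single pass over the augmented universe of ``stage1_values``.

    ``labels`` may be a single 0/1 vector or an (n, n_lab) matrix of label
    vectors (e.g. permutations) scored simultaneously.  When ``rows`` is
    given, scoring (and calibration) uses only those rows — the fold-safe
    training partition.  ``strength_sink``, if given, receives
    ``add_block(i_idx, j_idx, chi_plain, chi_log)`` calls for every product
    block (single label vector only).

    Returns, per label vector, ``(chi2, positions)`` of the top-k features
    sorted descending (ties to earlier position), or ``(None, None)``
    placeholders if ``k`` is None.
    """
    S = np.asarray(stage1_values, dtype=float)
    if rows is not None:
        S = S[rows]
        labels = np.asarray(labels)[rows]
    Y = np.asarray(labels, dtype=float)
    single = Y.ndim == 1
    if single:
        Y = Y[:, None]
    for col in range(Y.shape[1]):
        _validate_labels(Y[:, col].astype(int))
    if strength_sink is not None and Y.shape[1] != 1:
        raise ValueError("strength accumulation requires a single label vector")

    m = S.shape[1]
    tops = [_TopK(k) for _ in range(Y.shape[1])] if k is not None else None

    for i_idx, j_idx in iter_base_blocks(m, block_size):
        if j_idx[0] < 0:
            V = S[:, i_idx]
            base = i_idx
        else:
            V = S[:, i_idx] * S[:, j_idx]
            base = m + (
                i_idx * (2 * m - i_idx - 1) // 2 + (j_idx - i_idx - 1)
            )
        chi_plain, chi_log = _block_chi2(V, Y, nonneg)
        if strength_sink is not None:
            if j_idx[0] >= 0:
                strength_sink.add_block(i_idx, j_idx, chi_plain[0], chi_log[0])
            elif hasattr(strength_sink, "count_skipped"):
                strength_sink.count_skipped(2 * len(i_idx))
        if tops is not None:
            pos_plain = 2 * base
            pos_log = pos_plain + 1
            for col, top in enumerate(tops):
                top.offer(
                    np.concatenate([chi_plain[col], chi_log[col]]),
                    np.concatenate([pos_plain, pos_log]),
                )
    if tops is None:
        return [(None, None)] * Y.shape[1]
    return [t.result() for t in tops]


def materialize_positions(
    stage1_values: np.ndarray,
    positions: np.ndarray,
    *,
    rows: np.ndarray | None = None,
    nonneg: str = "auto",
) -> np.ndarray:
    """Materialize universe columns (by stream position) for all subjects.

    Calibration min/max come from ``rows`` (the training partition) when
    given; other rows are transformed with those statistics.  For log
    features the scaled value is clipped to [0, 1] before ``log1p`` so the
    transform stays in its domain on out-of-partition rows.
    """
    S = np.asarray(stage1_values, dtype=float)
    m = S.shape[1]
    positions = np.asarray(positions, dtype=np.int64)
    is_log = positions % 2 == 1
    base = positions // 2
    singleton = base < m
    V = np.empty((S.shape[0], len(positions)))
    V[:, singleton] = S[:, base[singleton]]
    if (~singleton).any():
        i, j = pair_unrank(base[~singleton] - m, m)
        V[:, ~singleton] = S[:, i] * S[:, j]

    ref = V if rows is None else V[rows]
    mn = ref.min(axis=0)
    mx = ref.max(axis=0)
    rng = mx - mn
    safe_rng = np.where(rng == 0, 1.0, rng)

    out = V.copy()
    if nonneg == "always":
        calib = rng > 0
    elif nonneg == "off":
        calib = np.zeros(len(positions), dtype=bool)
    else:
        calib = (mn < 0) & (rng > 0)
    scaled = (V - mn[None, :]) / safe_rng[None, :]
    plain_cal = ~is_log & calib
    out[:, plain_cal] = scaled[:, plain_cal]
    out[:, ~is_log & (rng == 0) & (mn < 0)] = 0.0
    if is_log.any():
        lg = np.log1p(np.clip(scaled[:, is_log], 0.0, 1.0))
        lg[:, rng[is_log] == 0] = 0.0
        out[:, is_log] = lg
    return out


# ---------------------------------------------------------------------------
# descriptor-level surfaces
# ---------------------------------------------------------------------------


@dataclass
class TopKSelection:
    """The k best features for one symptom: records in descending chi2
    order plus their materialized value matrix (subjects x k)."""

    k: int
    records: list[ChiSquareRecord]
    values: np.ndarray
    symptom: str | None = None
    universe: int = 0  # number of features scored

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.records) + 1),
                "chi2": [r.chi2 for r in self.records],
                "feature": [r.descriptor.encode() for r in self.records],
            }
        )


def _iter_blocks(stream) -> Iterator[FeatureBlock]:
    return iter(stream() if callable(stream) else stream)


def select_top_k(
    stream: Iterable[FeatureBlock] | Callable[[], Iterable[FeatureBlock]],
    labels: np.ndarray,
    k: int = 40_000,
    *,
    nonneg: str = "auto",
    symptom: str | None = None,
) -> TopKSelection:
    """Exact top-k chi-squared selection over a streamed feature universe.

    Each streamed column is scored twice (plain and calibrated-log); the
    running top-k is exact (equivalent to full sort) and deterministic given
    the stream order, with ties broken toward the earlier stream position.
    The selected columns are materialized alongside.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    y = _validate_labels(labels)
    Y = y[:, None]

    best: list[tuple[float, int, FeatureDescriptor, np.ndarray]] = []
    thr = -np.inf  # k-th best so far; later positions lose ties, so a
    # strict > filter against it is exact
    pos = 0
    n_scored = 0
    for block in _iter_blocks(stream):
        chi_plain, chi_log = _block_chi2(block.values, Y, nonneg)
        mn = block.values.min(axis=0)
        mx = block.values.max(axis=0)
        safe_rng = np.where(mx == mn, 1.0, mx - mn)
        for c, desc in enumerate(block.descriptors):
            col = block.values[:, c]
            for is_log, chi in ((False, chi_plain[0, c]), (True, chi_log[0, c])):
                n_scored += 1
                entry_pos = pos
                pos += 1
                if chi <= thr:
                    continue
                if is_log:
                    if mx[c] == mn[c]:
                        vals = np.zeros_like(col)
                    else:
                        vals = np.log1p(
                            np.clip((col - mn[c]) / safe_rng[c], 0.0, 1.0)
                        )
                    d = desc.with_log()
                else:
                    if mx[c] == mn[c] and mn[c] < 0:
                        vals = np.zeros_like(col)
                    elif (
                        nonneg == "always" or (nonneg == "auto" and mn[c] < 0)
                    ) and mx[c] > mn[c]:
                        vals = (col - mn[c]) / safe_rng[c]
                    else:
                        vals = col
                    d = desc
                best.append((float(chi), entry_pos, d, vals))
        if len(best) >= k:
            best.sort(key=lambda e: (-e[0], e[1]))
            del best[k:]
            thr = best[-1][0]
    if pos == 0:
        raise ValueError("empty feature stream")
    best.sort(key=lambda e: (-e[0], e[1]))
    best = best[:k]
    records = [
        ChiSquareRecord(d, chi, position=p, symptom=symptom)
        for chi, p, d, _ in best
    ]
    values = (
        np.column_stack([v for _, _, _, v in best])
        if best
        else np.empty((len(y), 0))
    )
    return TopKSelection(k, records, values, symptom=symptom, universe=n_scored)


def score_all_for_strength(
    stream: Iterable[FeatureBlock] | Callable[[], Iterable[FeatureBlock]],
    labels: np.ndarray,
    sink,
    *,
    nonneg: str = "auto",
    symptom: str | None = None,
) -> int:
    """Score every feature in the stream (plain and log) and emit each
    :class:`ChiSquareRecord` to ``sink`` without retaining it.

    ``sink`` is a callable or an object with an ``add_record`` method (the
    hub-graph strength accumulator).  Returns the number of records emitted.
    """
    y = _validate_labels(labels)
    Y = y[:, None]
    emit = sink.add_record if hasattr(sink, "add_record") else sink
    pos = 0
    for block in _iter_blocks(stream):
        chi_plain, chi_log = _block_chi2(block.values, Y, nonneg)
        for c, desc in enumerate(block.descriptors):
            emit(
                ChiSquareRecord(
                    desc, float(chi_plain[0, c]), position=pos, symptom=symptom
                )
            )
            pos += 1
            emit(
                ChiSquareRecord(
                    desc.with_log(),
                    float(chi_log[0, c]),
                    position=pos,
                    symptom=symptom,
                )
            )
            pos += 1
    return pos
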