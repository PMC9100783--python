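"""Feature augmentation: stage-1 statistical features and the streamed
product/log feature universe.

Stage 1 expands each subject's (R, B, T) tensor into

* ``R*B*T`` identity features (ROI-major, then band, then task),
* ``7*B*T`` features from the seven statistics taken across ROIs
  (ordered by band, then task, then measure),
* ``7*R*B`` features from the statistics taken across tasks
  (ordered by ROI, then band, then measure),
* ``7*R*T`` features from the statistics taken across bands
  (ordered by ROI, then task, then measure),

for ``R*B*T + 7*(B*T + R*B + R*T)`` features in total (4933 at the full
68 x 3 x 5 scale).  The seven statistics are max, min, range, mean,
population std, and the 0.75/0.25 quantiles (linear interpolation).

Stage 2 forms the elementwise product of every unordered pair of distinct
stage-1 features; stage 3 pairs every feature (singleton or product) with a
calibrated log transform.  The full universe is therefore
``2 * (m + C(m, 2))`` columns for ``m`` stage-1 features — 24,339,422 at
full scale — and is streamed in fixed-size blocks, never materialized.

Universe ordering (the tie-break order for selection): base columns are the
``m`` stage-1 singletons followed by pairs (i, j), i < j, in lexicographic
order; base column ``p`` occupies stream positions ``2p`` (plain) and
``2p + 1`` (log).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .data import BANDS, TASKS, CohortDataset

__all__ = [
    "MEASURES",
    "FeatureDescriptor",
    "FeatureBlock",
    "stage1_features",
    "count_augmented",
    "product_stream",
    "log_calibrate",
    "universe_size",
    "pair_rank",
    "pair_unrank",
    "iter_base_blocks",
]

MEASURES: tuple[str, ...] = ("max", "min", "range", "mean", "std", "q75", "q25")

_AGG = None  # attribute value meaning "aggregated over this axis"


@dataclass(frozen=True)
class FeatureDescriptor:
    """Provenance of one (possibly augmented) feature.

    ``roi``/``band``/``task`` are concrete values or ``None`` when the
    measure aggregates over that axis.  ``product`` holds the two
    constituent (non-product) descriptors for interaction features.
    """

    measure: str  # "identity", one of MEASURES, or "product"
    roi: int | None = None
    band: str | None = None
    task: int | None = None
    product: tuple["FeatureDescriptor", "FeatureDescriptor"] | None = None
    log: bool = False

    def __post_init__(self):
        if self.measure == "identity":
            if None in (self.roi, self.band, self.task):
                raise ValueError("identity features need concrete roi/band/task")
        elif self.measure in MEASURES:
            if sum(a is None for a in (self.roi, self.band, self.task)) != 1:
                raise ValueError(
                    "stage-1 statistical features aggregate exactly one axis"
                )
        elif self.measure == "product":
            if self.product is None:
                raise ValueError("product descriptor needs constituents")
            if any(c.product is not None or c.log for c in self.product):
                raise ValueError("product constituents must be plain stage-1 features")
        else:
            raise ValueError(f"unknown measure {self.measure!r}")

    @property
    def constituents(self) -> tuple["FeatureDescriptor", ...]:
        return self.product if self.product is not None else (self,)

    @property
    def roi_pair(self) -> tuple[int, int] | None:
        """(i1, i2) with i1 < i2 when both constituents have concrete,
        distinct ROIs; otherwise None."""
        if self.product is None:
            return None
        r1, r2 = self.product[0].roi, self.product[1].roi
        if r1 is None or r2 is None or r1 == r2:
            return None
        return (min(r1, r2), max(r1, r2))

    def with_log(self) -> "FeatureDescriptor":
        return FeatureDescriptor(
            self.measure, self.roi, self.band, self.task, self.product, log=True
        )

    def encode(self) -> str:
        """Compact text encoding: measure:roi:band:task[*...][,log]."""

        def one(d: "FeatureDescriptor") -> str:
            return ":".join(
                [
                    d.measure,
                    "agg" if d.roi is None else str(d.roi),
                    "agg" if d.band is None else str(d.band),
                    "agg" if d.task is None else str(d.task),
                ]
            )

        body = "*".join(one(c) for c in self.constituents)
        return body + (",log" if self.log else "")

    @classmethod
    def decode(cls, text: str) -> "FeatureDescriptor":
        body, _, tail = text.partition(",")
        log = tail == "log"
        parts = []
        for chunk in body.split("*"):
            measure, roi, band, task = chunk.split(":")
            parts.append(
                cls(
                    measure,
                    None if roi == "agg" else int(roi),
                    None if band == "agg" else band,
                    None if task == "agg" else int(task),
                )
            )
        if len(parts) == 1:
            d = parts[0]
            return cls(d.measure, d.roi, d.band, d.task, log=log) if log else d
        return cls("product", product=(parts[0], parts[1]), log=log)


@dataclass
class FeatureBlock:
    """A contiguous block of the feature universe: descriptors plus the
    (subjects x width) value matrix."""

    descriptors: list[FeatureDescriptor]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.descriptors):
            raise ValueError("values must be (subjects x len(descriptors))")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")

    @property
    def width(self) -> int:
        return self.values.shape[1]


def _stats(block: np.ndarray, axis: int) -> list[np.ndarray]:
    """The seven statistics along ``axis``, in MEASURES order.

    std is the population standard deviation (ddof=0); quantiles use linear
    interpolation between order statistics.
    """
    mx = block.max(axis=axis)
    mn = block.min(axis=axis)
    return [
        mx,
        mn,
        mx - mn,
        block.mean(axis=axis),
        block.std(axis=axis),
        np.quantile(block, 0.75, axis=axis),
        np.quantile(block, 0.25, axis=axis),
    ]


def stage1_features(dataset: CohortDataset) -> FeatureBlock:
    """Stage-1 feature matrix for the whole cohort (see module docstring
    for the exact ordering)."""
    tensor = dataset.tensor_array()  # (n, R, B, T)
    n, R, B, T = tensor.shape
    bands, tasks = dataset.bands, dataset.tasks

    cols: list[np.ndarray] = []
    desc: list[FeatureDescriptor] = []

    # identity block: ROI-major, then band, then task
    cols.append(tensor.reshape(n, R * B * T))
    for r in range(R):
        for b in range(B):
            for t in range(T):
                desc.append(
                    FeatureDescriptor("identity", r + 1, bands[b], tasks[t])
                )

    # across ROIs: per (band, task), 7 measures
    stats = _stats(tensor, axis=1)  # each (n, B, T)
    for b in range(B):
        for t in range(T):
            for m, s in zip(MEASURES, stats):
                cols.append(s[:, b, t][:, None])
                desc.append(FeatureDescriptor(m, _AGG, bands[b], tasks[t]))

    # across tasks: per (roi, band), 7 measures
    stats = _stats(tensor, axis=3)  # each (n, R, B)
    for r in range(R):
        for b in range(B):
            for m, s in zip(MEASURES, stats):
                cols.append(s[:, r, b][:, None])
                desc.append(FeatureDescriptor(m, r + 1, bands[b], _AGG))

    # across bands: per (roi, task), 7 measures
    stats = _stats(tensor, axis=2)  # each (n, R, T)
    for r in range(R):
        for t in range(T):
            for m, s in zip(MEASURES, stats):
                cols.append(s[:, r, t][:, None])
                desc.append(FeatureDescriptor(m, r + 1, _AGG, tasks[t]))

    return FeatureBlock(desc, np.hstack(cols))


def count_augmented(R: int, B: int, T: int) -> tuple[int, int, int]:
    """Closed-form universe sizes ``(stage1, with_products, with_logs)``.

    ``stage1 = R*B*T + 7*(B*T + R*B + R*T)``; products add ``C(stage1, 2)``
    interaction features; the calibrated log transform doubles the total.
    At (68, 3, 5): (4933, 12_169_711, 24_339_422).
    """
    if min(R, B, T) < 1:
        raise ValueError("R, B, T must all be >= 1")
    stage1 = R * B * T + 7 * (B * T + R * B + R * T)
    with_products = stage1 + math.comb(stage1, 2)
    return stage1, with_products, 2 * with_products


def universe_size(m: int) -> int:
    """Streamed universe size (with logs) for ``m`` stage-1 features."""
    return 2 * (m + math.comb(m, 2))


def pair_rank(i: np.ndarray, j: np.ndarray, m: int) -> np.ndarray:
    """Lexicographic rank of pair (i, j), i < j, among C(m, 2) pairs."""
    i = np.asarray(i, dtype=np.int64)
    j = np.asarray(j, dtype=np.int64)
    return i * (2 * m - i - 1) // 2 + (j - i - 1)


def pair_unrank(rank: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`pair_rank` (vectorized, exact in integer arithmetic)."""
    rank = np.asarray(rank, dtype=np.int64)
    # i is the largest integer with i*(2m-i-1)/2 <= rank
    b = 2 * m - 1
    disc = b * b - 8 * rank
    i = ((b - np.sqrt(disc.astype(float))) // 2).astype(np.int64)
    # float sqrt can be off by one near boundaries; correct exactly
    while True:
        lo = i * (2 * m - i - 1) // 2
        bad = lo > rank
        if not bad.any():
            break
        i = i - bad
    while True:
        hi = (i + 1) * (2 * m - i - 2) // 2
        bad = (hi <= rank) & (i + 1 < m - 1)
        if not bad.any():
            break
        i = i + bad
    j = rank - i * (2 * m - i - 1) // 2 + i + 1
    return i, j


def iter_base_blocks(
    m: int, block_size: int
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield the base universe (singletons then lexicographic pairs) as
    ``(i_idx, j_idx)`` blocks; singletons carry ``j = -1``.

    Base positions run 0..m-1 (singletons) then m..m+C(m,2)-1 (pairs);
    blocks partition that range contiguously.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    for start in range(0, m, block_size):
        stop = min(start + block_size, m)
        idx = np.arange(start, stop, dtype=np.int64)
        yield idx, np.full(stop - start, -1, dtype=np.int64)
    n_pairs = math.comb(m, 2)
    for start in range(0, n_pairs, block_size):
        stop = min(start + block_size, n_pairs)
        i, j = pair_unrank(np.arange(start, stop, dtype=np.int64), m)
        yield i, j


def product_stream(
    stage1: FeatureBlock, block_size: int = 4096
) -> Iterator[FeatureBlock]:
    """Stream the (pre-log) augmented universe as FeatureBlocks.

    Stage-1 features pass through first as singletons, then every unordered
    pair i < j appears exactly once (lexicographic order) as an elementwise
    product.  Log variants are not emitted here — scoring derives them
    lazily from each block (every base column has a plain and a log stream
    position).
    """
    S = stage1.values
    desc = stage1.descriptors
    m = len(desc)
    for i_idx, j_idx in iter_base_blocks(m, block_size):
        if j_idx[0] < 0:  # singleton pass-through
            yield FeatureBlock([desc[i] for i in i_idx], S[:, i_idx])
        else:
            block_desc = [
                FeatureDescriptor("product", product=(desc[i], desc[j]))
                for i, j in zip(i_idx, j_idx)
            ]
            yield FeatureBlock(block_desc, S[:, i_idx] * S[:, j_idx])


def log_calibrate(values: np.ndarray) -> np.ndarray:
    """Calibrated log transform: ``log(1 + (x - min) / (max - min))``.

    Maps each feature to [0, log 2]; a constant feature (max == min) maps to
    all zeros, the limit of the formula as the spread shrinks.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("log_calibrate needs at least 2 subjects")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values")
    mn, mx = x.min(), x.max()
    if mx == mn:
        return np.zeros_like(x)
    return np.log1p((x - mn) / (mx - mn))


def descriptor_meta(
    descriptors: list[FeatureDescriptor],
    bands: tuple[str, ...] = BANDS,
    tasks: tuple[int, ...] = TASKS,
) -> dict[str, np.ndarray]:
    """Integer-coded (roi, band, task) attributes per stage-1 column, for
    the vectorized strength accumulator; -1 codes an aggregated attribute.

    Band codes follow ``bands`` order; task codes are 0-based positions in
    ``tasks``.
    """
    band_code = {b: i for i, b in enumerate(bands)}
    task_code = {t: i for i, t in enumerate(tasks)}
    roi = np.array([-1 if d.roi is None else d.roi for d in descriptors])
    band = np.array([-1 if d.band is None else band_code[d.band] for d in descriptors])
    task = np.array([-1 if d.task is None else task_code[d.task] for d in descriptors])
    return {"roi": roi, "band": band, "task": task}
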