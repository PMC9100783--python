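"""ROI-pair strength aggregation, the thresholded hub graph, and
current-flow centralities.

Every product feature whose two constituents sit in concrete, distinct ROIs
``(i1, i2)`` contributes its chi-squared score to ``strength[i1, i2]``,
summed over both constituents' bands, tasks and the log flag.  The strength
matrix induces a weighted graph over the 68 ROIs (edge iff pair strength
exceeds a threshold; 100 in the reference figures); hub ROIs are ranked by
current-flow (electrical-network) closeness and betweenness centralities,
which account for all paths rather than only shortest ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .atlas import AtlasMap, default_atlas
from .augment import pair_rank
from .data import BANDS, TASKS
from .scoring import ChiSquareRecord

__all__ = [
    "StrengthMatrix",
    "accumulate_strengths",
    "vertex_strength",
    "dominant_factor",
    "build_graph",
    "current_flow_centralities",
    "CentralityScores",
    "centrality_table",
]

log = logging.getLogger(__name__)


class StrengthMatrix:
    """Symmetric ROI x ROI cumulative chi-squared strengths plus
    per-(pair, factor-level) sub-accumulators for bands, tasks and the log
    flag.

    Contributions whose constituents lack two concrete distinct ROIs
    (singletons, across-ROI statistics, same-ROI products) are skipped and
    counted.  Accumulation is a single pass and order-independent.
    """

    def __init__(
        self,
        n_roi: int,
        bands: tuple[str, ...] = BANDS,
        tasks: tuple[int, ...] = TASKS,
        symptom: str | None = None,
        stage1_meta: dict[str, np.ndarray] | None = None,
    ):
        self.n_roi = int(n_roi)
        self.bands = tuple(bands)
        self.tasks = tuple(tasks)
        self.symptom = symptom
        self._meta = stage1_meta
        n_pairs = n_roi * (n_roi - 1) // 2
        self._pair = np.zeros(n_pairs)
        # one extra level per factor for "aggregated" constituents: they
        # contribute to pair strength but never compete in dominant_factor
        self._band_acc = np.zeros((n_pairs, len(bands) + 1))
        self._task_acc = np.zeros((n_pairs, len(tasks) + 1))
        self._log_acc = np.zeros((n_pairs, 2))
        self.skipped = 0
        self.n_records = 0

    # -- indexing -----------------------------------------------------------

    def _pair_index(self, i1: int, i2: int) -> int:
        a, b = min(i1, i2) - 1, max(i1, i2) - 1
        if a < 0 or b >= self.n_roi or a == b:
            raise ValueError(f"invalid ROI pair ({i1}, {i2})")
        return int(pair_rank(np.int64(a), np.int64(b), self.n_roi))

    # -- accumulation -------------------------------------------------------

    def add_record(self, record: ChiSquareRecord) -> None:
        """Accumulate one scored feature (descriptor-level path)."""
        self.n_records += 1
        pair = record.descriptor.roi_pair
        if pair is None:
            self.skipped += 1
            return
        p = self._pair_index(*pair)
        w = record.chi2
        self._pair[p] += w
        self._log_acc[p, int(record.descriptor.log)] += w
        band_idx = {b: i for i, b in enumerate(self.bands)}
        task_idx = {t: i for i, t in enumerate(self.tasks)}
        for c in record.descriptor.constituents:
            bi = band_idx[c.band] if c.band is not None else len(self.bands)
            ti = task_idx[c.task] if c.task is not None else len(self.tasks)
            self._band_acc[p, bi] += w
            self._task_acc[p, ti] += w

    def count_skipped(self, n: int) -> None:
        """Record ``n`` scored features that carry no ROI pair (e.g.
        singleton pass-through columns in the block path)."""
        self.n_records += n
        self.skipped += n

    def add_block(
        self,
        i_idx: np.ndarray,
        j_idx: np.ndarray,
        chi_plain: np.ndarray,
        chi_log: np.ndarray,
    ) -> None:
        """Vectorized accumulation of a product block (stage-1 column
        indices); requires ``stage1_meta`` from
        :func:`neurosym.augment.descriptor_meta`."""
        if self._meta is None:
            raise ValueError("add_block requires stage1_meta")
        roi = self._meta["roi"]
        r1, r2 = roi[i_idx], roi[j_idx]
        ok = (r1 > 0) & (r2 > 0) & (r1 != r2)
        self.n_records += 2 * len(i_idx)
        self.skipped += 2 * int((~ok).sum())
        if not ok.any():
            return
        i_idx, j_idx = i_idx[ok], j_idx[ok]
        wp, wl = chi_plain[ok], chi_log[ok]
        w = wp + wl
        a = np.minimum(r1[ok], r2[ok]) - 1
        b = np.maximum(r1[ok], r2[ok]) - 1
        p = pair_rank(a, b, self.n_roi)
        np.add.at(self._pair, p, w)
        np.add.at(self._log_acc[:, 0], p, wp)
        np.add.at(self._log_acc[:, 1], p, wl)
        nb, nt = len(self.bands), len(self.tasks)
        for side in (i_idx, j_idx):
            bc = self._meta["band"][side].copy()
            bc[bc < 0] = nb
            np.add.at(self._band_acc, (p, bc), w)
            tc = self._meta["task"][side].copy()
            tc[tc < 0] = nt
            np.add.at(self._task_acc, (p, tc), w)

    # -- views --------------------------------------------------------------

    @property
    def matrix(self) -> np.ndarray:
        """Dense symmetric (n_roi x n_roi) strength matrix, zero diagonal."""
        M = np.zeros((self.n_roi, self.n_roi))
        a, b = np.triu_indices(self.n_roi, k=1)
        M[a, b] = self._pair
        M[b, a] = self._pair
        return M

    def pair_strength(self, i1: int, i2: int) -> float:
        return float(self._pair[self._pair_index(i1, i2)])

    def ranked_pairs(self) -> list[tuple[tuple[int, int], float]]:
        """Pairs (1-based ROI ids) by descending strength."""
        a, b = np.triu_indices(self.n_roi, k=1)
        order = np.argsort(-self._pair, kind="stable")
        return [
            ((int(a[o]) + 1, int(b[o]) + 1), float(self._pair[o])) for o in order
        ]

    def _factor_acc(self, factor: str):
        if factor == "band":
            return self._band_acc, list(self.bands)
        if factor == "task":
            return self._task_acc, list(self.tasks)
        if factor == "log":
            return self._log_acc, [0, 1]
        raise ValueError(f"unknown factor {factor!r}")

    def dominant(self, factor: str, *, pair=None, vertex=None):
        """Argmax factor level for a pair or a vertex; see
        :func:`dominant_factor`."""
        acc, levels = self._factor_acc(factor)
        if (pair is None) == (vertex is None):
            raise ValueError("give exactly one of pair= or vertex=")
        if pair is not None:
            row = acc[self._pair_index(*pair)]
        else:
            v = int(vertex) - 1
            a, b = np.triu_indices(self.n_roi, k=1)
            sel = (a == v) | (b == v)
            row = acc[sel].sum(axis=0)
        concrete = row[: len(levels)]  # aggregated level never competes
        if concrete.sum() == 0:
            log.info("dominant %s undetermined (all-zero accumulator)", factor)
            return None
        best = int(np.argmax(concrete))  # first max wins: fixed level order
        if (concrete == concrete[best]).sum() > 1:
            log.info("dominant %s tie broken by level order", factor)
        return levels[best]

    def to_edge_frame(self) -> pd.DataFrame:
        a, b = np.triu_indices(self.n_roi, k=1)
        mask = self._pair > 0
        return pd.DataFrame(
            {"roi_i": a[mask] + 1, "roi_j": b[mask] + 1, "strength": self._pair[mask]}
        )


def accumulate_strengths(
    records: Iterable[ChiSquareRecord],
    n_roi: int,
    bands: tuple[str, ...] = BANDS,
    tasks: tuple[int, ...] = TASKS,
    symptom: str | None = None,
) -> StrengthMatrix:
    """Fold a stream of chi-squared records into a strength matrix."""
    m = StrengthMatrix(n_roi, bands, tasks, symptom)
    for r in records:
        m.add_record(r)
    return m


def vertex_strength(m: StrengthMatrix, roi_id: int) -> float:
    """Total pair strength incident to one ROI (the vertex size of the
    topographical plots): sum_j strength[i, j]."""
    return float(m.matrix[int(roi_id) - 1].sum())


def dominant_factor(m: StrengthMatrix, *, pair=None, vertex=None, factor="band"):
    """Dominant band/task for a pair or vertex: the concrete level with the
    largest accumulated chi-squared mass.  Ties break by fixed level order
    (theta < alpha < beta; tasks 1..5); an all-zero accumulator returns
    ``None`` ("undetermined")."""
    return m.dominant(factor, pair=pair, vertex=vertex)


def build_graph(
    m: StrengthMatrix, threshold: float = 100.0, mode: str = "pair"
) -> nx.Graph:
    """Build the thresholded ROI graph.

    ``mode="pair"`` (primary): edge (i, j) iff ``strength[i, j]`` exceeds
    the threshold.  ``mode="vertex_sum"`` (documented alternative reading of
    the figure captions): edge iff the two endpoint vertex strengths sum
    above the threshold (pairs with zero mass never gain an edge).  Edge
    weight is the pair strength; every ROI is a node, with its vertex
    strength as a node attribute.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    G = nx.Graph()
    M = m.matrix
    vs = M.sum(axis=1)
    for i in range(m.n_roi):
        G.add_node(i + 1, strength=float(vs[i]))
    a, b = np.triu_indices(m.n_roi, k=1)
    for i, j, s in zip(a, b, m._pair):
        if s <= 0:
            continue
        stat = s if mode == "pair" else vs[i] + vs[j]
        if mode not in ("pair", "vertex_sum"):
            raise ValueError(f"unknown mode {mode!r}")
        if stat > threshold:
            G.add_edge(i + 1, j + 1, weight=float(s))
    return G


@dataclass
class CentralityScores:
    """Per-vertex current-flow closeness and betweenness (NaN where
    undefined, i.e. vertices in components of fewer than 2 nodes)."""

    closeness: dict[int, float]
    betweenness: dict[int, float]

    def frame(self, atlas: AtlasMap | None = None) -> pd.DataFrame:
        atlas = atlas or default_atlas()
        ids = sorted(self.closeness)
        return pd.DataFrame(
            {
                "roi_id": ids,
                "name": [
                    atlas.label(i) if i <= len(atlas) else str(i) for i in ids
                ],
                "closeness": [self.closeness[i] for i in ids],
                "betweenness": [self.betweenness[i] for i in ids],
            }
        )


def current_flow_centralities(G: nx.Graph) -> CentralityScores:
    """Current-flow closeness (information centrality) and current-flow
    betweenness, per connected component, edge weights as conductances.

    Closeness follows the information-centrality convention
    ``1 / sum_u R_eff(v, u)`` within the component; betweenness is
    normalized by the ``(n - 1)(n - 2) / 2`` vertex pairs of the component
    (so it lies in [0, 1]).  Vertices in singleton components get NaN; in a
    2-vertex component betweenness is 0 by convention.
    """
    closeness: dict[int, float] = {}
    betweenness: dict[int, float] = {}
    for comp in nx.connected_components(G):
        sub = G.subgraph(comp)
        n = sub.number_of_nodes()
        if n < 2:
            for v in comp:
                closeness[v] = float("nan")
                betweenness[v] = float("nan")
            continue
        cc = nx.current_flow_closeness_centrality(sub, weight="weight")
        closeness.update({v: float(c) for v, c in cc.items()})
        if n == 2:
            for v in comp:
                betweenness[v] = 0.0
        else:
            cb = nx.current_flow_betweenness_centrality(
                sub, normalized=True, weight="weight"
            )
            betweenness.update({v: float(c) for v, c in cb.items()})
    return CentralityScores(closeness, betweenness)


def centrality_table(
    scores: CentralityScores,
    atlas: AtlasMap | None = None,
    top: int = 5,
) -> pd.DataFrame:
    """Top ROIs by each centrality, shaped like the published hub tables
    (roi id, name, closeness, betweenness)."""
    df = scores.frame(atlas)
    by_close = df.dropna(subset=["closeness"]).nlargest(top, "closeness")
    by_betw = df.dropna(subset=["betweenness"]).nlargest(top, "betweenness")
    out = (
        pd.concat([by_close, by_betw])
        .drop_duplicates("roi_id")
        .reset_index(drop=True)
    )
    return out.sort_values("closeness", ascending=False).reset_index(drop=True)


def plot_strength_topography(
    m: StrengthMatrix,
    threshold: float = 100.0,
    atlas: AtlasMap | None = None,
    ax=None,
):
    """Schematic topographical plot of the thresholded hub graph (vertex
    size ~ vertex strength; left/right hemisphere columns, regions in
    alphabetical order).  Convenience only."""
    import matplotlib.pyplot as plt

    atlas = atlas or default_atlas()
    G = build_graph(m, threshold)
    pos = {}
    for roi_id in G.nodes:
        region, hemi = atlas[roi_id] if roi_id <= len(atlas) else (str(roi_id), "L")
        row = (roi_id - 1) // 2
        pos[roi_id] = (-1.0 if hemi == "L" else 1.0, -row)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 10))
    vs = np.array([G.nodes[v]["strength"] for v in G.nodes])
    scale = vs.max() if vs.max() > 0 else 1.0
    nx.draw_networkx(
        G,
        pos=pos,
        ax=ax,
        with_labels=False,
        node_size=50 + 450 * vs / scale,
        node_color="tab:blue",
        edge_color="0.6",
    )
    ax.set_axis_off()
    return ax
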