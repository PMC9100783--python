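"""End-to-end orchestration: run the stages on a cohort and write the
artifact directory (delimited tables + a machine-readable run manifest)."""

from __future__ import annotations

import json
import platform
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineParams, canonical_variant
from .data import SYMPTOMS, CohortDataset
from .evaluate import permutation_null
from .model import HubAnalysis, SymptomClassifier

__all__ = ["run_all"]


def _versions() -> dict[str, str]:
    import networkx
    import scipy
    import sklearn

    return {
        "python": platform.python_version(),
        "neurosym": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "networkx": networkx.__version__,
    }


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_all(
    dataset: CohortDataset,
    out_dir: str | Path,
    *,
    symptoms: tuple[str, ...] = SYMPTOMS,
    variants: tuple[str, ...] = ("original", "da_fs_os"),
    params: PipelineParams | None = None,
    seed: int = 0,
    with_null: bool = False,
    log=lambda msg: print(msg, file=sys.stderr),
) -> Path:
    """Run CV evaluation (all requested variants), optional permutation
    nulls, and the hub-graph analysis for each symptom; write every result
    table plus the run manifest under ``out_dir``.

    Identical dataset + params + seed produce byte-identical outputs.
    """
    params = params or PipelineParams()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    variants = tuple(canonical_variant(v) for v in variants)

    cv_rows, null_rows = [], []
    for symptom in symptoms:
        for variant in variants:
            t0 = time.perf_counter()
            res = SymptomClassifier(dataset, symptom, variant, params).fit(seed)
            cv_rows.append(res.cv.summary_frame())
            if res.selection is not None:
                _write(res.selection, out / f"topk_{symptom}.tsv")
            log(
                f"[evaluate] {symptom}/{variant}: accuracy "
                f"{res.accuracy:.3f} ({time.perf_counter() - t0:.1f}s)"
            )
            if with_null:
                t0 = time.perf_counter()
                null = permutation_null(
                    dataset,
                    symptom,
                    variant,
                    n_perm=params.null_permutations,
                    folds=params.folds,
                    repeats=params.null_repeats,
                    seed=seed,
                    params=params,
                )
                null_rows.append(
                    pd.DataFrame(
                        {
                            "symptom": symptom,
                            "variant": variant,
                            "permutation": np.arange(1, null.n_permutations + 1),
                            "mean_accuracy": null.accuracies,
                        }
                    )
                )
                log(
                    f"[permute] {symptom}/{variant}: 95th pct "
                    f"{null.p95:.3f} ({time.perf_counter() - t0:.1f}s)"
                )

        t0 = time.perf_counter()
        hub = HubAnalysis(dataset, symptom, params).fit()
        _write(hub.strength.to_edge_frame(), out / f"strength_{symptom}.tsv")
        _write(
            hub.centralities.frame(dataset.atlas),
            out / f"centralities_{symptom}.tsv",
        )
        _write(hub.dominance_frame(top=20), out / f"dominance_{symptom}.tsv")
        edges = pd.DataFrame(
            [
                {"roi_i": u, "roi_j": v, "strength": d["weight"]}
                for u, v, d in hub.graph.edges(data=True)
            ],
            columns=["roi_i", "roi_j", "strength"],
        )
        _write(edges, out / f"graph_edges_{symptom}.tsv")
        log(
            f"[hubs] {symptom}: {hub.graph.number_of_edges()} edges "
            f"({time.perf_counter() - t0:.1f}s)"
        )

    _write(pd.concat(cv_rows, ignore_index=True), out / "cv_results.tsv")
    if null_rows:
        _write(pd.concat(null_rows, ignore_index=True), out / "null_results.tsv")

    params.to_yaml(out / "params.yaml")
    manifest = {
        "seed": seed,
        "symptoms": list(symptoms),
        "variants": list(variants),
        "n_subjects": dataset.n_subjects,
        "tensor_shape": list(dataset.shape),
        "params": params.to_dict(),
        "versions": _versions(),
    }
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return out
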