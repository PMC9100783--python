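"""Pipeline parameters shared by the model classes and the CLI."""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

__all__ = ["PipelineParams", "VARIANTS", "canonical_variant"]

#: Pipeline variants: raw 1020-dimensional features; oversampled raw
#: features; data augmentation + chi-squared feature selection + oversampling.
VARIANTS: tuple[str, ...] = ("original", "os", "da_fs_os")

_VARIANT_ALIASES = {
    "original": "original",
    "os": "os",
    "da_fs_os": "da_fs_os",
    "da+fs+os": "da_fs_os",
    "dafsos": "da_fs_os",
}


def canonical_variant(name: str) -> str:
    key = str(name).strip().lower().replace(" ", "")
    if key not in _VARIANT_ALIASES:
        raise ValueError(f"unknown variant {name!r}; expected one of {VARIANTS}")
    return _VARIANT_ALIASES[key]


@dataclass(frozen=True)
class PipelineParams:
    """Everything tunable about the analysis, validated up front.

    ``leakage_mode``: ``"fold_safe"`` (default) fits selection and
    calibration on training folds only; ``"paper_faithful"`` computes them
    on the whole cohort before splitting, matching the description of the
    reference analysis.
    """

    label_threshold: int = 5
    k: int = 40_000
    lam: float = 1.0
    folds: int = 5
    repeats: int = 5
    smote_k: int = 5
    gaussian_factor: int = 9
    gaussian_scale: float = 1.0 / 100.0
    oversample_order: str = "smote_then_gaussian"
    strength_threshold: float = 100.0
    leakage_mode: str = "fold_safe"
    nonneg: str = "auto"
    block_size: int = 20_000
    fit_intercept: bool = True
    null_permutations: int = 100
    null_repeats: int = 1

    def __post_init__(self):
        if self.label_threshold < 0:
            raise ValueError("label_threshold must be >= 0")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if self.folds < 2 or self.repeats < 1:
            raise ValueError("need folds >= 2 and repeats >= 1")
        if self.leakage_mode not in ("fold_safe", "paper_faithful"):
            raise ValueError("leakage_mode must be fold_safe or paper_faithful")
        if self.nonneg not in ("auto", "always", "off"):
            raise ValueError("nonneg must be auto, always or off")
        if self.gaussian_factor < 0 or self.gaussian_scale <= 0:
            raise ValueError("invalid Gaussian oversampling parameters")
        if self.null_permutations < 1 or self.null_repeats < 1:
            raise ValueError("invalid permutation-null parameters")

    def to_dict(self) -> dict:
        return asdict(self)

    def updated(self, **kwargs) -> "PipelineParams":
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineParams":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8"
        )
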