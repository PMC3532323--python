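"""Pipeline configuration with lossless YAML round-tripping.

Defaults follow the study design the pipeline implements: 5% control-variance
gene filter, 20-fold cross-validation for the ridge grid, 1000 permutations
for component significance and target resampling, p < 0.05 retention, top-20
compounds / top-10 gene sets per component.  Synthetic-stage sizes default to
a desk-scale study.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .io import ParameterError

__all__ = ["PipelineConfig"]

DEFAULT_GRID = [[10.0**i, 10.0**j] for i in range(-3, 4) for j in range(-3, 4)]


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "chemcca_run"

    # stage toggles
    run_synth: bool = True
    run_retrieval: bool = True
    run_characterize: bool = True

    # input paths (used when run_synth is False)
    descriptors_path: str | None = None
    expression_path: str | None = None
    gene_sets_path: str | None = None
    annotations_path: str | None = None

    # synthetic study
    n_compounds: int = 60
    n_genes: int = 600
    n_sets: int = 30
    n_descriptors: int = 20
    latent_k: int = 3
    planted_correlations: list[float] = field(default_factory=lambda: [0.9, 0.8, 0.7])
    batches: int = 6
    controls_per_batch: int = 3
    noise_sd: float = 0.5
    effect_scale: float = 1.5
    outlier_shift: float = 20.0
    n_labels: int = 5
    alignment: float = 0.9

    # preprocessing / enrichment
    variance_fraction: float = 0.05
    gsea_n_perm: int = 200

    # model
    folds: int = 20
    grid: list[list[float]] = field(default_factory=lambda: [list(g) for g in DEFAULT_GRID])
    n_components: int | None = None
    n_perm: int = 1000
    p_threshold: float = 0.05
    top_components: int = 10
    score_side: str = "mean"

    # reporting
    k_sets: int = 10
    k_compounds: int = 20
    retrieval_ks: list[int] = field(default_factory=lambda: list(range(5, 101, 5)))
    target_draws: int = 1000

    def validate(self) -> None:
        if not 0 <= self.variance_fraction < 1:
            raise ParameterError("variance_fraction must lie in [0, 1)")
        if self.folds < 2:
            raise ParameterError("folds must be >= 2")
        if self.run_retrieval and not self.run_synth and self.annotations_path is None:
            raise ParameterError("retrieval stage enabled but no annotations provided")
        if not self.run_synth:
            missing = [
                name
                for name, path in (
                    ("descriptors_path", self.descriptors_path),
                    ("expression_path", self.expression_path),
                    ("gene_sets_path", self.gene_sets_path),
                )
                if path is None
            ]
            if missing:
                raise ParameterError(f"synth disabled but inputs missing: {', '.join(missing)}")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
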