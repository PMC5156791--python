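"""Run configuration: one flat key-value schema for the whole pipeline.

Every stage parameter has a documented default; unknown keys are rejected
before any computation; a config round-trips through YAML unchanged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .data_io import ValidationError
from . import synthetic_data as syn


@dataclass
class RunConfig:
    """Parameters for a full pipeline run.

    When ``simulate`` is true the five input files are generated under the
    output directory from the synthetic-data defaults; otherwise the
    ``*_path`` entries must point at existing files.
    """

    # orchestration
    out_dir: str = "mirpoma_run"
    seed: int = 0
    label: str = "disease"
    log_level: str = "INFO"
    simulate: bool = True

    # input files (used when simulate is false)
    matrix_path: str | None = None
    groups_path: str | None = None
    network_path: str | None = None
    tf_path: str | None = None
    gmt_path: str | None = None
    reported_path: str | None = None
    truth_path: str | None = None

    # simulation parameters (see synthetic_data.DEFAULTS)
    n_mirna: int = syn.DEFAULTS["n_mirna"]
    n_gene: int = syn.DEFAULTS["n_gene"]
    tf_fraction: float = syn.DEFAULTS["tf_fraction"]
    mean_out_degree: float = syn.DEFAULTS["mean_out_degree"]
    n_planted: int = syn.DEFAULTS["n_planted"]
    private_targets_per_planted: int = syn.DEFAULTS["private_targets_per_planted"]
    planted_tf_boost: float = syn.DEFAULTS["planted_tf_boost"]
    n_control: int = syn.DEFAULTS["n_control"]
    n_case: int = syn.DEFAULTS["n_case"]
    de_fraction: float = syn.DEFAULTS["de_fraction"]
    lfc_magnitude: float = syn.DEFAULTS["lfc_magnitude"]
    d0: float = syn.DEFAULTS["d0"]
    s0sq: float = syn.DEFAULTS["s0sq"]
    n_gene_sets: int = 50
    gene_set_size_low: int = 20
    gene_set_size_high: int = 60
    enrichment_strength: float = 0.8

    # analysis parameters
    de_alpha: float = 0.05
    selection_alpha: float = 0.05
    selection_mode: str = "signed-rank"  # or "permutation"
    perm_iters: int = 1000
    enrich_alpha: float = 0.05
    universe: str = "network"  # or "gmt-union"
    coverage_target_mode: str = "unique"  # or "all"

    def __post_init__(self) -> None:
        if self.selection_mode not in {"signed-rank", "permutation"}:
            raise ValidationError(f"unknown selection_mode {self.selection_mode!r}")
        if self.universe not in {"network", "gmt-union"}:
            raise ValidationError(f"unknown universe {self.universe!r}")
        if self.coverage_target_mode not in {"unique", "all"}:
            raise ValidationError(f"unknown coverage_target_mode {self.coverage_target_mode!r}")
        if not self.simulate:
            for key in ("matrix_path", "groups_path", "network_path"):
                if getattr(self, key) is None:
                    raise ValidationError(f"simulate=false requires {key}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8"
        )
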