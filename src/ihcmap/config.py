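"""Run configuration for the command-line pipeline (YAML, validated)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .catalog import MARKER_PALETTE, MARKERS
from .ihc import MarkerConfig
from .pipeline import AnalysisConfig


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    workspace: Path
    seed: int = 0
    cohort: dict[str, int] = field(
        default_factory=lambda: {"Control": 2, "Klf5-like": 2, "DSS-like": 2}
    )
    markers: dict[str, MarkerConfig] = field(
        default_factory=lambda: {m: MarkerConfig(m) for m in MARKERS}
    )
    qc_threshold: float = 0.80
    pca_components: int = 32
    model_seed: int = 0
    grid2d: bool = False
    equal_var: bool = False
    save_images: bool = True
    palette: dict[str, tuple] = field(default_factory=lambda: dict(MARKER_PALETTE))
    layout: dict = field(default_factory=dict)
    max_step_rotation: float = 4.0
    max_step_translation: float = 20.0

    def validate(self) -> None:
        if not isinstance(self.seed, int) or not isinstance(self.model_seed, int):
            raise ConfigError("seeds must be integers")
        for m in MARKERS:
            if m not in self.markers:
                raise ConfigError(f"missing marker configuration for {m}")
            if m not in self.palette:
                raise ConfigError(f"palette has no color for marker {m}")
        if not 0 <= self.qc_threshold <= 1:
            raise ConfigError("qc_threshold must lie in [0, 1]")
        for cond, n in self.cohort.items():
            if n < 1:
                raise ConfigError(f"cohort size for {cond} must be >= 1")

    def analysis_config(self) -> AnalysisConfig:
        return AnalysisConfig(
            marker_configs=self.markers,
            qc_threshold=self.qc_threshold,
            pca_components=self.pca_components,
            model_seed=self.model_seed,
            grid2d=self.grid2d,
            equal_var=self.equal_var,
        )


def load_config(path: str | Path | None, workspace: str | Path, seed: int | None = None) -> RunConfig:
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
    markers = {m: MarkerConfig(m) for m in MARKERS}
    for name, params in (data.get("markers") or {}).items():
        try:
            markers[name] = MarkerConfig(name, **(params or {}))
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid marker config for {name}: {exc}") from exc
    cfg = RunConfig(
        workspace=Path(workspace),
        seed=int(data.get("seed", 0)) if seed is None else int(seed),
        cohort=data.get("cohort", {"Control": 2, "Klf5-like": 2, "DSS-like": 2}),
        markers=markers,
        qc_threshold=float(data.get("qc_threshold", 0.80)),
        pca_components=int(data.get("pca_components", 32)),
        model_seed=int(data.get("model_seed", 0)),
        grid2d=bool(data.get("grid2d", False)),
        equal_var=bool(data.get("equal_var", False)),
        save_images=bool(data.get("save_images", True)),
        palette={**MARKER_PALETTE, **{k: tuple(v) for k, v in (data.get("palette") or {}).items()}},
        layout=data.get("layout", {}) or {},
        max_step_rotation=float(data.get("max_step_rotation", 4.0)),
        max_step_translation=float(data.get("max_step_translation", 20.0)),
    )
    cfg.validate()
    return cfg
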