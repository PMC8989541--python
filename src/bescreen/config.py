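"""Run configuration: a YAML-loadable tree of every pipeline constant.

Each threshold defaults to its published value (min 100 reads per sample,
alignment gaps -1/-0.1 with match threshold 50, 20%-of-max window, 90/10
split, 100 trees of depth 4 with learning rate 0.1, downsampling fractions
80/50/25/10% at 100 repetitions) and every output carries the config hash
so artifacts from different configurations cannot be mixed silently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .simulate import SimTruth


@dataclass
class LibraryConfig:
    n_guides: int = 2000
    force_g: bool = True
    upstream_context: int = 10
    editor_label: str = "CBE"


@dataclass
class ScreenConfig:
    n_samples: int = 2
    match_assay_reads_per_guide: int = 150
    use_alignment_match_stats: bool = True


@dataclass
class FilterConfig:
    min_reads: int = 100


@dataclass
class AlignmentConfig:
    gap_open: float = -1.0
    gap_extend: float = -0.1
    match_threshold: float = 50.0


@dataclass
class BiasConfig:
    window_threshold: float = 0.2
    n_boot: int = 1000
    min_stratum: int = 20


@dataclass
class ModelConfig:
    train_frac: float = 0.9
    n_estimators: int = 100
    max_depth: int = 4
    min_samples_leaf: int = 2
    learning_rate: float = 0.1
    min_training_rows: int = 50


@dataclass
class DownsampleConfig:
    fractions: tuple = (0.8, 0.5, 0.25, 0.1)
    n_reps: int = 100
    position: int | str = 6


@dataclass
class ScalingConfig:
    anchor_mean: float = 0.5
    anchor_sd: float = 0.2
    scaling: dict = field(
        default_factory=lambda: {
            3: 0.30, 4: 0.55, 5: 0.85, 6: 1.0, 7: 0.85, 8: 0.55, 9: 0.30, 10: 0.15,
        }
    )


@dataclass
class RunConfig:
    seed: int = 1
    library: LibraryConfig = field(default_factory=LibraryConfig)
    truth: SimTruth = field(default_factory=SimTruth)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    alignment: AlignmentConfig = field(default_factory=AlignmentConfig)
    bias: BiasConfig = field(default_factory=BiasConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    downsample: DownsampleConfig = field(default_factory=DownsampleConfig)
    scaling: ScalingConfig = field(default_factory=ScalingConfig)

    def validate(self) -> None:
        if self.library.n_guides < 1:
            raise ValueError("n_guides must be >= 1")
        if not 0 < self.model.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")
        if self.filters.min_reads < 0:
            raise ValueError("min_reads must be >= 0")
        if not 0 < self.bias.window_threshold < 1:
            raise ValueError("window threshold must be in (0, 1)")
        self.truth.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["truth"] = self.truth.to_dict()
        d["downsample"]["fractions"] = list(self.downsample.fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kwargs = {"seed": int(d.get("seed", 1))}
        sections = {
            "library": LibraryConfig,
            "screen": ScreenConfig,
            "filters": FilterConfig,
            "alignment": AlignmentConfig,
            "bias": BiasConfig,
            "model": ModelConfig,
            "downsample": DownsampleConfig,
            "scaling": ScalingConfig,
        }
        for name, typ in sections.items():
            if name in d and d[name] is not None:
                section = dict(d[name])
                if name == "downsample" and "fractions" in section:
                    section["fractions"] = tuple(section["fractions"])
                if name == "scaling" and "scaling" in section:
                    section["scaling"] = {
                        int(k): float(v) for k, v in section["scaling"].items()
                    }
                kwargs[name] = typ(**section)
        if "truth" in d and d["truth"] is not None:
            kwargs["truth"] = SimTruth.from_dict(d["truth"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        """Stable short hash of the full configuration."""
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
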