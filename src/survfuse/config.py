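"""Pipeline configuration: YAML in, validated dataclasses out.

Unknown keys are rejected loudly — a typo in a config must fail pre-flight,
not silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

from .classify import ClassifierSpec
from .containers import ConfigError
from .preprocess import PreprocessConfig
from .synthetic import SimConfig
from .vae import VAEConfig
from .wsi import WsiConfig


def _build(cls, data: dict | None, where: str):
    data = dict(data or {})
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")
    return cls(**data)


@dataclass
class ReducerConfig:
    pca_variance: float = 0.95
    fit_scope: str = "full"
    vae: dict = field(default_factory=dict)  # global VAEConfig overrides
    vae_per_modality: dict = field(default_factory=dict)  # tag -> overrides

    def __post_init__(self) -> None:
        if self.fit_scope not in ("full", "per-fold"):
            raise ConfigError(f"fit_scope must be 'full' or 'per-fold', got {self.fit_scope!r}")

    def vae_config(self, tag: str, seed: int) -> VAEConfig:
        from .vae import default_vae_config

        overrides = {**self.vae, **self.vae_per_modality.get(tag, {})}
        overrides.setdefault("seed", seed)
        return default_vae_config(tag, **overrides)


@dataclass
class AblationBlock:
    feature_kinds: tuple[str, ...] = ("raw", "pca", "vae")
    classifiers: tuple[str, ...] = (
        "rbf_svm",
        "linear_svm",
        "polynomial_svm",
        "sigmoid_svm",
        "random_forest",
    )
    min_arity: int = 1
    max_arity: int | None = None


@dataclass
class ProtocolBlock:
    n_folds: int = 10
    seed: int = 0
    cutoff_months: float = 60.0
    censored_policy: str = "exclude"


@dataclass
class PipelineConfig:
    simulation: SimConfig | None = None
    paths: dict = field(default_factory=dict)  # modality/survival/wsi -> file
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    wsi: WsiConfig = field(default_factory=WsiConfig)
    reducer: ReducerConfig = field(default_factory=ReducerConfig)
    protocol: ProtocolBlock = field(default_factory=ProtocolBlock)
    ablation: AblationBlock = field(default_factory=AblationBlock)

    def classifier_specs(self) -> list[ClassifierSpec]:
        return [ClassifierSpec(kind=k, seed=self.protocol.seed) for k in self.ablation.classifiers]

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        allowed = {f.name for f in fields(cls)}
        unknown = set(data) - allowed
        if unknown:
            raise ConfigError(f"pipeline config: unknown keys {sorted(unknown)}")
        out = cls(
            simulation=_build(SimConfig, data["simulation"], "simulation")
            if data.get("simulation") is not None
            else None,
            paths=dict(data.get("paths") or {}),
            preprocess=_build(PreprocessConfig, data.get("preprocess"), "preprocess"),
            wsi=_build(WsiConfig, data.get("wsi"), "wsi"),
            reducer=_build(ReducerConfig, data.get("reducer"), "reducer"),
            protocol=_build(ProtocolBlock, data.get("protocol"), "protocol"),
            ablation=_build(AblationBlock, data.get("ablation"), "ablation"),
        )
        if isinstance(out.preprocess.top_k_modalities, list):
            out.preprocess.top_k_modalities = tuple(out.preprocess.top_k_modalities)
        if isinstance(out.ablation.feature_kinds, list):
            out.ablation.feature_kinds = tuple(out.ablation.feature_kinds)
        if isinstance(out.ablation.classifiers, list):
            out.ablation.classifiers = tuple(out.ablation.classifiers)
        return out

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
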