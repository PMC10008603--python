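"""The package's reference synthetic study.

A fixed, reproducible study at desk scale: a 600-patient cohort with the six
modality views at reduced dimensionality (copy number / methylation / mRNA
150 features, miRNA 80, clinical 21, WSI 8 patches x 32 dims), preprocessed
exactly as the real pipeline would be, with the VAE feature pathway and a
random-forest classifier evaluated over all 63 modality combinations.  The
stability analysis — how the across-combination spread of the metrics
shrinks as modalities are added — is computed from the resulting report.
"""

from __future__ import annotations

import pandas as pd

from .ablation import AblationReport, ProtocolConfig, aggregate_by_arity, run_ablation
from .classify import ClassifierSpec
from .config import PipelineConfig
from .pipeline import load_dataset, prepare_dataset


def reference_study_config(
    seed: int, effect_size: float = 3.0, prevalence: float = 0.77
) -> PipelineConfig:
    """Study conditions: n=600, shared-signal delta, unit observation noise."""
    return PipelineConfig.from_dict(
        {
            "simulation": {
                "n_patients": 600,
                "prevalence": prevalence,
                "effect_size": effect_size,
                "noise_sd": 1.0,
                "n_features": {"cln": 21, "cnv": 150, "dna": 150, "mir": 80, "mrna": 150},
                "wsi_patches": 8,
                "wsi_dim": 32,
                "seed": seed,
            },
            "preprocess": {"top_k": 100},
            "wsi": {"fraction": 0.5, "cap": 4, "patch_dim": 16, "final_dim": 32},
            "reducer": {
                "vae": {
                    "epochs": 60,
                    "hidden_widths": [64],
                    "learning_rate": 3e-3,
                    "patience": 15,
                }
            },
            "protocol": {"seed": seed},
        }
    )


def run_reference_ablation(
    seed: int,
    effect_size: float = 3.0,
    prevalence: float = 0.77,
    min_arity: int = 1,
    max_arity: int | None = None,
) -> tuple[AblationReport, pd.DataFrame]:
    """Simulate, preprocess and ablate (VAE pathway, random forest).

    Returns the full record-level report and its per-arity aggregation.
    """
    cfg = reference_study_config(seed, effect_size=effect_size, prevalence=prevalence)
    prepared, _ = prepare_dataset(load_dataset(cfg), cfg)
    protocol = ProtocolConfig(seed=seed, pca_variance=cfg.reducer.pca_variance)
    vae_configs = {t: cfg.reducer.vae_config(t, seed) for t in prepared.modalities}
    report = run_ablation(
        prepared,
        feature_kinds=("vae",),
        classifier_specs=[ClassifierSpec(kind="random_forest", seed=seed)],
        protocol=protocol,
        vae_configs=vae_configs,
        min_arity=min_arity,
        max_arity=max_arity,
    )
    return report, aggregate_by_arity(report)
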