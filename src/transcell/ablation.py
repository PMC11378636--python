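"""Encoder-variant ablation: two_step vs target_only vs source_only.

Reproduces, on the synthetic paired domains, the encoder comparison that
motivates the transfer design: at an equal target-phase epoch budget the
two-step encoder should reconstruct held-out target samples better AND
yield higher downstream test Spearman than both a no-transfer target
encoder and a source-only encoder.

The downstream comparison freezes each encoder and trains only the
prediction head, so it measures representation quality — the property the
ablation varies — rather than what end-to-end fine-tuning can recover on
top of any initialization.  Production models fine-tune all layers.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .containers import align_task
from .evaluation import spearman
from .feature_selection import select_similar_genes
from .networks import (
    AutoencoderSpec,
    AutoencoderWeights,
    EncoderState,
    TrainConfig,
    build_predictor,
    fit_predictor,
    predict,
    train_autoencoder,
    transfer_encoder_weights,
    validation_reconstruction_loss,
)
from .synthetic import SyntheticConfig, generate_domains

VARIANTS = ("two_step", "target_only", "source_only")


def _two_step_autoencoder(
    source_ae: AutoencoderWeights,
    target_X,
    spec: AutoencoderSpec,
    cfg: TrainConfig,
    warmup_fraction: float = 0.25,
) -> AutoencoderWeights:
    """The target phase of the two-step procedure, keeping the full
    autoencoder (same schedule and seeds as :func:`two_step_pretrain`)."""
    init = transfer_encoder_weights(source_ae, spec, seed=cfg.seed + 1)
    warm = int(round(cfg.epochs * warmup_fraction))
    if warm:
        init = train_autoencoder(
            target_X,
            spec,
            init=init,
            config=dataclasses.replace(cfg, epochs=warm),
            phase="target_warmup",
            freeze_encoder=True,
        )
    return train_autoencoder(
        target_X,
        spec,
        init=init,
        config=dataclasses.replace(cfg, epochs=cfg.epochs - warm, seed=cfg.seed + 1),
        phase="target",
    )


def compare_encoder_variants(
    seeds=range(5),
    synthetic_config: SyntheticConfig | None = None,
    hidden_dim: int = 64,
    bottleneck_dim: int = 16,
    ae_epochs: int = 60,
    head_epochs: int = 60,
    head_hidden=(32, 16),
    n_features: int = 10,
    n_val: int = 50,
    n_task_train: int = 50,
) -> pd.DataFrame:
    """Run the three-variant ablation across seeds.

    Per seed: generate a paired study, KS-select the non-shifted gene
    budget, train the three encoders at equal target epoch budgets, then
    score each on (a) reconstruction loss over held-out target samples and
    (b) mean downstream test Spearman over ``n_features`` continuous
    features with a frozen-encoder head trained on ``n_task_train``
    samples.  Returns one row per (seed, variant).
    """
    base = synthetic_config or SyntheticConfig()
    rows = []
    for seed in seeds:
        cfg = SyntheticConfig(**{**dataclasses.asdict(base), "seed": int(seed)})
        data = generate_domains(cfg)
        k = cfg.n_genes - cfg.n_shifted_genes
        selection = select_similar_genes(data.source, data.target, k=k)
        genes = selection.selected
        Xs = data.source.subset_genes(genes).values
        Xt = data.target.subset_genes(genes).values

        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(Xt))
        val, tr_ae = perm[:n_val], perm[n_val:]
        tr_task = perm[n_val : n_val + n_task_train]
        te_task = perm[n_val + n_task_train :]

        # fixed-budget comparison: early stopping off so every variant
        # consumes exactly the same number of gradient epochs
        spec = AutoencoderSpec(len(genes), hidden_dim, bottleneck_dim)
        train_cfg = TrainConfig(epochs=ae_epochs, seed=int(seed), patience=None)
        source_ae = train_autoencoder(Xs, spec, config=train_cfg, phase="source")
        target_ae = train_autoencoder(Xt[tr_ae], spec, config=train_cfg, phase="target_only")
        two_step_ae = _two_step_autoencoder(source_ae, Xt[tr_ae], spec, train_cfg)

        autoencoders = {
            "two_step": two_step_ae,
            "target_only": target_ae,
            "source_only": source_ae,
        }
        feature_ids = data.measurements.feature_ids[:n_features]
        for variant, ae in autoencoders.items():
            encoder = EncoderState(spec, ae.encoder_layers, variant, selected_genes=genes)
            rhos = []
            for fid in feature_ids:
                task = align_task(data.target, data.measurements, fid, genes)
                state = build_predictor(
                    encoder, "regression", {"hidden": tuple(head_hidden), "seed": int(seed)}
                )
                state = fit_predictor(
                    state,
                    task.X[tr_task],
                    task.y[tr_task],
                    config=TrainConfig(epochs=head_epochs, seed=int(seed), patience=None),
                    freeze_encoder=True,
                )
                rhos.append(spearman(task.y[te_task], predict(state, task.X[te_task])))
            rows.append(
                {
                    "seed": int(seed),
                    "variant": variant,
                    "target_val_recon_loss": validation_reconstruction_loss(ae, Xt[val]),
                    "downstream_spearman": float(np.mean(rhos)),
                }
            )
    return pd.DataFrame(rows)


def summarize_ablation(table: pd.DataFrame) -> pd.DataFrame:
    """Mean metrics per variant plus pairwise sign counts against two_step."""
    summary = table.groupby("variant")[["target_val_recon_loss", "downstream_spearman"]].mean()
    wide_loss = table.pivot(index="seed", columns="variant", values="target_val_recon_loss")
    wide_rho = table.pivot(index="seed", columns="variant", values="downstream_spearman")
    for other in ("target_only", "source_only"):
        summary.loc[other, "loss_wins_vs_two_step"] = int(
            (wide_loss["two_step"] < wide_loss[other]).sum()
        )
        summary.loc[other, "rho_wins_vs_two_step"] = int(
            (wide_rho["two_step"] > wide_rho[other]).sum()
        )
    return summary
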