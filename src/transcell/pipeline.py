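"""End-to-end pipeline: simulate -> select-features -> pretrain -> train ->
evaluate -> screen, with a manifest, a per-feature model registry, and
ensemble prediction.

The registry keeps one weight file per (feature, CV fold): five models per
feature, whose averaged prediction is what gets served.  Mutation features
whose cross-validated macro F1 does not exceed the gate (0.7 by default)
are excluded from the served set.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tc_io
from .containers import align_task
from .evaluation import build_benchmark_table, kfold_split, run_cv, subsample_features
from .feature_selection import select_similar_genes
from .networks import (
    AutoencoderSpec,
    TrainConfig,
    TransCellClassifier,
    TransCellRegressor,
    make_encoder_variant,
)
from .screening import ScreenMatrix, drug_selectivity
from .synthetic import SyntheticConfig, generate_domains

logger = logging.getLogger("transcell")

STAGES = ("simulate", "select_features", "pretrain", "train", "evaluate", "screen")


class PipelineError(RuntimeError):
    """A stage failed; the stage name is recorded in the manifest."""


@dataclass
class RunConfig:
    """Everything one pipeline run needs; round-trips through YAML/JSON."""

    out_dir: str = "run"
    seed: int = 0
    k_genes: int = 250
    encoder_variant: str = "two_step"
    hidden_dim: int = 64
    bottleneck_dim: int = 16
    head_hidden: tuple = (32, 16)
    epochs: int = 40
    batch_size: int = 32
    lr: float = 1e-3
    patience: int | None = 10
    cv_folds: int = 5
    feature_cap: int = 2000
    n_features_to_train: int = 2
    n_mutations_to_train: int = 1
    f1_gate: float = 0.7
    screen_threshold: float = -2.0
    synthetic: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            data = yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") else json.load(fh)
        cfg = cls(**data)
        cfg.head_hidden = tuple(cfg.head_hidden)
        return cfg

    def to_file(self, path) -> None:
        data = asdict(self)
        data["head_hidden"] = list(self.head_hidden)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def train_config(self, offset: int = 0) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            lr=self.lr,
            patience=self.patience,
            seed=self.seed + offset,
        )


def count_models(feature_counts, replicates_per_feature: int) -> int:
    """Registry arithmetic: (sum of per-type feature counts) x replicates."""
    counts = list(feature_counts)
    if any(int(c) != c or c < 0 for c in counts):
        raise ValueError("feature counts must be non-negative integers")
    if replicates_per_feature < 1:
        raise ValueError("replicates_per_feature must be positive")
    return int(sum(int(c) for c in counts) * replicates_per_feature)


def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class Pipeline:
    """Stage runner with manifest-driven resumability."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.manifest = self._load_manifest()

    def _load_manifest(self) -> dict:
        if self.manifest_path.exists():
            with open(self.manifest_path) as fh:
                return json.load(fh)
        cfg = asdict(self.config)
        cfg["head_hidden"] = list(self.config.head_hidden)
        return {
            "config": cfg,
            "config_hash": hashlib.sha256(
                json.dumps(cfg, sort_keys=True).encode()
            ).hexdigest(),
            "stages": {},
        }

    def _save_manifest(self) -> None:
        with open(self.manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=2)

    def _stage_done(self, name: str) -> bool:
        entry = self.manifest["stages"].get(name)
        if not entry or entry.get("status") != "completed":
            return False
        for rel, digest in entry.get("outputs", {}).items():
            p = self.out / rel
            if not p.exists() or _file_hash(p) != digest:
                return False
        return True

    def _record(self, name: str, outputs: list, seed: int | None = None) -> None:
        self.manifest["stages"][name] = {
            "status": "completed",
            "seed": seed,
            "outputs": {str(p.relative_to(self.out)): _file_hash(p) for p in outputs},
        }
        self._save_manifest()

    def run(self, stages=STAGES) -> Path:
        for name in stages:
            if self._stage_done(name):
                logger.info("stage %s already completed; skipping", name)
                continue
            logger.info("running stage %s", name)
            try:
                getattr(self, f"_stage_{name}")()
            except Exception as exc:
                self.manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                self._save_manifest()
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return self.out

    # -- stages ----------------------------------------------------------
    def _stage_simulate(self) -> None:
        cfg = SyntheticConfig(**{"seed": self.config.seed, **self.config.synthetic})
        data = generate_domains(cfg)
        tc_io.write_expression(data.source, self.out / "source.tsv")
        tc_io.write_expression(data.target, self.out / "target.tsv")
        tc_io.write_measurements(data.measurements, self.out / "measurements.tsv")
        tc_io.write_measurements(data.mutations, self.out / "mutations.tsv")
        groups = pd.DataFrame(
            {"sample_id": data.target.sample_ids, "group": data.group_labels}
        )
        groups.to_csv(self.out / "groups.tsv", sep="\t", index=False)
        with open(self.out / "truth.json", "w") as fh:
            json.dump(
                {
                    "shifted_genes": data.truth["shifted_genes"],
                    "config": data.truth["config"],
                },
                fh,
                indent=2,
            )
        self._record(
            "simulate",
            [
                self.out / n
                for n in (
                    "source.tsv",
                    "target.tsv",
                    "measurements.tsv",
                    "mutations.tsv",
                    "groups.tsv",
                    "truth.json",
                )
            ],
            seed=cfg.seed,
        )

    def _stage_select_features(self) -> None:
        source = tc_io.read_expression(self.out / "source.tsv", orientation="samples")
        target = tc_io.read_expression(self.out / "target.tsv", orientation="samples")
        result = select_similar_genes(source, target, k=self.config.k_genes)
        result.to_frame().to_csv(self.out / "selected.tsv", sep="\t", index=False)
        self._record("select_features", [self.out / "selected.tsv"], seed=None)

    def _selected_genes(self) -> list:
        df = pd.read_csv(self.out / "selected.tsv", sep="\t")
        return list(df.loc[df.selected == 1, "gene_id"])

    def _stage_pretrain(self) -> None:
        source = tc_io.read_expression(self.out / "source.tsv", orientation="samples")
        target = tc_io.read_expression(self.out / "target.tsv", orientation="samples")
        genes = self._selected_genes()
        spec = AutoencoderSpec(
            len(genes), self.config.hidden_dim, self.config.bottleneck_dim
        )
        encoder = make_encoder_variant(
            source.subset_genes(genes).values,
            target.subset_genes(genes).values,
            spec,
            variant=self.config.encoder_variant,
            config=self.config.train_config(),
            selected_genes=genes,
        )
        tc_io.save_weights(encoder, self.out / "encoder.h5")
        self._record("pretrain", [self.out / "encoder.h5"], seed=self.config.seed)

    def _make_factory(self, encoder, task: str, seed: int):
        cfg = self.config

        def factory():
            cls = TransCellClassifier if task == "classification" else TransCellRegressor
            return cls(
                encoder=encoder,
                head_hidden=cfg.head_hidden,
                epochs=cfg.epochs,
                batch_size=cfg.batch_size,
                lr=cfg.lr,
                patience=cfg.patience,
                random_state=seed,
            )

        factory.method_name = "transcell"
        return factory

    def _stage_train(self) -> None:
        cfg = self.config
        target = tc_io.read_expression(self.out / "target.tsv", orientation="samples")
        encoder = tc_io.load_weights(self.out / "encoder.h5")
        genes = self._selected_genes()
        registry = self.out / "registry"
        outputs = []
        all_rows = []

        jobs = []
        meas = tc_io.read_measurements(self.out / "measurements.tsv", "metabolite")
        for fid in subsample_features(meas.feature_ids, cfg.feature_cap, cfg.seed)[
            : cfg.n_features_to_train
        ]:
            jobs.append((meas, fid, "regression"))
        muts = tc_io.read_measurements(self.out / "mutations.tsv", "mutation")
        for fid in subsample_features(muts.feature_ids, cfg.feature_cap, cfg.seed)[
            : cfg.n_mutations_to_train
        ]:
            jobs.append((muts, fid, "classification"))

        for table, fid, task_kind in jobs:
            task = align_task(target, table, fid, genes)
            factory = self._make_factory(encoder, task_kind, cfg.seed)
            ev = run_cv(task, factory, k=cfg.cv_folds, seed=cfg.seed)
            all_rows.append(ev)
            # persist the five fold models for the serving ensemble
            folds = np.array([ev.fold_assignments[s] for s in task.sample_ids])
            type_dir = registry / table.measurement_type
            for fold in range(cfg.cv_folds):
                model = factory()
                model.fit(task.X[folds != fold], task.y[folds != fold])
                path = type_dir / f"{fid}_fold{fold}.h5"
                tc_io.save_weights(model.state_, path)
                outputs.append(path)

        results = pd.concat([ev.to_rows() for ev in all_rows], ignore_index=True)
        results.to_csv(self.out / "results.tsv", sep="\t", index=False)
        agg = build_benchmark_table(all_rows)
        agg.to_csv(self.out / "aggregates.tsv", sep="\t", index=False)
        outputs += [self.out / "results.tsv", self.out / "aggregates.tsv"]
        self._record("train", outputs, seed=cfg.seed)

    def _stage_evaluate(self) -> None:
        agg = pd.read_csv(self.out / "aggregates.tsv", sep="\t")
        rmse_rows = agg[(agg.metric == "rmse")]
        summary = {"n_features": int(agg.feature_id.nunique())}
        if len(rmse_rows) >= 4:
            from .evaluation import quartile_partition

            parts = quartile_partition(dict(zip(rmse_rows.feature_id, rmse_rows["mean"])))
            summary["well"] = sorted(parts["well"])
            summary["poor"] = sorted(parts["poor"])
        with open(self.out / "evaluation.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        self._record("evaluate", [self.out / "evaluation.json"], seed=None)

    def _stage_screen(self) -> None:
        cfg = self.config
        target = tc_io.read_expression(self.out / "target.tsv", orientation="samples")
        genes = self._selected_genes()
        groups = pd.read_csv(self.out / "groups.tsv", sep="\t")
        meas = tc_io.read_measurements(self.out / "measurements.tsv", "metabolite")
        X = target.subset_genes(genes).values
        scores = np.column_stack(
            [
                predict_ensemble(self.out / "registry" / "metabolite", fid, X)
                for fid in meas.feature_ids
                if (self.out / "registry" / "metabolite" / f"{fid}_fold0.h5").exists()
            ]
        )
        trained = [
            fid
            for fid in meas.feature_ids
            if (self.out / "registry" / "metabolite" / f"{fid}_fold0.h5").exists()
        ]
        screen = ScreenMatrix(
            cell_line_ids=list(target.sample_ids),
            group_labels=list(groups.set_index("sample_id").loc[target.sample_ids, "group"]),
            drug_ids=trained,
            scores=scores,
            threshold=cfg.screen_threshold,
        )
        tables = []
        for group in screen.groups:
            res = drug_selectivity(screen, group)
            t = res.table.copy()
            t.insert(0, "group", group)
            tables.append(t)
        pd.concat(tables, ignore_index=True).to_csv(
            self.out / "selectivity.tsv", sep="\t", index=False
        )
        self._record("screen", [self.out / "selectivity.tsv"], seed=None)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all six stages; returns the run directory."""
    return Pipeline(config).run()


def predict_ensemble(registry_dir, feature_id: str, X, n_replicates: int = 5) -> np.ndarray:
    """Average prediction of the five CV-fold models saved for a feature."""
    registry_dir = Path(registry_dir)
    paths = [registry_dir / f"{feature_id}_fold{i}.h5" for i in range(n_replicates)]
    missing = [p.name for p in paths if not p.exists()]
    if missing:
        raise FileNotFoundError(
            f"missing replicate models for {feature_id!r}: {missing}"
        )
    from .networks import predict as net_predict

    preds = [net_predict(tc_io.load_weights(p), X) for p in paths]
    return np.mean(preds, axis=0)


def gated_features(aggregates: pd.DataFrame, gate: float = 0.7) -> list:
    """Feature ids served by the registry: mutation-task features must have
    cross-validated macro F1 strictly above the gate; others pass through."""
    served = []
    for fid, sub in aggregates.groupby("feature_id"):
        macro = sub[sub.metric == "f1_macro"]
        if len(macro) and float(macro["mean"].iloc[0]) <= gate:
            continue
        served.append(fid)
    return sorted(served)
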