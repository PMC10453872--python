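"""End-to-end experiment runs: data → preprocess → train → generate → evaluate.

An :class:`ExperimentConfig` (typically loaded from a YAML file) fully
determines a run: the dataset (a synthetic one generated in place, or an
existing directory of PNGs + metadata CSV), the preprocessing stages, the
training grid (learning rates × batch sizes), and the evaluation outputs.
Each grid cell gets its own sub-directory with a checkpoint, the training
trace CSV, generated sample images, and a metrics report; a manifest
records every output file and every seed so a saved config re-runs to
identical deterministic artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify_eval, synthetic_data
from .gan_core import TrainConfig, generate_images, save_checkpoint, train_dcgan
from .image import ImageTensor
from .preprocess import PipelineConfig, SharpenConfig, preprocess_pipeline

__all__ = ["ExperimentConfig", "run_experiment", "report_summary", "load_config"]

log = logging.getLogger("lesiongan")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    output_dir: str = "runs/experiment"
    seed: int = 0
    data_dir: str | None = None  # existing dataset; None → synthesize
    synthetic: synthetic_data.SyntheticParams = field(
        default_factory=synthetic_data.SyntheticParams
    )
    train_fraction: float = 0.7
    unlabeled_fraction: float = 0.3
    preprocess: PipelineConfig = field(default_factory=PipelineConfig)
    learning_rates: tuple[float, ...] = (0.01,)
    batch_sizes: tuple[int, ...] = (64,)
    epochs: int = 10
    momentum: float = 0.5
    generator_loss_form: str = "saturating"
    latent_dim: int = 100
    n_generate: int = 8

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        kwargs = dict(raw)
        if "synthetic" in kwargs:
            kwargs["synthetic"] = synthetic_data.SyntheticParams(**kwargs["synthetic"])
        if "preprocess" in kwargs:
            pp = dict(kwargs["preprocess"])
            if "sharpen_cfg" in pp:
                pp["sharpen_cfg"] = SharpenConfig(**pp["sharpen_cfg"])
            if "target_size" in pp:
                pp["target_size"] = tuple(pp["target_size"])
            kwargs["preprocess"] = PipelineConfig(**pp)
        for key in ("learning_rates", "batch_sizes"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return ExperimentConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid experiment config {path}: {exc}") from exc


def _load_split_images(
    records: list[synthetic_data.LesionRecord], data_dir: Path, cfg: ExperimentConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Preprocess each record's PNG to a 64×64×3 array in [−1, 1]."""
    xs, ys = [], []
    for rec in records:
        img = ImageTensor.load(data_dir / f"{rec.image_name}.png")
        out = preprocess_pipeline(img, cfg.preprocess)
        xs.append(out.pixels * 2.0 - 1.0)
        ys.append(rec.target)
    return np.stack(xs), np.asarray(ys, dtype=np.intp)


def run_experiment(cfg: ExperimentConfig) -> Path:
    """Execute the configured run; returns the run directory."""
    run_dir = Path(cfg.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "config": cfg.to_dict(), "outputs": []}

    def emit(path: Path) -> None:
        manifest["outputs"].append(str(path.relative_to(run_dir)))

    stage = "synth-data"
    try:
        if cfg.data_dir is None:
            data_dir = run_dir / "data"
            log.info("stage=%s dir=%s", stage, data_dir)
            records = synthetic_data.make_dataset(cfg.synthetic, data_dir)
        else:
            data_dir = Path(cfg.data_dir)
            records = synthetic_data.read_metadata(data_dir)

        stage = "split"
        split = synthetic_data.split_dataset(
            records, cfg.train_fraction, cfg.unlabeled_fraction, seed=cfg.seed
        )

        stage = "preprocess"
        log.info("stage=%s n_train=%d n_test=%d", stage, len(split.train_records),
                 len(split.test_records))
        x_train, y_train = _load_split_images(split.train_records, data_dir, cfg)
        x_test, y_test = _load_split_images(split.test_records, data_dir, cfg)

        for lr in cfg.learning_rates:
            for bs in cfg.batch_sizes:
                sub = run_dir / f"lr_{lr:g}_bs_{bs}"
                sub.mkdir(parents=True, exist_ok=True)
                stage = "train"
                log.info("stage=%s lr=%g batch=%d epochs=%d", stage, lr, bs, cfg.epochs)
                tc = TrainConfig(
                    learning_rate=lr,
                    momentum=cfg.momentum,
                    batch_size=bs,
                    epochs=cfg.epochs,
                    seed=cfg.seed,
                    generator_loss_form=cfg.generator_loss_form,
                    latent_dim=cfg.latent_dim,
                )
                G, D, trace = train_dcgan(
                    x_train, y_train, split.unlabeled_mask, tc,
                    val_images=x_test, val_labels=y_test,
                )
                trace.to_csv(sub / "trace.csv")
                emit(sub / "trace.csv")
                save_checkpoint(sub / "model.ckpt.npz", G, D, tc)
                emit(sub / "model.ckpt.npz")

                stage = "generate"
                for i, img in enumerate(generate_images(G, cfg.n_generate, cfg.seed)):
                    img.save(sub / f"generated_{i:03d}.png")
                    emit(sub / f"generated_{i:03d}.png")

                stage = "evaluate"
                report = classify_eval.evaluate(D, x_test, y_test, sub / "report.json")
                emit(sub / "report.json")
                cm = classify_eval.confusion(
                    y_test, classify_eval.predict(D, x_test)[0]
                )
                pd.DataFrame([dataclasses.asdict(cm)]).to_csv(
                    sub / "confusion.csv", index=False
                )
                emit(sub / "confusion.csv")
                if report.roc_points:
                    pd.DataFrame(report.roc_points, columns=["fpr", "tpr"]).to_csv(
                        sub / "roc.csv", index=False
                    )
                    emit(sub / "roc.csv")
                log.info("stage=evaluate accuracy=%.2f%% bas=%.2f%%",
                         report.accuracy, report.bas)
    except Exception:
        log.exception("experiment failed at stage %s", stage)
        raise

    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return run_dir


def report_summary(run_dirs: list[str | Path], sort_by: str = "accuracy") -> pd.DataFrame:
    """One row per completed sub-run: hyperparameters + final metrics.

    Accuracy is recomputed from the stored confusion matrix as a
    consistency check; incomplete runs are flagged rather than dropped.
    """
    rows = []
    for base in run_dirs:
        base = Path(base)
        subs = sorted(d for d in base.glob("lr_*_bs_*") if d.is_dir()) or [base]
        for sub in subs:
            row: dict = {"run": str(sub)}
            parts = sub.name.split("_")
            if len(parts) == 4 and parts[0] == "lr":
                row["learning_rate"] = float(parts[1])
                row["batch_size"] = int(parts[3])
            report_path = sub / "report.json"
            if not report_path.exists():
                row["incomplete"] = True
                rows.append(row)
                continue
            row["incomplete"] = False
            row.update(json.loads(report_path.read_text()))
            cm_path = sub / "confusion.csv"
            if cm_path.exists():
                cm = pd.read_csv(cm_path).iloc[0]
                n = int(cm.tp + cm.tn + cm.fp + cm.fn)
                row["accuracy_from_confusion"] = 100.0 * (cm.tp + cm.tn) / n
            trace_path = sub / "trace.csv"
            if trace_path.exists():
                tail = pd.read_csv(trace_path).iloc[-1]
                row["final_d_loss"] = float(tail.d_loss)
                row["final_g_loss"] = float(tail.g_loss)
            rows.append(row)
    df = pd.DataFrame(rows)
    if sort_by in df.columns:
        df = df.sort_values(sort_by, ascending=False).reset_index(drop=True)
    return df
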