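"""End-to-end pipeline commands: generate, prepare, train, evaluate, inspect.

Artifact layout under ``workdir``::

    raw/       images/*.png, params.csv, manifest.csv      (generate)
    prepared/  images/*.png, features.csv, reduction.json,
               manifest.csv                                 (prepare)
    train/     checkpoint.zip, log.csv                      (train)
    eval/      metrics.json, confusion.csv                  (evaluate)

Every stage writes a ``meta.json`` embedding the config hash and seed, so
reruns with identical configuration produce identical manifests.  The
split is computed on raw sample ids; six-fold image augmentation and
parameter jitter are applied to the training split only, and the PCA
reduction is fitted on the (augmented) training records before being
applied to validation and test.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, config_hash, derive_seed
from .data import (AUGMENT_NAMES, augment_six_fold, center_crop,
                   dataset_manifest, load_parameter_table, read_image, resize,
                   split_dataset, write_image, write_parameter_table)
from .errors import DataError
from .features import ReductionModel, apply_reduction, fit_reduction, jitter_parameters
from .classifier import MmVitnNetClassifier
from .model import (ModelConfig, count_flops, count_parameters,
                    load_checkpoint, model_summary, save_checkpoint)
from .synthetic import GeneratorConfig, generate_dataset
from .training import evaluate as eval_metrics

COMMANDS = ("generate", "prepare", "train", "evaluate", "inspect")


def _log(msg: str) -> None:
    print(f"[mmfluorfuse] {msg}", file=sys.stderr)


def _write_meta(directory: Path, cfg: RunConfig, stage: str) -> None:
    meta = {"stage": stage, "config_hash": config_hash(cfg), "seed": cfg.seed}
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise DataError(f"missing artifact {path}; run `mmfluorfuse {producer}` first")
    return path


# ----------------------------------------------------------------- commands

def cmd_generate(cfg: RunConfig) -> Path:
    out = Path(cfg.workdir) / "raw"
    (out / "images").mkdir(parents=True, exist_ok=True)
    gen = GeneratorConfig(**{**cfg.generator.__dict__,
                             "seed": derive_seed(cfg.seed, "generate")})
    _log(f"generate: n={gen.n_samples} seed={gen.seed}")
    samples, manifest = generate_dataset(gen, render_images=True)
    records = []
    for s in samples:
        rel = f"images/{s.params.sample_id}.png"
        write_image(s.image, out / rel)
        records.append(s.params)
    manifest["image_path"] = [f"images/{r.sample_id}.png" for r in records]
    write_parameter_table(records, out / "params.csv")
    manifest.to_csv(out / "manifest.csv", index=False)
    counts = dataset_manifest(samples)
    _log(f"generate: per-level counts {counts['per_level']} total {counts['total']}")
    _write_meta(out, cfg, "generate")
    return out


def cmd_prepare(cfg: RunConfig) -> Path:
    root = Path(cfg.workdir)
    raw = root / "raw"
    _require(raw / "manifest.csv", "generate")
    manifest = pd.read_csv(raw / "manifest.csv")
    records = {r.sample_id: r for r in load_parameter_table(raw / "params.csv")}
    levels = dict(zip(manifest["sample_id"].astype(str), manifest["level"].astype(int)))

    split = split_dataset(list(levels), levels, cfg.split_ratios,
                          seed=derive_seed(cfg.seed, "split"))
    membership = {sid: "train" for sid in split.train}
    membership.update({sid: "val" for sid in split.val})
    membership.update({sid: "test" for sid in split.test})
    _log(f"prepare: split sizes train={len(split.train)} "
         f"val={len(split.val)} test={len(split.test)}")

    out = root / "prepared"
    (out / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    train_records = []
    for _, row in manifest.iterrows():
        sid = str(row["sample_id"])
        img = read_image(raw / row["image_path"])
        side = min(cfg.crop_side, img.height, img.width)
        img = resize(center_crop(img, side), cfg.model.img_size)
        split_name = membership[sid]
        if split_name == "train":
            variants = augment_six_fold(img)
            for aug_name, variant in zip(AUGMENT_NAMES, variants):
                vid = f"{sid}__{aug_name}"
                rec = jitter_parameters(
                    records[sid], cfg.jitter_lo, cfg.jitter_hi,
                    seed=derive_seed(cfg.seed, f"jitter:{vid}"))
                rec.sample_id = vid
                train_records.append(rec)
                rel = f"images/{vid}.png"
                write_image(variant, out / rel)
                rows.append({"sample_id": vid, "source_id": sid,
                             "image_path": rel, "level": levels[sid],
                             "split": "train"})
        else:
            rel = f"images/{sid}__orig.png"
            write_image(img, out / rel)
            rows.append({"sample_id": f"{sid}__orig", "source_id": sid,
                         "image_path": rel, "level": levels[sid],
                         "split": split_name})

    reduction = fit_reduction(train_records, k=cfg.model.pca_k)
    reduction.to_json(out / "reduction.json")

    feat_rows = []
    by_id = {r.sample_id: r for r in train_records}
    for row in rows:
        rec = by_id.get(row["sample_id"]) or records[row["source_id"]]
        feats = apply_reduction(reduction, rec).values
        entry = dict(row)
        for j, v in enumerate(feats, start=1):
            entry[f"pc{j}"] = v
        feat_rows.append(entry)
    pd.DataFrame(feat_rows).to_csv(out / "features.csv", index=False)
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    _write_meta(out, cfg, "prepare")
    return out


def _load_split(prepared: Path, cfg: RunConfig, split_name: str):
    feats = pd.read_csv(prepared / "features.csv")
    sel = feats[feats["split"] == split_name]
    if len(sel) == 0:
        raise DataError(f"split {split_name!r} is empty in {prepared}")
    k = cfg.model.pca_k
    text = sel[[f"pc{j}" for j in range(1, k + 1)]].to_numpy(float)
    images = np.stack([read_image(prepared / p).pixels
                       for p in sel["image_path"]])
    return images, text, sel["level"].to_numpy(int)


def cmd_train(cfg: RunConfig) -> Path:
    root = Path(cfg.workdir)
    prepared = root / "prepared"
    _require(prepared / "features.csv", "prepare")
    train_data = _load_split(prepared, cfg, "train")
    val_data = _load_split(prepared, cfg, "val")
    _log(f"train: n_train={len(train_data[2])} n_val={len(val_data[2])} "
         f"seed={cfg.seed}")
    clf = MmVitnNetClassifier(model_config=cfg.model, train_config=cfg.train,
                              seed=derive_seed(cfg.seed, "init"))
    clf.fit((train_data[0], train_data[1]), train_data[2],
            validation_data=((val_data[0], val_data[1]), val_data[2]))
    out = root / "train"
    out.mkdir(parents=True, exist_ok=True)
    save_checkpoint(clf.model_, out / "checkpoint.zip",
                    extra={"config_hash": config_hash(cfg), "seed": cfg.seed})
    clf.history_.to_csv(out / "log.csv", index=False)
    _write_meta(out, cfg, "train")
    best = clf.history_["val_acc"].max()
    _log(f"train: best val accuracy {best:.3f}")
    return out


def cmd_evaluate(cfg: RunConfig, split_name: str = "test",
                 checkpoint: Path | None = None) -> Path:
    root = Path(cfg.workdir)
    prepared = root / "prepared"
    _require(prepared / "features.csv", "prepare")
    ckpt = Path(checkpoint) if checkpoint else root / "train" / "checkpoint.zip"
    _require(ckpt, "train")
    model = load_checkpoint(ckpt)
    images, text, y = _load_split(prepared, cfg, split_name)
    from .training import _predict_logits
    logits = _predict_logits(model, images, text)
    y_pred = logits.argmax(axis=1) + 1
    report, counts, mat = eval_metrics(y, y_pred, n_classes=model.config.n_classes)
    out = root / "eval"
    out.mkdir(parents=True, exist_ok=True)
    (out / "metrics.json").write_text(json.dumps(report.to_dict(), indent=2))
    labels = [f"level_{i}" for i in range(1, model.config.n_classes + 1)]
    pd.DataFrame(mat, index=labels, columns=labels).to_csv(out / "confusion.csv")
    _write_meta(out, cfg, "evaluate")
    _log(f"evaluate[{split_name}]: accuracy {report.accuracy:.3f} "
         f"macro-F1 {report.macro_f1:.3f}")
    return out


#: the four stage-depth configurations compared in the depth ablation
DEPTH_ABLATION = ((1, 1, 1, 1), (1, 3, 1, 1), (1, 1, 3, 1), (1, 3, 3, 1))


def cmd_inspect(cfg: RunConfig) -> dict:
    summary = model_summary(cfg.model)
    ablation = []
    for depths in DEPTH_ABLATION:
        mc = ModelConfig(**{**cfg.model.__dict__, "stage_depths": depths})
        ablation.append({"stage_depths": depths,
                         "parameters": count_parameters(mc),
                         "flops": count_flops(mc)})
    summary["depth_ablation"] = ablation
    print(json.dumps(summary, indent=2, default=str))
    return summary


def run_pipeline(command: str, cfg: RunConfig):
    """Dispatch one pipeline command; each is idempotent for a fixed config."""
    if command not in COMMANDS:
        raise DataError(f"unknown command {command!r}; choose from {COMMANDS}")
    return {"generate": cmd_generate, "prepare": cmd_prepare, "train": cmd_train,
            "evaluate": cmd_evaluate, "inspect": cmd_inspect}[command](cfg)
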