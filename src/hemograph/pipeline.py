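"""End-to-end orchestration: simulate/load -> preprocess -> (augment) ->
build graphs -> split -> train -> evaluate -> optional noise sweep.

Every stage draws its seed deterministically from the global seed, all
stage configs and seeds are logged to a provenance record, and a rerun
with an identical config reproduces the metrics bit-for-bit.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path


from . import chebnet, gan, metrics
from .config import PipelineConfig, simparams_for, stage_seed
from .graphs import build_region_graph, pad_graph
from .preprocess import ImageSample, load_dataset
from .simulate import generate_dataset


def _log(lines: list[str], msg: str):
    stamp = time.strftime("%H:%M:%S")
    lines.append(f"{stamp} {msg}")


def build_graphs_for(
    samples: list[ImageSample], config: PipelineConfig
) -> list:
    seg = config.segmentation
    budget = config.model.node_budget
    out = []
    for s in samples:
        g = build_region_graph(
            s.pixels,
            n_regions_target=seg.n_regions,
            compactness=seg.compactness,
            gaussian_sigma=seg.gaussian_sigma,
            label=s.label,
            source_id=s.source_id,
        )
        out.append(pad_graph(g, budget))
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the results dict and writes
    metrics, model checkpoint, provenance and logs under ``out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    # --- data ------------------------------------------------------------
    if config.data.manifest:
        _log(log, f"stage=load manifest={config.data.manifest}")
        samples = load_dataset(config.data.manifest, side=config.side)
        if not samples:
            raise RuntimeError("load stage: manifest yielded no images")
    else:
        _log(
            log,
            f"stage=simulate n_per_class={config.data.n_per_class} "
            f"separation={config.data.separation}",
        )
        samples = generate_dataset(
            config.data.n_per_class,
            simparams_for(config),
            seed=stage_seed(config.seed, "simulate"),
        )
        # simulated rasters take the same per-image normalization that
        # manifest images receive in preprocessing
        from .preprocess import minmax_normalize

        for s in samples:
            s.pixels = minmax_normalize(s.pixels)

    # --- split -----------------------------------------------------------
    split_s = stage_seed(config.seed, "split")
    train, val, test = metrics.split_dataset(
        samples, config.eval.fractions, seed=split_s
    )
    _log(log, f"stage=split sizes={len(train)}/{len(val)}/{len(test)} seed={split_s}")

    # --- optional GAN balancing on the training portion -------------------
    if config.augment.enabled:
        pool = samples if not config.augment.train_only else train
        by_class: dict[str, list[ImageSample]] = {}
        for s in pool:
            by_class.setdefault(s.label, []).append(s)
        gan_models = {}
        for label in sorted(by_class):
            if len(by_class[label]) >= config.augment.target_per_class:
                continue
            g_seed = stage_seed(config.seed, f"gan-{label}")
            cfg = gan.GanConfig(**{**asdict(config.gan), "seed": g_seed})
            _log(log, f"stage=gan-train class={label} seed={g_seed}")
            gan_models[label] = gan.train_gan(
                [s.pixels for s in by_class[label]], cfg
            )
        balanced = gan.balance_classes(
            pool,
            config.augment.target_per_class,
            gan_models,
            seed=stage_seed(config.seed, "balance"),
        )
        _log(log, f"stage=balance total={len(balanced)}")
        if config.augment.train_only:
            train = balanced
        else:
            train, val, test = metrics.split_dataset(
                balanced, config.eval.fractions, seed=split_s
            )

    # --- graphs ----------------------------------------------------------
    _log(log, f"stage=build-graphs regions={config.segmentation.n_regions}")
    g_train = build_graphs_for(train, config)
    g_val = build_graphs_for(val, config)
    g_test = build_graphs_for(test, config)

    # --- train -----------------------------------------------------------
    m_seed = stage_seed(config.seed, "train")
    model_cfg = chebnet.ModelConfig(**{**asdict(config.model), "seed": m_seed})
    _log(log, f"stage=train epochs={model_cfg.epochs} seed={m_seed}")
    model, report = chebnet.train_model(g_train, g_val, model_cfg)
    chebnet.save_model(model, report, out_dir / "model")

    # --- evaluate --------------------------------------------------------
    probs = model.predict_proba(g_test)
    y_true = [g.label for g in g_test]
    y_pred = model.predict(g_test)
    rep = metrics.evaluate_predictions(
        y_true, y_pred, scores=probs[:, 0], positive=config.eval.positive_class
    )
    _log(log, f"stage=evaluate accuracy={rep.accuracy:.4f}")

    results = {
        "test_metrics": rep.to_dict(),
        "train_report": {
            "final_train_acc": report.train_acc[-1] if report.train_acc else None,
            "final_val_acc": report.val_acc[-1] if report.val_acc else None,
            "best_epoch": report.best_epoch,
        },
        "sizes": {"train": len(train), "val": len(val), "test": len(test)},
    }

    # --- optional noise sweep ---------------------------------------------
    if config.eval.snr_list:
        sweep = metrics.noise_robustness_sweep(
            model,
            test,
            config.eval.snr_list,
            seed=stage_seed(config.seed, "noise"),
            n_regions_target=config.segmentation.n_regions,
            compactness=config.segmentation.compactness,
        )
        results["noise_sweep"] = {str(k): v for k, v in sweep.items()}
        _log(log, f"stage=noise-sweep snrs={config.eval.snr_list}")

    # --- provenance and outputs -------------------------------------------
    provenance = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "stage_seeds": {
            s: stage_seed(config.seed, s)
            for s in ("simulate", "split", "train", "noise", "balance")
        },
    }
    with open(out_dir / "metrics.json", "w") as fh:
        json.dump(results, fh, indent=2)
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    config.save(out_dir / "config.yaml")
    with open(out_dir / "log.txt", "w") as fh:
        fh.write("\n".join(log) + "\n")
    return results


def crossvalidate(config: PipelineConfig, samples: list[ImageSample] | None = None):
    """Stratified k-fold CV of the classifier over the whole dataset.

    Within each fold the training portion is re-split 80/20 for validation.
    Returns the per-fold MetricsReports.
    """
    if samples is None:
        if config.data.manifest:
            samples = load_dataset(config.data.manifest, side=config.side)
        else:
            from .preprocess import minmax_normalize

            samples = generate_dataset(
                config.data.n_per_class,
                simparams_for(config),
                seed=stage_seed(config.seed, "simulate"),
            )
            for s in samples:
                s.pixels = minmax_normalize(s.pixels)
    graphs = build_graphs_for(samples, config)
    m_seed = stage_seed(config.seed, "cv-train")

    def train_fn(train_graphs):
        tr, va, _ = metrics.split_dataset(
            train_graphs, (0.8, 0.2, 0.0), seed=m_seed
        )
        cfg = chebnet.ModelConfig(**{**asdict(config.model), "seed": m_seed})
        model, _ = chebnet.train_model(tr, va, cfg)
        return model

    def eval_fn(model, test_graphs):
        probs = model.predict_proba(test_graphs)
        y_true = [g.label for g in test_graphs]
        y_pred = model.predict(test_graphs)
        return metrics.evaluate_predictions(
            y_true, y_pred, scores=probs[:, 0],
            positive=config.eval.positive_class,
        )

    return metrics.kfold_cv(
        graphs, config.eval.kfold, stage_seed(config.seed, "cv"), train_fn, eval_fn
    )
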