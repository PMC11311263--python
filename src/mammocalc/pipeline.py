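"""End-to-end reproducible runs: phantoms -> features -> CNN -> evaluation.

A run is described by a YAML/dict config with one section per stage; a
single global seed is propagated everywhere, so a run is bit-reproducible.
The run directory is self-describing: the normalized config, the phantom
manifest with split assignment, training history, test predictions, metrics
and localization candidates are all written alongside a JSON-lines log with
per-stage timing.

Localization runs only on classifier-positive test images, mirroring the
clinical reading order (first decide, then point), unless
``localize.all_images`` forces every image through.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import augment as aug
from . import evaluate as ev
from .cnn import CNNClassifier
from .features import FeatureStackExtractor
from .localize import TopHatLocalizer, default_se_radius
from .phantom import PATTERNS, PhantomSpec, generate_phantom
from .preprocess import preprocess_pipeline

__all__ = ["DEFAULT_CONFIG", "ConfigError", "PipelineStageError",
           "validate_config", "run_end_to_end"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "mammocalc_run",
    "phantom": {
        "n_pos": 16,
        "n_neg": 16,
        "width": 128,
        "height": 128,
        "pixel_spacing": 0.07,
        "n_spots": 5,
        "spot_contrast": 0.5,
        "spot_diameter_range": [0.1, 1.0],
        "tissue_texture_scale": 12.0,
        "add_artifacts": False,
    },
    "preprocess": {"side": 128, "artifact_removal": True},
    "augment": {"enabled": False, "scales": [0.8, 1.0, 1.2],
                "angles": [90, 180, 270], "reflections": ["horizontal", "vertical"]},
    "split": {"fractions": [0.70, 0.20, 0.10]},
    "features": {"out_side": 64, "gabor_mode": "canonical",
                 "glcm_window": 17, "glcm_stride": 8, "glcm_feature": "contrast"},
    "cnn": {"conv_blocks": [[16, 3, 2], [16, 3, 2]], "dense_units": 64,
            "learning_rate": 1e-3, "batch_size": 8, "epochs": 10,
            "dropout": 0.2, "l2": 0.001, "threshold": 0.5},
    "localize": {"se_radius": None, "k_sigma": 3.0, "min_area": 1,
                 "max_area": None, "all_images": False},
}


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid config:\n" + "\n".join(f"  - {e}" for e in errors))


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"[{stage}] {cause}")


def _merge(defaults: dict, user: dict, prefix: str, errors: list[str]) -> dict:
    out = {}
    for key, dval in defaults.items():
        if isinstance(dval, dict):
            sub = user.get(key, {})
            if not isinstance(sub, dict):
                errors.append(f"{prefix}{key}: expected a mapping")
                sub = {}
            out[key] = _merge(dval, sub, f"{prefix}{key}.", errors)
        else:
            out[key] = user.get(key, dval)
    for key in user:
        if key not in defaults:
            errors.append(f"{prefix}{key}: unknown key")
    return out


def _check_ranges(cfg: dict, errors: list[str]) -> None:
    ph = cfg["phantom"]
    if ph["n_pos"] < 0 or ph["n_neg"] < 0:
        errors.append("phantom.n_pos/n_neg: must be non-negative")
    if not (0.0 < ph["spot_contrast"] <= 1.0):
        errors.append("phantom.spot_contrast: must be in (0, 1]")
    fr = cfg["split"]["fractions"]
    if len(fr) != 3 or abs(sum(fr) - 1.0) > 1e-9 or any(f < 0 for f in fr):
        errors.append("split.fractions: must be three non-negative numbers summing to 1")
    cnn = cfg["cnn"]
    if cnn["learning_rate"] <= 0:
        errors.append("cnn.learning_rate: must be positive")
    if cnn["epochs"] < 1:
        errors.append("cnn.epochs: must be >= 1")
    if not (0.0 <= cnn["dropout"] < 1.0):
        errors.append("cnn.dropout: must be in [0, 1)")
    if cfg["features"]["glcm_window"] % 2 == 0:
        errors.append("features.glcm_window: must be odd")


def validate_config(source=None) -> dict:
    """Normalize a config (path, YAML text, dict or None -> defaults).

    Unknown keys and out-of-range values are collected exhaustively and
    raised together as a :class:`ConfigError`.
    """
    if source is None:
        user: dict = {}
    elif isinstance(source, dict):
        user = source
    else:
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        user = yaml.safe_load(text) or {}
        if not isinstance(user, dict):
            raise ConfigError(["top level of the config must be a mapping"])
    errors: list[str] = []
    cfg = _merge(DEFAULT_CONFIG, user, "", errors)
    _check_ranges(cfg, errors)
    if errors:
        raise ConfigError(errors)
    return cfg


def _stage(log, name, fn):
    t0 = time.perf_counter()
    try:
        result = fn()
    except Exception as e:           # noqa: BLE001 - re-tagged with stage name
        log({"stage": name, "status": "failed", "error": str(e)})
        raise PipelineStageError(name, e) from e
    log({"stage": name, "status": "ok", "seconds": round(time.perf_counter() - t0, 3)})
    return result


def run_end_to_end(config=None, out_dir=None) -> Path:
    """Execute the full pipeline; returns the run directory."""
    cfg = validate_config(config)
    run_dir = Path(out_dir or cfg["out_dir"])
    run_dir.mkdir(parents=True, exist_ok=True)
    log_path = run_dir / "log.jsonl"
    log_fh = log_path.open("w")

    def log(event: dict) -> None:
        log_fh.write(json.dumps(event) + "\n")
        log_fh.flush()

    log({"stage": "config", "seed": cfg["seed"]})
    (run_dir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    seed = int(cfg["seed"])
    rng = np.random.default_rng(seed)

    # ---- phantoms --------------------------------------------------------
    def make_phantoms():
        ph = cfg["phantom"]
        n_pos, n_neg = int(ph["n_pos"]), int(ph["n_neg"])
        sub_seeds = rng.integers(0, 2**31 - 1, size=n_pos + n_neg)
        images, truths, rows = [], [], []
        for i in range(n_pos + n_neg):
            positive = i < n_pos
            spec = PhantomSpec(
                width=ph["width"], height=ph["height"],
                pixel_spacing=ph["pixel_spacing"],
                n_spots=ph["n_spots"] if positive else 0,
                spot_diameter_range=tuple(ph["spot_diameter_range"]),
                pattern=PATTERNS[i % len(PATTERNS)] if positive else "scattered",
                spot_contrast=ph["spot_contrast"],
                tissue_texture_scale=ph["tissue_texture_scale"],
                add_artifacts=ph["add_artifacts"],
                seed=int(sub_seeds[i]))
            grid, truth = generate_phantom(spec)
            images.append(grid)
            truths.append(truth)
            rows.append({"index": i, "label": int(positive),
                         "seed": int(sub_seeds[i]), "n_spots": len(truth.spots),
                         "pattern": spec.pattern})
        return images, truths, pd.DataFrame(rows)

    images, truths, manifest = _stage(log, "phantom", make_phantoms)

    # ---- preprocess ------------------------------------------------------
    def preprocess_all():
        pp = cfg["preprocess"]
        return [preprocess_pipeline(
            im, side=pp["side"],
            artifact_removal=pp["artifact_removal"] and cfg["phantom"]["add_artifacts"])
            for im in images]

    clean = _stage(log, "preprocess", preprocess_all)
    labels = manifest["label"].to_numpy()

    # ---- augmentation (optional) ----------------------------------------
    if cfg["augment"]["enabled"]:
        def augment_all():
            plan = aug.AugmentPlan(
                scales=tuple(cfg["augment"]["scales"]),
                angles=tuple(cfg["augment"]["angles"]),
                reflections=tuple(cfg["augment"]["reflections"]))
            imgs, labs, prov = aug.augment_arrays(clean, labels, plan)
            return imgs, np.asarray(labs), prov
        clean, labels, provenance = _stage(log, "augment", augment_all)
        # truth records only exist for originals; map back by source_id
        truths = [truths[int(s)] for s in provenance["source_id"]]
        manifest = provenance.assign(label=labels)

    # ---- split -----------------------------------------------------------
    def split():
        return aug.stratified_split(labels, aug.SplitSpec(
            fractions=tuple(cfg["split"]["fractions"]), seed=seed))

    assignment = _stage(log, "split", split)
    manifest = manifest.assign(split=assignment)
    manifest.to_csv(run_dir / "manifest.csv", index=False)

    # ---- features --------------------------------------------------------
    def extract():
        fx = FeatureStackExtractor(**cfg["features"])
        return fx.transform(clean)

    stacks = _stage(log, "features", extract)

    # ---- train -----------------------------------------------------------
    tr = assignment == "train"
    va = assignment == "val"
    te = assignment == "test"

    def fit():
        c = cfg["cnn"]
        clf = CNNClassifier(
            conv_blocks=tuple(tuple(b) for b in c["conv_blocks"]),
            dense_units=c["dense_units"], learning_rate=c["learning_rate"],
            batch_size=c["batch_size"], epochs=c["epochs"],
            dropout=c["dropout"], l2=c["l2"], threshold=c["threshold"],
            random_state=seed)
        clf.fit(stacks[tr], labels[tr], X_val=stacks[va], y_val=labels[va])
        clf.history_.to_csv(run_dir / "history.csv", index=False)
        return clf

    clf = _stage(log, "train", fit)

    # ---- predict + evaluate ---------------------------------------------
    def evaluate():
        prob = clf.predict_proba(stacks[te])[:, 1]
        pred = (prob > cfg["cnn"]["threshold"]).astype(int)
        true = labels[te]
        pd.DataFrame({"index": np.flatnonzero(te), "probability": prob,
                      "pred": pred, "label": true}).to_csv(
            run_dir / "predictions.csv", index=False)
        cm = ev.confusion(pred, true)
        rep = ev.metrics(cm)
        payload = {"confusion": asdict(cm), **rep.to_dict()}
        if len(np.unique(true)) == 2:
            _, auc = ev.roc_auc(prob, true)
            payload["auc"] = auc
        ev.probability_distribution_export(prob, pred, true,
                                           run_dir / "probabilities.csv")
        (run_dir / "metrics.json").write_text(json.dumps(payload, indent=2,
                                                         sort_keys=True))
        return pred, prob

    pred, prob = _stage(log, "evaluate", evaluate)

    # ---- localize --------------------------------------------------------
    def localize():
        lc = cfg["localize"]
        spacing = cfg["phantom"]["pixel_spacing"]
        radius = lc["se_radius"] or default_se_radius(spacing)
        loc = TopHatLocalizer(se_radius=radius, k_sigma=lc["k_sigma"],
                              min_area=lc["min_area"], max_area=lc["max_area"])
        test_idx = np.flatnonzero(te)
        rows = []
        for local_i, global_i in enumerate(test_idx):
            if not lc["all_images"] and pred[local_i] != 1:
                continue
            for cid, cand in enumerate(loc.detect(clean[global_i])):
                r0, c0, r1, c1 = cand.bbox
                rows.append({"image": int(global_i), "id": cid,
                             "row": cand.centroid[0], "col": cand.centroid[1],
                             "r0": r0, "c0": c0, "r1": r1, "c1": c1,
                             "area": cand.area, "score": cand.score})
        pd.DataFrame(rows, columns=["image", "id", "row", "col", "r0", "c0",
                                    "r1", "c1", "area", "score"]).to_csv(
            run_dir / "candidates.csv", index=False)
        return rows

    _stage(log, "localize", localize)
    log_fh.close()
    return run_dir
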