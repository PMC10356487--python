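"""End-to-end pipeline: simulate -> segment -> extract -> augment -> train -> evaluate.

Driven by a single YAML config with per-stage sections; every stage writes
its artifact under the output directory and the run closes with a manifest
(config hash, seeds, stage artifacts, package version) so results are
traceable and reruns are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .augmentation import augment, randomize_within_class
from .evaluation import evaluate_model, split_train_test
from .exceptions import ConfigurationError
from .features import FeatureConfig, extract_features
from .io_formats import write_feature_dataset, write_windows_csv
from .model import MultitaskLSTM, MultitaskModelConfig
from .preprocessing import match_windows_to_truth, segment_by_peaks
from .synthetic import SyntheticConfig, generate_dataset

#: config keys every pipeline run must provide
REQUIRED_KEYS = (
    "seed",
    "synthetic.n_subjects",
    "segment.window_len",
    "features.S",
    "features.L",
    "model.hidden_units",
    "model.iterations",
)

DEFAULTS = {
    "segment": {"peak_height": 12.0, "min_separation": None},
    "features": {"frame_len": 16, "hop": 8, "window_fn": "hamming"},
    "augment": {"levels": [1, 2], "shuffle_seed": 17},
    "evaluate": {"fraction": 0.8},
}


def _lookup(cfg: dict, dotted: str):
    node = cfg
    for part in dotted.split("."):
        if not isinstance(node, dict) or part not in node:
            return None
        node = node[part]
    return node


def validate_config(cfg: dict) -> None:
    """Raise a ConfigurationError naming every missing required key."""
    missing = [k for k in REQUIRED_KEYS if _lookup(cfg, k) is None]
    if missing:
        raise ConfigurationError(
            "pipeline config is missing required keys: " + ", ".join(missing)
        )


def _write_raw_csv(rec, path: Path) -> None:
    df = pd.DataFrame(
        np.column_stack([rec.timestamps, rec.accel, rec.gyro]),
        columns=["t", "ax", "ay", "az", "gx", "gy", "gz"],
    )
    df.to_csv(path, index=False, float_format="%.17g")


def run_pipeline(config, out_dir) -> dict:
    """Run every stage from one config; returns the manifest dict.

    ``config`` is a YAML file path or an already-parsed dict.  Any stage
    failure propagates with the stage name attached.
    """
    if isinstance(config, (str, Path)):
        raw_text = Path(config).read_text()
        cfg = yaml.safe_load(raw_text)
    else:
        cfg = config
        raw_text = yaml.safe_dump(cfg, sort_keys=True)
    validate_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "config_sha256": hashlib.sha256(raw_text.encode()).hexdigest(),
        "seed": seed,
        "stages": [],
    }

    def stage(name, fn):
        try:
            artifact = fn()
        except Exception as exc:  # annotate failures with the stage name
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages"].append({"name": name, "artifact": str(artifact)})

    state: dict = {}

    def do_simulate():
        syn = dict(cfg.get("synthetic", {}))
        syn.setdefault("seed", seed)
        recs, truth = generate_dataset(SyntheticConfig(**syn))
        raw_dir = out / "raw"
        raw_dir.mkdir(exist_ok=True)
        for rec in recs:
            _write_raw_csv(rec, raw_dir / f"{rec.subject_id}.csv")
        write_windows_csv(truth, raw_dir / "ground_truth.csv")
        state["recordings"], state["truth"] = recs, truth
        return raw_dir

    def do_segment():
        seg = {**DEFAULTS["segment"], **cfg["segment"]}
        labeled = []
        for rec in state["recordings"]:
            detected = segment_by_peaks(
                rec,
                window_len=int(seg["window_len"]),
                min_peak_height=float(seg["peak_height"]),
                min_separation=seg["min_separation"],
            )
            truth = [t for t in state["truth"] if t.subject_id == rec.subject_id]
            labeled.extend(match_windows_to_truth(detected, truth))
        state["windows"] = labeled
        path = out / "windows.csv"
        write_windows_csv(labeled, path)
        return path

    def do_extract():
        fc = {**DEFAULTS["features"], **cfg["features"]}
        fcfg = FeatureConfig(
            frame_len=int(fc["frame_len"]), hop=int(fc["hop"]),
            window_fn=fc["window_fn"], S=int(fc["S"]), L=int(fc["L"]),
        )
        state["samples"] = [extract_features(w, fcfg) for w in state["windows"]]
        return f"{len(state['samples'])} feature matrices (in memory)"

    def do_augment():
        ac = {**DEFAULTS["augment"], **cfg.get("augment", {})}
        ds = augment(state["samples"], levels=tuple(ac["levels"]))
        ds = randomize_within_class(ds, seed=int(ac["shuffle_seed"]))
        state["dataset"] = ds
        path = out / "augmented.csv"
        write_feature_dataset(ds, path)
        return path

    def do_train():
        mc = dict(cfg["model"])
        iterations = int(mc.pop("iterations"))
        mc.setdefault("seed", seed)
        frac = float({**DEFAULTS["evaluate"], **cfg.get("evaluate", {})}["fraction"])
        train, test = split_train_test(state["dataset"], fraction=frac, seed=seed)
        state["test"] = test
        mcfg = MultitaskModelConfig(iterations=iterations, **mc)
        model = MultitaskLSTM.from_dataset(train, config=mcfg)
        state["results"] = model.fit()
        model_dir = out / "model"
        state["results"].save(model_dir)
        return model_dir

    def do_evaluate():
        rep = evaluate_model(state["results"], state["test"])
        path = out / "metrics.json"
        with open(path, "w") as fh:
            json.dump(rep.as_dict(), fh, indent=1, sort_keys=True)
        return path

    stage("simulate", do_simulate)
    stage("segment", do_segment)
    stage("extract", do_extract)
    stage("augment", do_augment)
    stage("train", do_train)
    stage("evaluate", do_evaluate)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def demo_config(seed: int = 7) -> dict:
    """A small, fast configuration exercising all six stages."""
    return {
        "seed": seed,
        "synthetic": {
            "n_subjects": 3,
            "motions_per_subject_per_class": 10,
        },
        "segment": {"window_len": 128, "peak_height": 12.0},
        "features": {"S": 16, "L": 16},
        "augment": {"levels": [1, 2], "shuffle_seed": 17},
        "model": {"hidden_units": 32, "iterations": 200, "batch_size": 64},
        "evaluate": {"fraction": 0.8},
    }
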