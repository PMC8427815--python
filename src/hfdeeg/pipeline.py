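"""End-to-end analysis pipeline: simulate -> features -> compare -> classify.

A :class:`RunConfig` describes one fully seeded run: the synthetic study (or
an existing dataset directory), the feature-extraction settings, the group
pairs to compare, and the classification grids.  :func:`run_pipeline`
materialises a bundle directory::

    bundle/
      dataset/                  (optional copy of the generated dataset)
      features.csv
      comparison_<pair>_<task>_<offset>.csv
      eval_<task>.json
      transfer_<task>.json      (when a transfer source is configured)
      summary.txt
      run.json                  (config echo, config hash, seed)

Every artifact is derived deterministically from the config: rerunning the
same config reproduces the bundle bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .classify import ClassifierConfig, nested_loso_evaluate, transfer_evaluate
from .higuchi import HfdConfig, extract_features, write_features
from .stats import compare_groups
from .synthetic import (
    SynthConfig,
    generate_dataset,
    preset_config,
    read_dataset,
    write_dataset,
)

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    out_dir: Path
    synth: SynthConfig | None = None
    dataset_path: Path | None = None
    hfd: HfdConfig = field(default_factory=HfdConfig)
    comparison_pairs: list[tuple[str, str]] = field(default_factory=list)
    comparison_offsets: list[float] | None = None  # default: all HFD offsets
    bootstrap_m: int = 10_000
    p_nominal: float = 0.05
    classify_tasks: list[str] | None = None  # default: every task
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    transfer_source: dict | None = None  # {"channels": [...], "offset": float}
    save_dataset: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.synth is None) == (self.dataset_path is None):
            raise ValueError("configure exactly one of synth / dataset_path")
        if self.synth is not None:
            for pair in self.comparison_pairs:
                for g in pair:
                    if g not in self.synth.group_labels:
                        raise ValueError(f"comparison pair names unknown group {g!r}")

    def to_jsonable(self) -> dict:
        return {
            "synth": self.synth.to_jsonable() if self.synth else None,
            "dataset_path": str(self.dataset_path) if self.dataset_path else None,
            "hfd": {
                "k_max": self.hfd.k_max,
                "k_grid": list(self.hfd.k_grid),
                "window_length": self.hfd.window_length,
                "window_offsets": list(self.hfd.window_offsets),
            },
            "comparison_pairs": [list(p) for p in self.comparison_pairs],
            "comparison_offsets": self.comparison_offsets,
            "bootstrap_m": self.bootstrap_m,
            "p_nominal": self.p_nominal,
            "classify_tasks": self.classify_tasks,
            "classifier": {
                "nu_grid": list(self.classifier.nu_grid),
                "offset_grid": list(self.classifier.offset_grid),
                "kernel": self.classifier.kernel,
                "standardize": self.classifier.standardize,
                "svc_tol": self.classifier.svc_tol,
            },
            "transfer_source": self.transfer_source,
            "save_dataset": self.save_dataset,
            "seed": self.seed,
        }

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_run_config(path: str | Path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file.

    The ``synth`` section is either ``{preset: dataset1|dataset2, ...}`` or
    explicit :class:`SynthConfig` fields with a ``montage`` name/path.
    """
    import yaml

    from .montage import load_montage

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    seed = int(raw.get("seed", 0))
    synth = None
    if "synth" in raw:
        s = dict(raw["synth"])
        preset = s.pop("preset", None)
        if preset:
            synth = preset_config(preset, seed=seed, **{
                k: tuple(v) if isinstance(v, list) else v for k, v in s.items()
            })
        else:
            s["montage"] = load_montage(s["montage"])
            for key in ("tasks", "group_labels"):
                if key in s:
                    s[key] = tuple(s[key])
            synth = SynthConfig(seed=seed, **s)
    hfd = HfdConfig(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in raw.get("hfd", {}).items()
    })
    clf = ClassifierConfig(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in raw.get("classifier", {}).items()
    })
    return RunConfig(
        out_dir=Path(raw["out_dir"]),
        synth=synth,
        dataset_path=Path(raw["dataset_path"]) if raw.get("dataset_path") else None,
        hfd=hfd,
        comparison_pairs=[tuple(p) for p in raw.get("comparison_pairs", [])],
        comparison_offsets=raw.get("comparison_offsets"),
        bootstrap_m=int(raw.get("bootstrap_m", 10_000)),
        p_nominal=float(raw.get("p_nominal", 0.05)),
        classify_tasks=raw.get("classify_tasks"),
        classifier=clf,
        transfer_source=raw.get("transfer_source"),
        save_dataset=bool(raw.get("save_dataset", False)),
        seed=seed,
    )


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; partial artifacts are left in place."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.1f s", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis described by ``config``.

    Returns a manifest dict mapping artifact names to paths; the same
    manifest is written to ``run.json`` together with the config echo and
    hash.  Any stage failure raises :class:`PipelineStageError` naming the
    stage, leaving artifacts from completed stages behind.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash, "seed": config.seed,
                      "artifacts": {}}

    @_stage("simulate")
    def _simulate():
        if config.synth is not None:
            ds = generate_dataset(config.synth)
            if config.save_dataset:
                write_dataset(ds, out / "dataset")
                manifest["artifacts"]["dataset"] = "dataset"
            return ds
        return read_dataset(config.dataset_path)

    dataset = _simulate()

    @_stage("features")
    def _features():
        table = extract_features(dataset, config.hfd)
        write_features(table, out / "features.csv")
        manifest["artifacts"]["features"] = "features.csv"
        return table

    features = _features()

    @_stage("compare")
    def _compare():
        offsets = (config.comparison_offsets
                   if config.comparison_offsets is not None
                   else list(config.hfd.window_offsets))
        for pair in config.comparison_pairs:
            for task in dataset.tasks:
                frames = []
                for off in offsets:
                    res = compare_groups(
                        features, tuple(pair), task, off,
                        m=config.bootstrap_m, p_nominal=config.p_nominal,
                        seed=config.seed,
                    )
                    frames.append(res.to_frame())
                name = f"comparison_{pair[0]}-{pair[1]}_{task}.csv"
                pd.concat(frames, ignore_index=True).to_csv(out / name,
                                                            index=False)
                manifest["artifacts"][name] = name

    _compare()

    @_stage("classify")
    def _classify():
        if len(dataset.groups) != 2:
            logger.info("classification skipped: %d groups", len(dataset.groups))
            return
        tasks = config.classify_tasks or list(dataset.tasks)
        for task in tasks:
            report = nested_loso_evaluate(features, task, config.classifier)
            payload = report.to_jsonable()
            payload.update(config_hash=config.config_hash, seed=config.seed)
            path = out / f"eval_{task}.json"
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=1)
            report.predictions.to_csv(out / f"predictions_{task}.csv",
                                      index=False)
            manifest["artifacts"][f"eval_{task}"] = path.name

    _classify()

    @_stage("transfer")
    def _transfer():
        if not config.transfer_source or len(dataset.groups) != 2:
            return
        tasks = config.classify_tasks or list(dataset.tasks)
        src = config.transfer_source
        for task in tasks:
            report = transfer_evaluate(
                features, task, list(src["channels"]), float(src["offset"]),
                config.classifier,
            )
            payload = report.to_jsonable()
            payload.update(config_hash=config.config_hash, seed=config.seed,
                           transfer_source=src)
            path = out / f"transfer_{task}.json"
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=1)
            manifest["artifacts"][f"transfer_{task}"] = path.name

    _transfer()

    @_stage("report")
    def _report():
        lines = [
            "hfdeeg pipeline run",
            f"config hash : {config.config_hash}",
            f"seed        : {config.seed}",
            f"groups      : {', '.join(dataset.groups)}",
            f"tasks       : {', '.join(dataset.tasks)}",
            f"channels    : {len(dataset.montage)}",
            f"trials      : {dataset.data.shape[1]} per task",
            f"features    : {len(features)} rows "
            f"({int(features['hfd'].isna().sum())} missing)",
            "artifacts   :",
        ]
        lines += [f"  - {k}: {v}" for k, v in manifest["artifacts"].items()]
        (out / "summary.txt").write_text("\n".join(lines) + "\n")
        with open(out / "run.json", "w") as fh:
            json.dump({"config": config.to_jsonable(), **manifest}, fh, indent=1)

    _report()
    return manifest
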