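"""End-to-end experiment orchestration.

Pipeline: generate (or load) a 3-class image dataset -> stratified
80/10/10 split -> train the two branches (standardization fitted on the
training split inside each estimator; augmentation applied to the training
stream only) -> compute validation probability matrices -> SOA-optimize
the fusion weight on the validation split -> evaluate both branches and
the ensemble on the held-out test split -> write all artifacts.

Every stage is seeded from a single ``global_seed`` through fixed
per-stage offsets (see ``STAGE_OFFSETS``), so one integer reproduces the
whole run byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ensemble import EnsembleWeights, fuse_probabilities, optimize_weights
from .metrics import MetricsReport, full_report
from .models import (
    InternConfig,
    InternImageClassifier,
    LVMClassifier,
    LVMConfig,
    TrainConfig,
    save_checkpoint,
)
from .preprocess import AugmentationConfig
from .soa import SOAConfig
from .synth import CLASS_NAMES, LabeledDataset, SyntheticConfig, generate_dataset, split_dataset

logger = logging.getLogger("sharkfuse")

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
    "load_image_folder",
    "stage_seed",
    "STAGE_OFFSETS",
]

#: fixed per-stage seed offsets added to the global seed (mod 2**31)
STAGE_OFFSETS = {
    "data": 101,
    "split": 202,
    "lvm": 303,
    "intern": 404,
    "soa": 505,
    "bootstrap": 606,
}


def stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) + STAGE_OFFSETS[stage]) % 2**31


@dataclass(frozen=True)
class ExperimentConfig:
    """Full configuration of one run; defaults are the desk-scale protocol
    (CT profile, 100 images/class, 64x64 grayscale, 5 epochs/branch)."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    augmentation: AugmentationConfig | None = field(default_factory=AugmentationConfig)
    lvm: LVMConfig = field(default_factory=LVMConfig)
    intern: InternConfig = field(default_factory=InternConfig)
    training: TrainConfig = field(default_factory=lambda: TrainConfig(epochs=5))
    soa: SOAConfig = field(default_factory=SOAConfig)
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    data_dir: str | None = None  # load instead of generate when set
    output_dir: str | None = None
    global_seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["augmentation"] = None if self.augmentation is None else asdict(self.augmentation)
        return d

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(_tuples_to_lists(self.to_dict()), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        def tup2(x):
            return tuple(tuple(v) if isinstance(v, list) else v for v in x)

        kw = dict(d)
        if "synthetic" in kw and isinstance(kw["synthetic"], dict):
            s = dict(kw["synthetic"])
            if "image_size" in s:
                s["image_size"] = tuple(s["image_size"])
            kw["synthetic"] = SyntheticConfig(**s)
        if kw.get("augmentation") is not None and isinstance(kw["augmentation"], dict):
            a = dict(kw["augmentation"])
            if "scale_range" in a:
                a["scale_range"] = tuple(a["scale_range"])
            kw["augmentation"] = AugmentationConfig(**a)
        if "lvm" in kw and isinstance(kw["lvm"], dict):
            l = dict(kw["lvm"])
            if "conv_specs" in l:
                l["conv_specs"] = tup2(l["conv_specs"])
            if "fc_sizes" in l:
                l["fc_sizes"] = tuple(l["fc_sizes"])
            kw["lvm"] = LVMConfig(**l)
        if "intern" in kw and isinstance(kw["intern"], dict):
            i = dict(kw["intern"])
            if "inception_specs" in i:
                i["inception_specs"] = tup2(i["inception_specs"])
            kw["intern"] = InternConfig(**i)
        if "training" in kw and isinstance(kw["training"], dict):
            kw["training"] = TrainConfig(**kw["training"])
        if "soa" in kw and isinstance(kw["soa"], dict):
            s = dict(kw["soa"])
            if "bounds" in s:
                s["bounds"] = tuple(tuple(b) for b in s["bounds"])
            kw["soa"] = SOAConfig(**s)
        if "split_fractions" in kw:
            kw["split_fractions"] = tuple(kw["split_fractions"])
        return cls(**kw)

    def config_hash(self) -> str:
        canon = json.dumps(_tuples_to_lists(self.to_dict()), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _tuples_to_lists(x):
    if isinstance(x, dict):
        return {k: _tuples_to_lists(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_tuples_to_lists(v) for v in x]
    return x


@dataclass
class ExperimentResult:
    reports: dict[str, MetricsReport]  # keys: lvm, intern, ensemble
    weights: EnsembleWeights
    val_fitness: float
    lvm: LVMClassifier
    intern: InternImageClassifier
    dataset: LabeledDataset
    config: ExperimentConfig


def load_image_folder(root: str | Path, class_names=CLASS_NAMES) -> LabeledDataset:
    """Read ``<root>/<class>/*.png`` or ``<root>/<split>/<class>/*.png``.

    Files are taken in lexicographic order; labels follow directory
    membership in ``class_names`` order.
    """
    from PIL import Image, UnidentifiedImageError

    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root does not exist: {root}")
    split_dirs = [d for d in ("train", "val", "test", "all") if (root / d).is_dir()]
    groups = [(root / d, d) for d in split_dirs] if split_dirs else [(root, None)]
    images, labels, splits = [], [], []
    for base, split_name in groups:
        for k, cname in enumerate(class_names):
            cdir = base / cname
            if not cdir.is_dir():
                raise FileNotFoundError(f"missing class directory: {cdir}")
            files = sorted(p for p in cdir.iterdir() if p.is_file())
            if not files:
                logger.warning("class directory is empty: %s", cdir)
            for f in files:
                try:
                    with Image.open(f) as im:
                        arr = np.asarray(im, dtype=np.float32)
                except (UnidentifiedImageError, OSError) as exc:
                    raise ValueError(f"could not decode image file: {f}") from exc
                if arr.ndim == 2:
                    arr = arr[:, :, None]
                images.append(arr)
                labels.append(k)
                splits.append(split_name)
    split = None
    if any(s is not None and s != "all" for s in splits):
        split = np.array([s or "all" for s in splits], dtype="U5")
    return LabeledDataset(
        np.stack(images), np.asarray(labels, dtype=np.int64), tuple(class_names), split
    )


def _predictions_frame(probs: np.ndarray, labels: np.ndarray, class_names) -> pd.DataFrame:
    df = pd.DataFrame(probs, columns=[f"p_{c}" for c in class_names])
    df.insert(0, "sample_id", np.arange(len(labels)))
    df["label"] = labels
    df["pred"] = probs.argmax(axis=1)
    return df


def _history_frame(history: list[dict]) -> pd.DataFrame:
    cols = ["epoch", "train_loss", "val_loss", "train_acc", "val_acc"]
    df = pd.DataFrame(history)
    return df.reindex(columns=[c for c in cols if c in df.columns])


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full pipeline; writes artifacts when ``output_dir`` is set."""
    out = None
    file_handler = None
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        file_handler = logging.FileHandler(out / "run.log", mode="w")
        file_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logging.getLogger().addHandler(file_handler)
    g = config.global_seed
    try:
        stage = "generate"
        if config.data_dir is not None:
            dataset = load_image_folder(config.data_dir)
        else:
            dataset = generate_dataset(replace(config.synthetic, seed=stage_seed(g, "data")))
        logger.info("dataset: %d images, classes %s", len(dataset), dataset.class_names)

        stage = "split"
        dataset = split_dataset(dataset, config.split_fractions, seed=stage_seed(g, "split"))
        train, val, test = (dataset.subset(s) for s in ("train", "val", "test"))

        stage = "train-lvm"
        lvm = LVMClassifier(
            config.lvm, replace(config.training, seed=stage_seed(g, "lvm")),
            config.augmentation,
        ).fit(train.images, train.labels, val.images, val.labels)

        stage = "train-intern"
        intern = InternImageClassifier(
            config.intern, replace(config.training, seed=stage_seed(g, "intern")),
            config.augmentation,
        ).fit(train.images, train.labels, val.images, val.labels)

        stage = "fuse"
        p1_val = lvm.predict_proba(val.images)
        p2_val = intern.predict_proba(val.images)
        soa_cfg = replace(config.soa, seed=stage_seed(g, "soa"), bounds=((0.0, 1.0),))
        weights, val_fitness, _ = optimize_weights(p1_val, p2_val, val.labels, soa_cfg)
        logger.info("fusion weights: w1=%.4f w2=%.4f (val fitness %.4f)",
                    weights.omega1, weights.omega2, val_fitness)

        stage = "evaluate"
        p1_test = lvm.predict_proba(test.images)
        p2_test = intern.predict_proba(test.images)
        p_ens = fuse_probabilities(p1_test, p2_test, weights)
        reports = {
            "lvm": full_report(p1_test, test.labels, dataset.class_names),
            "intern": full_report(p2_test, test.labels, dataset.class_names),
            "ensemble": full_report(p_ens, test.labels, dataset.class_names),
        }
        for name, rep in reports.items():
            logger.info("%s test accuracy %.4f", name, rep.accuracy)

        stage = "write-artifacts"
        if out is not None:
            manifest = {
                "config": _tuples_to_lists(config.to_dict()),
                "config_hash": config.config_hash(),
                "stage_seeds": {s: stage_seed(g, s) for s in STAGE_OFFSETS},
                "n_train": len(train), "n_val": len(val), "n_test": len(test),
            }
            (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2))
            save_checkpoint(lvm, out / "lvm_checkpoint.npz")
            save_checkpoint(intern, out / "intern_checkpoint.npz")
            _history_frame(lvm.history_).to_csv(out / "lvm_history.csv", index=False)
            _history_frame(intern.history_).to_csv(out / "intern_history.csv", index=False)
            for name, probs in (("lvm", p1_test), ("intern", p2_test), ("ensemble", p_ens)):
                _predictions_frame(probs, test.labels, dataset.class_names).to_csv(
                    out / f"predictions_{name}.csv", index=False
                )
            (out / "ensemble_weights.json").write_text(
                json.dumps(
                    {"omega1": weights.omega1, "omega2": weights.omega2,
                     "val_fitness": val_fitness},
                    sort_keys=True, indent=2,
                )
            )
            for name, rep in reports.items():
                (out / f"metrics_{name}.json").write_text(rep.to_json())
        return ExperimentResult(
            reports=reports, weights=weights, val_fitness=val_fitness,
            lvm=lvm, intern=intern, dataset=dataset, config=config,
        )
    except Exception as exc:
        raise RuntimeError(f"experiment failed at stage {stage!r}: {exc}") from exc
    finally:
        if file_handler is not None:
            logging.getLogger().removeHandler(file_handler)
            file_handler.close()
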