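"""End-to-end orchestration: corpus -> (augment + contrastive pre-train)
-> fine-tune -> calibrate thresholds -> evaluate, with per-stage artifacts
stamped with the configuration hash and seed, resumable per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .augment import AugmentationConfig, load_synonym_lexicon
from .corpus import DEFAULT_MARKERS
from .evaluation import prf
from .io import read_instances
from .model import RelationClassifier, TrainConfig, prepare_samples, train_model
from .schema import ConstraintTable, N_LABELS, RelationLabel
from .thresholds import ThresholdTable, apply_thresholds, fit_thresholds

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "write_predictions", "read_predictions"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a full training-and-evaluation run."""

    corpus_path: str
    out_dir: str
    constraints_path: str | None = None
    lexicon_path: str | None = None
    hierarchy_path: str | None = None
    representation: str = "mention"
    contrastive: bool = False
    train: TrainConfig = field(default_factory=TrainConfig)
    hidden_size: int = 64
    n_layers: int = 2
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("corpus_path", "constraints_path", "lexicon_path", "hierarchy_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        if self.representation not in ("mention", "semtype", "semgroup"):
            raise ValueError(f"invalid representation {self.representation!r}")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def write_predictions(
    path: str | Path,
    ids: list[str],
    gold: list[RelationLabel],
    pred: list[RelationLabel],
    probs: np.ndarray,
) -> None:
    """Predictions TSV: instance id, gold, predicted, 23 probabilities."""
    cols = ["instance_id", "gold", "predicted"] + [
        f"p_{lab.name}" for lab in RelationLabel.ordered()
    ]
    rows = [
        [i, g.name, q.name] + [f"{p:.6g}" for p in row]
        for i, g, q, row in zip(ids, gold, pred, probs)
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path):
    df = pd.read_csv(path, sep="\t")
    gold = [RelationLabel.from_name(g) for g in df["gold"]]
    pred = [RelationLabel.from_name(p) for p in df["predicted"]]
    probs = df[[f"p_{lab.name}" for lab in RelationLabel.ordered()]].to_numpy(float)
    return list(df["instance_id"]), gold, pred, probs


def _stage_done(out: Path, name: str, resume: bool) -> bool:
    return resume and (out / name).exists()


def run_pipeline(config: RunConfig, resume: bool = True) -> dict:
    """Execute train -> calibrate -> evaluate; every artifact is stamped
    with the config hash and seed.  A failing stage raises an error naming
    the stage.  Returns the evaluation summary."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    (out / "run.json").write_text(
        json.dumps({**stamp, "config": asdict(config)}, indent=2), encoding="utf-8"
    )

    instances = read_instances(config.corpus_path)
    aug = None
    if config.lexicon_path:
        aug = AugmentationConfig(
            synonym_lexicon=load_synonym_lexicon(config.lexicon_path),
            seed=config.train.seed,
        )

    # stage: train
    ckpt = out / "checkpoint"
    try:
        if _stage_done(out, "checkpoint", resume):
            clf = RelationClassifier.load(ckpt)
            history = json.loads((out / "history.json").read_text())
        else:
            clf, history = train_model(
                instances,
                config.train,
                pretrain=config.contrastive,
                representation=config.representation,
                aug_config=aug,
                hidden_size=config.hidden_size,
                n_layers=config.n_layers,
            )
            clf.save(ckpt, config.train)
            (out / "history.json").write_text(json.dumps({**stamp, **history}))
    except Exception as exc:
        raise RuntimeError(f"stage 'train' failed: {exc}") from exc

    # stage: calibrate
    try:
        if _stage_done(out, "thresholds.tsv", resume):
            thresholds = ThresholdTable.from_tsv(out / "thresholds.tsv")
        else:
            val = [i for i in instances if i.split == "val"]
            val_samples = prepare_samples(val, config.representation)
            val_probs = clf.predict_proba(val_samples)
            thresholds = fit_thresholds(val_probs, [i.label for i in val])
            thresholds.to_tsv(out / "thresholds.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage 'calibrate' failed: {exc}") from exc

    # stage: evaluate
    try:
        test = [i for i in instances if i.split == "test"]
        test_samples = prepare_samples(test, config.representation)
        probs = clf.predict_proba(test_samples)
        pred = [apply_thresholds(p, thresholds) for p in probs]
        gold = [i.label for i in test]
        report = prf(gold, pred, probs=probs)
        write_predictions(
            out / "predictions.tsv", [i.instance_id for i in test], gold, pred, probs
        )
        summary = {
            **stamp,
            "micro": {
                "precision": report.micro_precision,
                "recall": report.micro_recall,
                "f1": report.micro_f1,
            },
            "macro": {
                "precision": report.macro_precision,
                "recall": report.macro_recall,
                "f1": report.macro_f1,
            },
            "auc": report.auc,
            "n_test": len(test),
            "history": history,
        }
        (out / "report.json").write_text(json.dumps(summary, indent=2), encoding="utf-8")
    except Exception as exc:
        raise RuntimeError(f"stage 'evaluate' failed: {exc}") from exc
    return summary
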