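"""Training, evaluation, splits and ablations.

Defaults mirror the reference configuration: Adam with initial learning
rate 1e-4, batch size 64, at most 100 epochs with early stopping, feature
width 128, 8 attention heads, results aggregated over 10 random seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold
from sklearn.metrics import roc_auc_score

from .ampnn import GraphBatch
from .autodiff import no_grad
from .fcs import FCSVocabulary, mine_vocabulary
from .fusion import loss_classification, loss_regression
from .knowledge import KnowledgeBase, build_knowledge_base
from .model import ABLATIONS, ModelConfig, MoleculeFeaturizer, SGATT
from .molio import PropertyDataset
from .nn import Adam

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    lr: float = 1e-4
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 15
    seeds: Sequence[int] = tuple(range(10))
    split: str = "scaffold"  # or "random"
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    ablation: str = "full"
    metric: str | None = None  # default: roc_auc (classification) / rmse (regression)
    # model hyperparameters
    dim: int = 128
    seq_heads: int = 8
    seq_layers: int = 4
    fusion_heads: int = 8
    rounds: int = 3
    aggregation: str = "sum"
    set2set_steps: int = 3
    max_len: int = 256
    dropout: float = 0.1
    # featurization / vocabulary
    explicit_h: bool | None = None
    n_bins: int = 5
    fcs_min_freq: int = 5
    fcs_max_token_len: int = 8
    fcs_max_vocab: int = 1024

    def __post_init__(self):
        if self.ablation not in ABLATIONS:
            raise ValueError(f"ablation must be one of {ABLATIONS}")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.fractions}")

    def model_config(self) -> ModelConfig:
        return ModelConfig(
            dim=self.dim,
            seq_heads=self.seq_heads,
            seq_layers=self.seq_layers,
            fusion_heads=self.fusion_heads,
            rounds=self.rounds,
            aggregation=self.aggregation,
            set2set_steps=self.set2set_steps,
            max_len=self.max_len,
            dropout=self.dropout,
            ablation=self.ablation,
        )

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def _scaffold_key(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol) if mol is not None else smiles


def split_dataset(
    ds: PropertyDataset,
    method: str = "scaffold",
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[PropertyDataset, PropertyDataset, PropertyDataset]:
    """Partition a dataset into train/valid/test.

    Scaffold splitting groups molecules by Bemis–Murcko scaffold and fills
    the partitions largest-group-first (structurally novel test set);
    random splitting shuffles by seed. Falls back to random with a warning
    when every molecule shares one scaffold.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    n = len(ds)
    n_train = int(round(fractions[0] * n))
    n_valid = int(round(fractions[1] * n))
    rng = np.random.default_rng(seed)

    if method == "scaffold":
        groups: dict[str, list[int]] = {}
        for i, smi in enumerate(ds.smiles):
            groups.setdefault(_scaffold_key(smi), []).append(i)
        if len(groups) <= 1:
            logger.warning("all molecules share one scaffold; falling back to random split")
            method = "random"
        else:
            order = sorted(groups.values(), key=lambda g: (-len(g), g[0]))
            train, valid, test = [], [], []
            for g in order:
                if len(train) + len(g) <= n_train:
                    train.extend(g)
                elif len(valid) + len(g) <= n_valid:
                    valid.extend(g)
                else:
                    test.extend(g)
            parts = (train, valid, test)

    if method == "random":
        perm = rng.permutation(n)
        parts = (
            list(perm[:n_train]),
            list(perm[n_train : n_train + n_valid]),
            list(perm[n_train + n_valid :]),
        )
    elif method != "scaffold":
        raise ValueError(f"unknown split method {method!r}")

    if any(len(p) == 0 for p in parts):
        raise ValueError(
            f"empty partition from split (sizes {[len(p) for p in parts]}); "
            "use more data or different fractions"
        )
    return tuple(ds.subset(sorted(p)) for p in parts)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _predict_all(
    model: SGATT, featurizer: MoleculeFeaturizer, ds: PropertyDataset, batch_size: int = 64
) -> np.ndarray:
    model.eval()
    preds = []
    with no_grad():
        for lo in range(0, len(ds), batch_size):
            smiles = ds.smiles[lo : lo + batch_size]
            toks, graphs = featurizer.featurize_batch(smiles)
            batch = GraphBatch.from_graphs(graphs, model.label_index)
            preds.append(model(toks, batch).data)
    model.train()
    return np.concatenate(preds, axis=0)


def compute_metrics(
    y: np.ndarray, mask: np.ndarray, preds: np.ndarray, task_type: str
) -> dict[str, float]:
    """Per-task metrics plus macro aggregate.

    Classification: masked per-task ROC-AUC (single-class tasks excluded
    with a warning). Regression: RMSE and MAE over all unmasked entries.
    """
    if task_type == "classification":
        aucs = []
        for t in range(y.shape[1]):
            m = mask[:, t]
            if m.sum() == 0 or len(np.unique(y[m, t])) < 2:
                logger.warning("task %d has a single class in this split; AUC undefined", t)
                continue
            aucs.append(roc_auc_score(y[m, t], preds[m, t]))
        if not aucs:
            return {"roc_auc": float("nan")}
        return {"roc_auc": float(np.mean(aucs))}
    m = mask.astype(bool)
    err = preds[m] - y[m]
    return {"rmse": float(np.sqrt(np.mean(err**2))), "mae": float(np.mean(np.abs(err)))}


def evaluate(
    model: SGATT,
    featurizer: MoleculeFeaturizer,
    ds: PropertyDataset,
    batch_size: int = 64,
) -> dict[str, float]:
    preds = _predict_all(model, featurizer, ds, batch_size)
    return compute_metrics(ds.labels(), ds.masks(), preds, ds.task_type)


@dataclass
class EvalReport:
    metric_name: str
    per_seed: list[dict]
    mean: float
    sd: float
    config_hash: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class Checkpoint:
    state: dict[str, np.ndarray]
    vocab: FCSVocabulary
    config: TrainConfig
    n_tasks: int
    task_type: str

    def save(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "state.npz", **self.state)
        self.vocab.save(d / "vocab.txt")
        (d / "meta.json").write_text(
            json.dumps(
                {
                    "config": asdict(self.config),
                    "n_tasks": self.n_tasks,
                    "task_type": self.task_type,
                },
                default=list,
            )
        )

    @classmethod
    def load(cls, directory) -> "Checkpoint":
        from pathlib import Path

        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        cfg = meta["config"]
        cfg["fractions"] = tuple(cfg["fractions"])
        with np.load(d / "state.npz") as npz:
            state = {k: npz[k] for k in npz.files}
        return cls(
            state=state,
            vocab=FCSVocabulary.load(d / "vocab.txt"),
            config=TrainConfig(**cfg),
            n_tasks=int(meta["n_tasks"]),
            task_type=meta["task_type"],
        )

    def build_model(self, kb: KnowledgeBase | None = None) -> tuple[SGATT, MoleculeFeaturizer]:
        kb = kb or build_knowledge_base(n_bins=self.config.n_bins)
        model = SGATT(
            self.vocab,
            kb,
            self.n_tasks,
            self.task_type,
            self.config.model_config(),
            np.random.default_rng(0),
        )
        model.load_state_dict(self.state)
        featurizer = MoleculeFeaturizer(self.vocab, kb, self.config.explicit_h)
        return model, featurizer


@dataclass
class TrainResult:
    checkpoint: Checkpoint  # best seed's best-validation checkpoint
    report: EvalReport
    history: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _metric_name(config: TrainConfig, task_type: str) -> str:
    if config.metric:
        return config.metric
    return "roc_auc" if task_type == "classification" else "rmse"


def _better(a: float, b: float, higher_is_better: bool) -> bool:
    if np.isnan(b):
        return True
    return a > b if higher_is_better else a < b


def train_single_seed(
    config: TrainConfig,
    dataset: PropertyDataset,
    seed: int,
    kb: KnowledgeBase | None = None,
) -> tuple[Checkpoint | None, dict, list[dict]]:
    """Train one seed; returns (checkpoint, summary, per-epoch history).

    The FCS vocabulary is mined on the training split only. Early stopping
    watches the validation metric; a NaN loss aborts the seed.
    """
    metric = _metric_name(config, dataset.task_type)
    higher = metric == "roc_auc"
    rng = np.random.default_rng(seed)

    train_ds, valid_ds, test_ds = split_dataset(dataset, config.split, config.fractions, seed)
    vocab = mine_vocabulary(
        [r[0] for r in train_ds.records],
        min_freq=config.fcs_min_freq,
        max_token_len=config.fcs_max_token_len,
        max_vocab=config.fcs_max_vocab,
    )
    # make held-out molecules tokenizable: extend the alphabet with their characters
    extra = {ch for ds_ in (valid_ds, test_ds) for smi in ds_.smiles for ch in smi}
    for ch in sorted(extra):
        vocab.tokens.setdefault(ch, 0)
    vocab.__post_init__()

    kb = kb or build_knowledge_base(n_bins=config.n_bins)
    model = SGATT(
        vocab, kb, len(dataset.task_names), dataset.task_type, config.model_config(), rng
    )
    featurizer = MoleculeFeaturizer(vocab, kb, config.explicit_h)
    optimizer = Adam(model.parameters(), lr=config.lr)

    y_train, m_train = train_ds.labels(), train_ds.masks()
    best_state: dict[str, np.ndarray] | None = None
    best_val = float("nan")
    epochs_since_improve = 0
    history: list[dict] = []

    for epoch in range(config.max_epochs):
        model.train()
        perm = rng.permutation(len(train_ds))
        epoch_losses = []
        for lo in range(0, len(perm), config.batch_size):
            idx = perm[lo : lo + config.batch_size]
            smiles = [train_ds.smiles[i] for i in idx]
            toks, graphs = featurizer.featurize_batch(smiles)
            batch = GraphBatch.from_graphs(graphs, model.label_index)
            preds = model(toks, batch)
            if dataset.task_type == "classification":
                loss = loss_classification(y_train[idx], preds, m_train[idx])
            else:
                loss = loss_regression(y_train[idx], preds)
            if not np.isfinite(loss.data):
                logger.error("seed %d: non-finite loss at epoch %d; aborting seed", seed, epoch)
                return None, {"seed": seed, "failed": True}, history
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(loss.item())

        val_metrics = evaluate(model, featurizer, valid_ds, config.batch_size)
        val = val_metrics[metric]
        history.append(
            {"epoch": epoch, "loss": float(np.mean(epoch_losses)), f"valid_{metric}": val}
        )
        logger.info("seed %d epoch %d loss %.4f valid %s %.4f", seed, epoch, history[-1]["loss"], metric, val)
        if _better(val, best_val, higher):
            best_val = val
            best_state = model.state_dict()
            epochs_since_improve = 0
        else:
            epochs_since_improve += 1
            if epochs_since_improve > config.patience:
                break

    if best_state is not None:
        model.load_state_dict(best_state)
    test_metrics = evaluate(model, featurizer, test_ds, config.batch_size)
    ckpt = Checkpoint(
        state=model.state_dict(),
        vocab=vocab,
        config=config,
        n_tasks=len(dataset.task_names),
        task_type=dataset.task_type,
    )
    summary = {"seed": seed, "failed": False, f"valid_{metric}": best_val, **{f"test_{k}": v for k, v in test_metrics.items()}}
    return ckpt, summary, history


def train(config: TrainConfig, dataset: PropertyDataset) -> TrainResult:
    """Train over all configured seeds and aggregate test metrics."""
    metric = _metric_name(config, dataset.task_type)
    higher = metric == "roc_auc"
    kb = build_knowledge_base(n_bins=config.n_bins)
    per_seed, checkpoints, all_hist = [], [], []
    for seed in config.seeds:
        ckpt, summary, history = train_single_seed(config, dataset, seed, kb)
        per_seed.append(summary)
        checkpoints.append(ckpt)
        all_hist.extend({"seed": seed, **h} for h in history)

    ok = [s for s in per_seed if not s.get("failed")]
    if not ok:
        raise RuntimeError("all seeds diverged")
    # seeds whose split left a task single-class report NaN; exclude from aggregate
    values = [v for s in ok if np.isfinite(v := s[f"test_{metric}"])]
    if not values:
        values = [float("nan")]
    best_idx = max(
        range(len(per_seed)),
        key=lambda i: (
            not per_seed[i].get("failed"),
            per_seed[i].get(f"valid_{metric}", -np.inf) * (1 if higher else -1),
        ),
    )
    report = EvalReport(
        metric_name=metric,
        per_seed=per_seed,
        mean=float(np.mean(values)),
        sd=float(np.std(values)),
        config_hash=config.hash(),
    )
    return TrainResult(checkpoint=checkpoints[best_idx], report=report, history=all_hist)


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------

def export_embeddings(
    model: SGATT, featurizer: MoleculeFeaturizer, smiles: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
    """Fused embedding per molecule plus the pairwise cosine-similarity table.

    Returns (embeddings, cosine matrix, failures) where failures lists
    (smiles, reason) for molecules that could not be featurised.
    """
    vecs, failures, kept = [], [], []
    model.eval()
    with no_grad():
        for smi in smiles:
            try:
                toks, graph = featurizer.featurize(smi)
                vecs.append(model.fuse([toks], [graph]).data[0])
                kept.append(smi)
            except Exception as exc:  # noqa: BLE001 - report and continue
                failures.append((smi, str(exc)))
    model.train()
    if not vecs:
        return np.zeros((0, model.config.dim)), np.zeros((0, 0)), failures
    emb = np.stack(vecs)
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    unit = emb / norms
    return emb, unit @ unit.T, failures
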