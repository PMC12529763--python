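"""Integrated bioactivity learning.

All curated training records — Ki, Kd, EC50 and IC50 pooled, with the type kept
as metadata only — feed one regressor.  Two 5-fold cross-validation cycles each
train five members: cycle one selects each member's best epoch on its held-out
fold, cycle two selects against a Ki-distribution-matched subsample of the fold
(equal draws across 0.5-log bins), favouring models that stay accurate on the
highest-quality assay type.  The ten members form the ensemble; the prediction
is their mean and the (n-1) standard deviation across members is the model
uncertainty.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import KFold

from . import nn
from .model import BatchedMolGraph, GGAPModel, ModelConfig, MolGraph, batch_molgraphs, featurize_molecule
from .protein import ProtGraph, build_protein_graph
from .records import ActivityType, BioactivityRecord, ProteinEntry

logger = logging.getLogger("ggapcpi")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 256
    epochs: int = 100
    learning_rate: float = 1e-4
    n_folds: int = 5
    n_cycles: int = 2
    ref_type: ActivityType = ActivityType.Ki
    validation_bin_width: float = 0.5
    seed: int = 0


@dataclass(frozen=True)
class TrainExample:
    smiles: str
    target_id: str
    activity_type: ActivityType
    value: float


class CPIDataset:
    """Featurized (molecule, protein, pActivity) examples ready for training."""

    def __init__(
        self,
        examples: Sequence[TrainExample],
        mol_graphs: Mapping[str, MolGraph],
        prot_graphs: Mapping[str, ProtGraph],
    ):
        for ex in examples:
            if ex.smiles not in mol_graphs:
                raise ValueError(f"no molecular graph for {ex.smiles}")
            if ex.target_id not in prot_graphs:
                raise ValueError(f"no protein graph for {ex.target_id}")
        self.examples = list(examples)
        self.mol_graphs = dict(mol_graphs)
        self.prot_graphs = dict(prot_graphs)

    def __len__(self) -> int:
        return len(self.examples)

    def subset(self, indices: Sequence[int]) -> "CPIDataset":
        return CPIDataset([self.examples[i] for i in indices], self.mol_graphs, self.prot_graphs)

    def values(self) -> np.ndarray:
        return np.array([ex.value for ex in self.examples])

    def batches(self, batch_size: int, rng: np.random.Generator | None = None):
        order = np.arange(len(self.examples))
        if rng is not None:
            order = rng.permutation(order)
        for start in range(0, len(order), batch_size):
            idx = order[start : start + batch_size]
            exs = [self.examples[i] for i in idx]
            yield (
                batch_molgraphs([self.mol_graphs[e.smiles] for e in exs]),
                [e.target_id for e in exs],
                np.array([e.value for e in exs]),
            )


def prepare_dataset(
    records: Sequence[BioactivityRecord],
    proteins: Sequence[ProteinEntry],
    graph_mode: str = "sequence",
) -> CPIDataset:
    """Featurize curated records and proteins into a trainable dataset."""
    examples = [
        TrainExample(r.smiles, r.target_id, r.activity_type, r.value)
        for r in records
        if r.value is not None
    ]
    mol_graphs = {s: featurize_molecule(s) for s in sorted({e.smiles for e in examples})}
    prot_graphs = {p.target_id: build_protein_graph(p, graph_mode) for p in proteins}
    return CPIDataset(examples, mol_graphs, prot_graphs)


def make_integrated_dataset(
    records: Sequence[BioactivityRecord],
    split,
    proteins: Sequence[ProteinEntry],
    partition: str = "train",
    per_type: bool = False,
    graph_mode: str = "sequence",
):
    """Pool the records of one split partition across activity types.

    ``split`` is the table produced by the splitting stage (columns smiles,
    target_id, activity_type, partition).  With ``per_type`` the pooled set is
    partitioned into one dataset per activity type (the non-integrated
    training variant).
    """
    assigned, wanted = set(), set()
    for row in split.itertuples(index=False):
        key = (row.smiles, row.target_id, row.activity_type)
        assigned.add(key)
        if row.partition == partition:
            wanted.add(key)
    keys = [(r.smiles, r.target_id, r.activity_type.value) for r in records]
    unassigned = sum(1 for r, k in zip(records, keys) if r.value is not None and k not in assigned)
    if unassigned:
        raise ValueError(f"{unassigned} records lack a split assignment")
    chosen = [r for r, k in zip(records, keys) if r.value is not None and k in wanted]
    if not chosen:
        raise ValueError(f"no records in partition {partition!r}")
    if not per_type:
        return prepare_dataset(chosen, proteins, graph_mode)
    by_type: dict[ActivityType, list[BioactivityRecord]] = {}
    for r in chosen:
        by_type.setdefault(r.activity_type, []).append(r)
    return {t: prepare_dataset(rs, proteins, graph_mode) for t, rs in by_type.items()}


def sample_type_matched_validation(
    dataset: CPIDataset,
    ref_type: ActivityType = ActivityType.Ki,
    seed: int = 0,
    bin_width: float = 0.5,
    budget: int | None = None,
) -> CPIDataset:
    """Histogram-stratified subsample of the reference assay type.

    Values are binned at ``bin_width`` log units; draws are allocated equally
    across occupied bins (spare quota flows to bins that still have members)
    up to ``budget``.  ``budget=None`` keeps every reference-type record.
    """
    idx = [i for i, ex in enumerate(dataset.examples) if ex.activity_type == ref_type]
    if not idx:
        raise ValueError(f"validation set has no {ref_type.value} records")
    if budget is None or budget >= len(idx):
        return dataset.subset(idx)
    rng = np.random.default_rng(seed)
    bins: dict[int, list[int]] = {}
    for i in idx:
        bins.setdefault(int(np.floor(dataset.examples[i].value / bin_width)), []).append(i)
    pools = [list(rng.permutation(members)) for _, members in sorted(bins.items())]
    chosen: list[int] = []
    while len(chosen) < budget and any(pools):
        quota = max(1, (budget - len(chosen)) // max(1, sum(1 for p in pools if p)))
        for p in pools:
            take = min(quota, len(p), budget - len(chosen))
            for _ in range(take):
                chosen.append(p.pop())
            if len(chosen) >= budget:
                break
    return dataset.subset(sorted(chosen))


@dataclass
class MemberProvenance:
    cycle: int
    fold: int
    best_epoch: int
    validation_mse: float


@dataclass
class PredictionWithUncertainty:
    mean: float
    std: float
    members: np.ndarray
    error: str | None = None


class EnsembleModel:
    """Ordered ensemble of trained members sharing one architecture."""

    def __init__(self, members: Sequence[GGAPModel], provenance: Sequence[MemberProvenance]):
        if not members:
            raise ValueError("ensemble needs at least one member")
        configs = {
            json.dumps({k: v for k, v in vars(m.config).items() if k != "seed"},
                       default=str, sort_keys=True)
            for m in members
        }
        if len(configs) > 1:
            raise ValueError("ensemble members must share one architecture config")
        self.members = list(members)
        self.provenance = list(provenance)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def config(self) -> ModelConfig:
        return self.members[0].config

    def predict_batch(
        self, batch: BatchedMolGraph, prot_graphs: Mapping[str, ProtGraph], pair_proteins
    ) -> list[PredictionWithUncertainty]:
        preds = np.stack([m.predict(batch, prot_graphs, pair_proteins) for m in self.members])
        out = []
        for j in range(preds.shape[1]):
            col = preds[:, j]
            std = float(col.std(ddof=1)) if len(col) > 1 else 0.0
            out.append(PredictionWithUncertainty(float(col.mean()), std, col.copy()))
        return out

    def predict_pairs(
        self,
        pairs: Sequence[tuple[str, str]],
        prot_graphs: Mapping[str, ProtGraph],
        mol_graphs: Mapping[str, MolGraph] | None = None,
    ) -> list[PredictionWithUncertainty]:
        """Predict (smiles, target_id) pairs; unfeaturizable molecules yield a
        per-pair error entry and the batch continues."""
        results: list[PredictionWithUncertainty | None] = [None] * len(pairs)
        good, graphs = [], []
        for i, (smi, _) in enumerate(pairs):
            try:
                g = mol_graphs[smi] if mol_graphs and smi in mol_graphs else featurize_molecule(smi)
                graphs.append(g)
                good.append(i)
            except (ValueError, KeyError) as exc:
                results[i] = PredictionWithUncertainty(
                    float("nan"), float("nan"), np.array([]), error=str(exc)
                )
        if good:
            batch = batch_molgraphs(graphs)
            preds = self.predict_batch(batch, prot_graphs, [pairs[i][1] for i in good])
            for i, p in zip(good, preds):
                results[i] = p
        return results  # type: ignore[return-value]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, m in enumerate(self.members):
            m.save(directory / f"member_{i}.npz")
        meta = [vars(p) for p in self.provenance]
        (directory / "ensemble.json").write_text(json.dumps({"provenance": meta}))

    @classmethod
    def load(cls, directory: str | Path) -> "EnsembleModel":
        directory = Path(directory)
        meta = json.loads((directory / "ensemble.json").read_text())
        members = [
            GGAPModel.load(p) for p in sorted(directory.glob("member_*.npz"))
        ]
        prov = [MemberProvenance(**d) for d in meta["provenance"]]
        return cls(members, prov)


def _validation_mse(
    model: GGAPModel, dataset: CPIDataset, batch_size: int
) -> float:
    errs = []
    for batch, prots, y in dataset.batches(batch_size):
        pred = model.predict(batch, dataset.prot_graphs, prots)
        errs.append((pred - y) ** 2)
    return float(np.concatenate(errs).mean())


def train_member(
    model: GGAPModel,
    train_set: CPIDataset,
    val_set: CPIDataset,
    config: TrainConfig,
    rng: np.random.Generator,
) -> tuple[GGAPModel, int, float, list[float]]:
    """Train one member; the epoch checkpoint with best validation MSE wins."""
    optimizer = nn.Adam(model.parameters(), lr=config.learning_rate)
    best_state = model.state_dict()
    best_mse = _validation_mse(model, val_set, config.batch_size)
    best_epoch = 0
    history = []
    for epoch in range(1, config.epochs + 1):
        model.train()
        for batch, prots, y in train_set.batches(config.batch_size, rng):
            pred = model.forward(batch, train_set.prot_graphs, prots)
            loss = nn.mse_loss(pred, y)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
        model.eval()
        mse = _validation_mse(model, val_set, config.batch_size)
        history.append(mse)
        if mse < best_mse:
            best_mse, best_epoch = mse, epoch
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    return model, best_epoch, best_mse, history


def train_ensemble(
    dataset: CPIDataset,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
) -> EnsembleModel:
    """Dual 5-fold cross-validation producing the 10-member ensemble.

    Cycle one validates each fold on its raw held-out part; cycle two
    re-partitions independently and validates on the Ki-matched subsample of
    the held-out part (falling back, with a warning, to the raw part when the
    fold holds no reference-type records).  Fully deterministic under the
    config seeds.
    """
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    if len(dataset) < train_config.n_folds:
        raise ValueError(
            f"dataset of {len(dataset)} examples cannot be split into "
            f"{train_config.n_folds} folds"
        )
    members, provenance = [], []
    member_id = 0
    for cycle in range(train_config.n_cycles):
        kf = KFold(
            n_splits=train_config.n_folds,
            shuffle=True,
            random_state=train_config.seed + cycle,
        )
        for fold, (tr_idx, va_idx) in enumerate(kf.split(np.arange(len(dataset)))):
            train_set = dataset.subset(tr_idx)
            val_set = dataset.subset(va_idx)
            if cycle >= 1:
                try:
                    val_set = sample_type_matched_validation(
                        val_set,
                        ref_type=train_config.ref_type,
                        seed=train_config.seed + member_id,
                        bin_width=train_config.validation_bin_width,
                    )
                except ValueError:
                    logger.warning(
                        "cycle %d fold %d: no %s records in the validation fold; "
                        "using the full fold",
                        cycle,
                        fold,
                        train_config.ref_type.value,
                    )
            cfg = ModelConfig(**{**vars(model_config), "seed": model_config.seed + member_id})
            model = GGAPModel(cfg)
            rng = np.random.default_rng(train_config.seed * 1000 + member_id)
            model, best_epoch, best_mse, _ = train_member(
                model, train_set, val_set, train_config, rng
            )
            members.append(model)
            provenance.append(MemberProvenance(cycle, fold, best_epoch, best_mse))
            member_id += 1
    return EnsembleModel(members, provenance)


def fine_tune(
    model: GGAPModel | EnsembleModel,
    dataset: CPIDataset,
    train_config: TrainConfig,
) -> GGAPModel | EnsembleModel:
    """Continue training with every parameter trainable.

    Zero epochs returns the model unchanged.  Callers are responsible for
    removing overlap with the original training data (see
    :func:`remove_overlap`).
    """
    if isinstance(model, EnsembleModel):
        tuned = [fine_tune(m, dataset, train_config) for m in model.members]
        return EnsembleModel(tuned, model.provenance)
    if train_config.epochs == 0:
        return model
    rng = np.random.default_rng(train_config.seed)
    optimizer = nn.Adam(model.parameters(), lr=train_config.learning_rate)
    for _ in range(train_config.epochs):
        model.train()
        for batch, prots, y in dataset.batches(train_config.batch_size, rng):
            pred = model.forward(batch, dataset.prot_graphs, prots)
            loss = nn.mse_loss(pred, y)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
    model.eval()
    return model


def remove_overlap(
    records: Sequence[BioactivityRecord], reference: Sequence[BioactivityRecord]
) -> list[BioactivityRecord]:
    """Drop records whose (molecule, target, value) already occur in reference —
    the leakage guard applied before fine-tuning or external evaluation."""
    seen = {(r.smiles, r.target_id, r.value) for r in reference}
    return [r for r in records if (r.smiles, r.target_id, r.value) not in seen]
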