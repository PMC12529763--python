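"""High-level model/results interface over the pipeline.

:class:`CPIBioactivityModel` bundles curated records and proteins the way a
statistical model bundles data and design: construct it from a record table
(or a DataFrame via :meth:`from_dataframe`), call :meth:`fit`, and receive a
:class:`CPIBioactivityResults` carrying the trained ensemble, per-pair
predictions with uncertainties, general and cliff metrics, and a
``summary()`` table.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cliffs import split_dataset
from .curation import curate
from .evaluation import MetricReport, cliff_metrics, regression_metrics
from .model import ModelConfig
from .records import BioactivityRecord, ProteinEntry, parse_activity_type, parse_relation
from .standardize import standardize_batch
from .training import (
    EnsembleModel,
    TrainConfig,
    make_integrated_dataset,
    train_ensemble,
)


class CPIBioactivityModel:
    """Compound–protein bioactivity regression on a curated record table."""

    def __init__(
        self,
        records: Sequence[BioactivityRecord],
        proteins: Sequence[ProteinEntry],
        model_config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
        n_clusters: int = 50,
        train_frac: float = 0.8,
        seed: int = 0,
        curate_records: bool = True,
    ):
        self.model_config = model_config or ModelConfig()
        self.train_config = train_config or TrainConfig(seed=seed)
        self.proteins = list(proteins)
        self.seed = seed
        if curate_records:
            self.records, self.curation_report = curate(records)
        else:
            self.records, self.curation_report = list(records), None
        self.molecules, _ = standardize_batch([r.smiles for r in self.records])
        self.molecules = {
            m.canonical_smiles: m for m in self.molecules.values()
        }
        self.split, self.ac_pairs = split_dataset(
            self.records, self.molecules, k=n_clusters, train_frac=train_frac, seed=seed
        )

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        proteins: Sequence[ProteinEntry],
        **kwargs,
    ) -> "CPIBioactivityModel":
        """Build from a DataFrame with columns molecule_id, smiles, target_id,
        activity_type, relation, value."""
        records = [
            BioactivityRecord(
                molecule_id=str(row.molecule_id),
                smiles=str(row.smiles),
                target_id=str(row.target_id),
                activity_type=parse_activity_type(row.activity_type),
                relation=parse_relation(getattr(row, "relation", "=")),
                value=float(row.value),
            )
            for row in frame.itertuples(index=False)
        ]
        return cls(records, proteins, **kwargs)

    def fit(self) -> "CPIBioactivityResults":
        """Train the ensemble on the AC-stratified training partition and
        evaluate on the held-out partition."""
        train_data = make_integrated_dataset(
            self.records, self.split, self.proteins, partition="train"
        )
        ensemble = train_ensemble(train_data, self.model_config, self.train_config)
        return CPIBioactivityResults(self, ensemble)


class CPIBioactivityResults:
    """Fitted ensemble plus test-set predictions, uncertainties, and metrics."""

    def __init__(self, model: CPIBioactivityModel, ensemble: EnsembleModel):
        self.model = model
        self.ensemble = ensemble
        test = make_integrated_dataset(
            model.records, model.split, model.proteins, partition="test"
        )
        self._test = test
        preds = ensemble.predict_pairs(
            [(e.smiles, e.target_id) for e in test.examples],
            test.prot_graphs,
            test.mol_graphs,
        )
        self.predictions = preds
        self.y_true = test.values()
        self.y_pred = np.array([p.mean for p in preds])
        self.uncertainty = np.array([p.std for p in preds])
        ac = {
            (row.smiles, row.target_id, row.activity_type): bool(row.ac_label)
            for row in model.split.itertuples(index=False)
        }
        self.ac_mask = np.array(
            [ac.get((e.smiles, e.target_id, e.activity_type.value), False) for e in test.examples]
        )
        self.metrics: MetricReport = regression_metrics(self.y_true, self.y_pred)
        self.metrics_cliff: MetricReport = cliff_metrics(self.y_true, self.y_pred, self.ac_mask)

    def predict(
        self, pairs: Sequence[tuple[str, str]], proteins: Mapping | None = None
    ):
        """Ensemble mean/std predictions for new (smiles, target_id) pairs."""
        prot_graphs = proteins or self._test.prot_graphs
        return self.ensemble.predict_pairs(pairs, prot_graphs)

    def summary(self) -> str:
        m, c = self.metrics, self.metrics_cliff
        lines = [
            "CPI bioactivity ensemble",
            "========================",
            f"members:            {len(self.ensemble)}",
            f"train/test records: "
            f"{int((self.model.split['partition'] == 'train').sum())}/"
            f"{int((self.model.split['partition'] == 'test').sum())}",
            f"test n (AC n):      {m.n} ({c.n})",
            f"RMSE:               {m.rmse:.3f}",
            f"PCC:                {m.pcc:.3f}" if m.defined else "PCC:                undefined",
            f"SRCC:               {m.srcc:.3f}" if m.defined else "SRCC:               undefined",
        ]
        if c.defined:
            lines += [
                f"RMSE_cliff:         {c.rmse:.3f}",
                f"PCC_cliff:          {c.pcc:.3f}",
                f"SRCC_cliff:         {c.srcc:.3f}",
            ]
        else:
            lines.append(f"cliff metrics:      undefined ({c.undefined_reason})")
        lines.append(
            f"mean uncertainty:   {float(np.nanmean(self.uncertainty)):.3f}"
        )
        return "\n".join(lines)
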