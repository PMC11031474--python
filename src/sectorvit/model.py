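"""Model/Results interface around the sector transformer.

Follows the fit-then-results convention of statistical modelling packages:

    >>> model = SectorTransformer(train_cohort, ModelConfig(embed_dim=32))
    >>> res = model.fit(TrainConfig(epochs=50, seed=1))
    >>> res.evaluate(test_cohort, level="patient").point["accuracy"]
    >>> res.sector_importance(test_cohort, n_rep=100)
    >>> print(res.summary())
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortDataset
from .importance import (ImportanceResult, SectorRanking, permutation_importance,
                         rank_sectors)
from .metrics import (MetricsReport, PairedTestResult, aggregate_patient,
                      delong_test, evaluate_predictions, mcnemar_test,
                      POSITIVE_UNMETHYLATED)
from .network import HEAD_ORDER, ModelConfig, VViTNetwork, cohort_inputs
from .train import TrainConfig, TrainHistory, train


class SectorTransformer:
    """Sector-split vision transformer bound to a training cohort."""

    def __init__(self, cohort: CohortDataset, config: ModelConfig | None = None):
        if len(cohort) == 0:
            raise ValueError("training cohort is empty")
        self.cohort = cohort
        self.config = config or ModelConfig()
        self.network = VViTNetwork(self.config)

    def fit(self, train_config: TrainConfig | None = None,
            verbose: bool = False,
            checkpoint_dir: str | None = None) -> "SectorTransformerResults":
        train_config = train_config or TrainConfig()
        inputs, labels = cohort_inputs(self.cohort)
        history = train(self.network, inputs, labels, train_config,
                        verbose=verbose, checkpoint_dir=checkpoint_dir)
        return SectorTransformerResults(self, self.network, train_config, history)


@dataclass
class SectorTransformerResults:
    model: SectorTransformer | None
    network: VViTNetwork
    train_config: TrainConfig | None
    history: TrainHistory | None

    # -- prediction ---------------------------------------------------------

    def predict(self, cohort: CohortDataset, batch_size: int = 64) -> pd.DataFrame:
        """Per-slice head probabilities, calls and the voted total output."""
        return self.network.predict_table(cohort, batch_size=batch_size)

    def predict_total(self, cohort: CohortDataset) -> tuple[np.ndarray, np.ndarray]:
        """(voted binary calls, mean probabilities) per slice — the predictor
        contract used by the permutation-importance machinery."""
        table = self.predict(cohort)
        return table["total_call"].to_numpy(), table["total_prob"].to_numpy()

    # -- evaluation ---------------------------------------------------------

    def evaluate(self, cohort: CohortDataset, level: str = "image",
                 head: str = "total", positive_class: int = POSITIVE_UNMETHYLATED,
                 n_boot: int = 1000, seed: int = 0) -> MetricsReport:
        """Metrics report for one head (or the voted total) at image or
        patient level."""
        table = self.predict(cohort)
        if head == "total":
            calls = table["total_call"].to_numpy()
            probs = table["total_prob"].to_numpy()
        else:
            calls = table[f"call:{head}"].to_numpy()
            probs = table[f"prob:{head}"].to_numpy()
        labels = table["label"].to_numpy()
        if level == "patient":
            pids = table["patient_id"].tolist()
            order, calls, probs = aggregate_patient(calls, probs, pids)
            lab_by_pid = dict(zip(pids, labels))
            labels = np.array([lab_by_pid[pid] for pid in order])
        # scores must be oriented toward the positive class for ROC
        scores = probs if positive_class == 1 else 1.0 - probs
        return evaluate_predictions(calls, scores, labels,
                                    positive_class=positive_class,
                                    n_boot=n_boot, seed=seed)

    def evaluate_all_heads(self, cohort: CohortDataset, level: str = "image",
                           n_boot: int = 1000, seed: int = 0) -> dict[str, MetricsReport]:
        out = {"total": self.evaluate(cohort, level, "total", n_boot=n_boot, seed=seed)}
        for name in self.network.head_names:
            out[name] = self.evaluate(cohort, level, name, n_boot=n_boot, seed=seed)
        return out

    def compare_calls(self, cohort: CohortDataset, other_calls: np.ndarray,
                      level: str = "image") -> PairedTestResult:
        """McNemar test of this model's total calls against a rival's calls."""
        calls, probs = self.predict_total(cohort)
        labels = cohort.labels
        if level == "patient":
            pids = list(cohort.patient_ids)
            order, calls, probs = aggregate_patient(calls, probs, pids)
            lab = dict(zip(pids, labels))
            labels = np.array([lab[p] for p in order])
        return mcnemar_test(calls, other_calls, labels)

    def compare_auc(self, cohort: CohortDataset, other_scores: np.ndarray,
                    positive_class: int = POSITIVE_UNMETHYLATED) -> PairedTestResult:
        """DeLong test of this model's total probability against rival scores."""
        _, probs = self.predict_total(cohort)
        scores = probs if positive_class == 1 else 1.0 - probs
        return delong_test(scores, other_scores, cohort.labels,
                           positive_class=positive_class)

    # -- importance ---------------------------------------------------------

    def sector_importance(self, cohort: CohortDataset, n_rep: int = 100,
                          base_seed: int = 0, level: str = "image",
                          sectors: list[str] | None = None) -> SectorRanking:
        """Permutation importance of every data sector, ranked."""
        names = sectors or [s.name for s in self.network.specs]
        results: list[ImportanceResult] = []
        for i, sector in enumerate(names):
            results.append(permutation_importance(
                self.predict_total, cohort, sector, n_rep=n_rep,
                base_seed=base_seed + 10_000 * i, level=level))
        return rank_sectors(results)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        cfg = self.network.config
        buf = _io.StringIO()
        buf.write("Sector transformer results\n")
        buf.write("=" * 60 + "\n")
        buf.write(f"sectors: {len(self.network.specs)} data + class token\n")
        buf.write(f"tokens:  {self.network.n_tokens}  "
                  f"(embed_dim={cfg.embed_dim}, depth={cfg.depth}, "
                  f"heads={cfg.n_heads}, patch={cfg.patch_size})\n")
        buf.write(f"attention: {cfg.attention_scope}; vote: {cfg.vote_members}\n")
        if self.history is not None and self.history.loss:
            buf.write(f"epochs run: {len(self.history.loss)}"
                      f"{'  [diverged]' if self.history.diverged else ''}\n")
            buf.write(f"final loss: {self.history.loss[-1]:.4f}   "
                      f"final voted train accuracy: {self.history.accuracy[-1]:.3f}\n")
        n_par = sum(p.data.size for p in self.network.parameters())
        buf.write(f"parameters: {n_par}\n")
        buf.write("=" * 60 + "\n")
        return buf.getvalue()

    # -- persistence --------------------------------------------------------

    def save(self, path: str) -> None:
        self.network.save(path)

    @classmethod
    def load(cls, path: str) -> "SectorTransformerResults":
        return cls(model=None, network=VViTNetwork.load(path),
                   train_config=None, history=None)


__all__ = ["SectorTransformer", "SectorTransformerResults", "ModelConfig",
           "TrainConfig", "HEAD_ORDER"]
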