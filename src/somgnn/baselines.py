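"""Per-atom feature-table baselines: random forest, AdaBoost, MLP.

The baselines consume the exact feature rows the GNNs see, but each atom is
classified independently with no graph context — the comparison isolates
what message passing adds over the shared input features.  Hyperparameter
selection uses the same criterion as the GNNs: validation molecular
R-precision, with table rows grouped back into molecules by example id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.neural_network import MLPClassifier

from .metrics import evaluate
from .molgraph import EnzymeContext, FeatureConfig, featurize
from .reaction import Example

ALGORITHMS = ("random_forest", "adaboost", "mlp")

#: Paper-style grids: tree counts for the ensemble methods, hidden sizes and
#: depths for the MLP.
DEFAULT_TREE_GRID = (100, 250, 500, 1000)
DEFAULT_MLP_HIDDEN_GRID = (32, 64, 128, 256, 512)
DEFAULT_MLP_DEPTH_GRID = (1, 2, 3, 4, 5)


@dataclass
class AtomTable:
    """One row per (example, atom), with the example's full feature row."""

    features: np.ndarray
    labels: np.ndarray
    example_ids: list[str]
    atom_indices: np.ndarray

    @property
    def n_rows(self) -> int:
        return self.features.shape[0]

    def groups(self) -> list[tuple[str, np.ndarray]]:
        """(example_id, row indices) in first-appearance order."""
        order: dict[str, list[int]] = {}
        for k, eid in enumerate(self.example_ids):
            order.setdefault(eid, []).append(k)
        return [(eid, np.array(idx)) for eid, idx in order.items()]

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.features)
        df.insert(0, "example_id", self.example_ids)
        df.insert(1, "atom_index", self.atom_indices)
        df["label"] = self.labels.astype(int)
        df.to_csv(path, sep="\t", index=False)


def build_atom_table(dataset: list[Example], config: FeatureConfig) -> AtomTable:
    """Flatten a dataset into per-atom rows, in example order then atom order.

    The feature layout is byte-identical to the GNN input for the same
    FeatureConfig.
    """
    feats, labels, ids, atoms = [], [], [], []
    for ex in dataset:
        if ex.target != "atoms":
            raise ValueError("atom tables require atom-target examples")
        X = featurize(ex.graph, EnzymeContext(ex.ec2), config).values
        y = ex.labels
        feats.append(X)
        labels.append(y)
        ids += [ex.example_id] * ex.graph.n_atoms
        atoms.append(np.arange(ex.graph.n_atoms))
    return AtomTable(
        features=np.vstack(feats),
        labels=np.concatenate(labels),
        example_ids=ids,
        atom_indices=np.concatenate(atoms),
    )


@dataclass
class BaselineScorer:
    """A fitted row-wise classifier exposing per-atom SOM probabilities."""

    algo: str
    estimator: object
    hyperparams: dict

    def score_rows(self, X: np.ndarray) -> np.ndarray:
        if self.algo == "adaboost":
            # Staged decision function mapped through the logistic function;
            # no calibration is applied.
            z = self.estimator.decision_function(X)
            return 1.0 / (1.0 + np.exp(-z))
        proba = self.estimator.predict_proba(X)
        classes = list(self.estimator.classes_)
        if 1 not in classes:
            return np.zeros(len(X))
        return proba[:, classes.index(1)]

    def score_table(self, table: AtomTable) -> list[tuple[str, np.ndarray, np.ndarray]]:
        """(example_id, scores, labels) per molecule."""
        p = self.score_rows(table.features)
        return [
            (eid, p[idx], table.labels[idx]) for eid, idx in table.groups()
        ]


def _make_estimator(algo: str, combo: dict, seed: int):
    if algo == "random_forest":
        return RandomForestClassifier(
            n_estimators=combo["n_estimators"], criterion="gini",
            random_state=seed, n_jobs=1,
        )
    if algo == "adaboost":
        return AdaBoostClassifier(n_estimators=combo["n_estimators"], random_state=seed)
    if algo == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=(combo["hidden"],) * combo["depth"],
            solver="adam", max_iter=300, random_state=seed,
        )
    raise ValueError(f"unknown baseline algorithm {algo!r}; choose from {ALGORITHMS}")


def default_baseline_grid(algo: str) -> list[dict]:
    if algo in ("random_forest", "adaboost"):
        return [{"n_estimators": n} for n in DEFAULT_TREE_GRID]
    if algo == "mlp":
        return [
            {"hidden": h, "depth": d}
            for h in DEFAULT_MLP_HIDDEN_GRID
            for d in DEFAULT_MLP_DEPTH_GRID
        ]
    raise ValueError(f"unknown baseline algorithm {algo!r}")


def train_baseline(
    table: AtomTable,
    algo: str,
    grid: list[dict] | None = None,
    seed: int = 0,
    validation_table: AtomTable | None = None,
) -> tuple[BaselineScorer, list[dict]]:
    """Fit a row-wise classifier; select hyperparameters on the validation
    table by molecular R-precision (grid order breaks ties).

    Without a validation table the first grid entry is used directly.
    """
    if table.n_rows == 0:
        raise ValueError("empty atom table")
    if algo not in ALGORITHMS:
        raise ValueError(f"unknown baseline algorithm {algo!r}; choose from {ALGORITHMS}")
    grid = grid or default_baseline_grid(algo)
    selection: list[dict] = []
    best, best_score = None, -np.inf
    for k, combo in enumerate(grid):
        est = _make_estimator(algo, combo, seed)
        est.fit(table.features, table.labels.astype(int))
        scorer = BaselineScorer(algo=algo, estimator=est, hyperparams=dict(combo))
        if validation_table is None:
            return scorer, [{"combo_index": k, **combo, "selected": True}]
        groups = scorer.score_table(validation_table)
        report = evaluate(
            [s for _, s, _ in groups], [y for _, _, y in groups],
            [eid for eid, _, _ in groups],
        )
        score = report.molecular_r_precision
        selection.append(
            {"combo_index": k, **combo, "val_molecular_r_precision": score}
        )
        if score > best_score:
            best_score, best = score, scorer
    return best, selection
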