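"""SOM prediction models: trunk of graph convolutions plus a node or bond head.

Node mode appends one more graph convolution producing a single value per
atom, mapped to [0, 1] by the logistic function.  Bond mode drops that final
convolution and instead applies a classifier MLP to the two concatenations
of a bond's endpoint representations; the reported bond probability is the
average of the two per-orientation probabilities:

    y_hat(i, j) = [sigma(MLP(x'_i || x'_j)) + sigma(MLP(x'_j || x'_i))] / 2

Training minimizes unweighted binary cross-entropy over all atoms (or
bonds) with Adam; the parameters returned are those of the epoch with the
best validation molecular R-precision.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np

from ..molgraph import EnzymeContext, FeatureConfig, FeatureMatrix, MoleculeGraph, featurize
from ..reaction import Example
from .autograd import Adam, Tensor, bce_loss, concat_cols, gather_rows
from .layers import (
    BatchedGraph,
    ChebLayerParams,
    GINLayerParams,
    MFLayerParams,
    MLPParams,
    glorot,
)

CONV_TYPES = ("gin", "mf", "cheb")
DEFAULT_HIDDEN_GRID = (64, 128, 256, 512)
DEFAULT_DEPTH_GRID = (1, 2, 3, 4, 5)
DEFAULT_CHEB_K_GRID = tuple(range(1, 11))
DEFAULT_MF_DMAX_GRID = (1, 2, 3, 4, 5)


@dataclass
class Predictions:
    """Per-candidate SOM probabilities for one molecule."""

    mode: str  # "atoms" | "bonds"
    values: dict  # atom index -> prob, or (i, j) -> prob

    def as_array(self, graph: MoleculeGraph) -> np.ndarray:
        if self.mode == "atoms":
            return np.array([self.values[i] for i in range(graph.n_atoms)])
        return np.array([self.values[(b.i, b.j)] for b in graph.bonds])


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0
    # loss is binary cross-entropy and the optimizer Adam, by construction


@dataclass
class ModelParams:
    """Full parameter set of one SOM model."""

    conv_type: str
    mode: str  # "atoms" | "bonds"
    trunk: list
    head: object  # conv layer params (node mode) or MLPParams (bond mode)
    hidden_width: int
    feature_config: FeatureConfig
    seed: int = 0
    hyperparams: dict = field(default_factory=dict)

    def tensors(self) -> list[Tensor]:
        out = []
        for layer in self.trunk:
            out += layer.tensors()
        out += self.head.tensors()
        return out

    def clone(self) -> "ModelParams":
        return copy.deepcopy(self)


def _make_conv(conv_type: str, in_w: int, out_w: int, rng, K: int, d_max: int):
    if conv_type == "gin":
        return GINLayerParams.create(in_w, out_w, rng)
    if conv_type == "mf":
        return MFLayerParams.create(in_w, out_w, d_max, rng)
    if conv_type == "cheb":
        return ChebLayerParams.create(in_w, out_w, K, rng)
    raise ValueError(f"unknown conv type {conv_type!r}")


def build_model(
    conv_type: str,
    feature_config: FeatureConfig,
    mode: str = "atoms",
    hidden_width: int = 64,
    depth: int = 3,
    K: int = 3,
    d_max: int = 4,
    seed: int = 0,
    bond_mlp_hidden: int | None = None,
) -> ModelParams:
    """Construct an initialized model.

    ``depth`` counts trunk convolutions (1..5); node mode adds a final
    single-output convolution of the same type on top.
    """
    if conv_type not in CONV_TYPES:
        raise ValueError(f"conv_type must be one of {CONV_TYPES}")
    if not 1 <= depth <= 5:
        raise ValueError("trunk depth must be in 1..5")
    if mode not in ("atoms", "bonds"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    widths = [feature_config.width] + [hidden_width] * depth
    trunk = [
        _make_conv(conv_type, w_in, w_out, rng, K, d_max)
        for w_in, w_out in zip(widths[:-1], widths[1:])
    ]
    if mode == "atoms":
        head = _make_conv(conv_type, hidden_width, 1, rng, K, d_max)
    else:
        h = bond_mlp_hidden or hidden_width
        head = MLPParams.create([2 * hidden_width, h, 1], rng)
    return ModelParams(
        conv_type=conv_type,
        mode=mode,
        trunk=trunk,
        head=head,
        hidden_width=hidden_width,
        feature_config=feature_config,
        seed=seed,
        hyperparams={"depth": depth, "K": K, "d_max": d_max,
                     "hidden_width": hidden_width},
    )


# ---------------------------------------------------------------------------
# Forward passes


def _trunk_forward(model: ModelParams, x: Tensor, batch: BatchedGraph) -> Tensor:
    for layer in model.trunk:
        x = layer.apply(x, batch).relu()
    return x


def _node_probs(model: ModelParams, x: Tensor, batch: BatchedGraph) -> Tensor:
    h = _trunk_forward(model, x, batch)
    return model.head.apply(h, batch).sigmoid()


def _bond_probs(model: ModelParams, x: Tensor, batch: BatchedGraph) -> Tensor:
    h = _trunk_forward(model, x, batch)
    endpoints = np.concatenate(
        [be for be in batch.bond_endpoints if len(be)] or
        [np.zeros((0, 2), dtype=np.int64)]
    )
    xi = gather_rows(h, endpoints[:, 0])
    xj = gather_rows(h, endpoints[:, 1])
    p_ij = model.head.apply(concat_cols(xi, xj)).sigmoid()
    p_ji = model.head.apply(concat_cols(xj, xi)).sigmoid()
    return (p_ij + p_ji) * Tensor(0.5)


def node_forward(model: ModelParams, features, graph: MoleculeGraph) -> Predictions:
    """Per-atom SOM probabilities for one molecule."""
    if model.mode != "atoms":
        raise ValueError("node_forward requires a node-mode model")
    x = Tensor(features.values if isinstance(features, FeatureMatrix) else features)
    batch = BatchedGraph.from_graphs([graph])
    p = _node_probs(model, x, batch).data.ravel()
    return Predictions(mode="atoms", values={i: float(p[i]) for i in range(len(p))})


def bond_forward(model: ModelParams, features, graph: MoleculeGraph) -> Predictions:
    """Per-bond SOM probabilities; symmetric in the stored endpoint order."""
    if model.mode != "bonds":
        raise ValueError("bond_forward requires a bond-mode model")
    x = Tensor(features.values if isinstance(features, FeatureMatrix) else features)
    batch = BatchedGraph.from_graphs([graph])
    p = _bond_probs(model, x, batch).data.ravel()
    return Predictions(
        mode="bonds",
        values={(b.i, b.j): float(p[k]) for k, b in enumerate(graph.bonds)},
    )


# ---------------------------------------------------------------------------
# Training


def _featurize_examples(model: ModelParams, examples: list[Example]) -> list[np.ndarray]:
    cfg = model.feature_config
    return [
        featurize(ex.graph, EnzymeContext(ex.ec2), cfg).values for ex in examples
    ]


def _batch_predict(model: ModelParams, examples, feats) -> list[np.ndarray]:
    """Per-example probability arrays, computed in one block-diagonal pass."""
    batch = BatchedGraph.from_graphs([ex.graph for ex in examples])
    x = Tensor(np.vstack(feats))
    if model.mode == "atoms":
        p = _node_probs(model, x, batch).data.ravel()
        return [p[a:b] for a, b in batch.node_slices]
    p = _bond_probs(model, x, batch).data.ravel()
    out, k = [], 0
    for be in batch.bond_endpoints:
        out.append(p[k:k + len(be)])
        k += len(be)
    return out


def predict_examples(model: ModelParams, examples: list[Example]) -> list[np.ndarray]:
    """Probability array per example (atom order or bond order)."""
    feats = _featurize_examples(model, examples)
    out = []
    for i in range(0, len(examples), 256):
        out += _batch_predict(model, examples[i:i + 256], feats[i:i + 256])
    return out


def _validation_r_precision(model: ModelParams, examples: list[Example]) -> float:
    from ..metrics import evaluate

    scores = predict_examples(model, examples)
    labels = [ex.labels for ex in examples]
    report = evaluate(scores, labels)
    return report.molecular_r_precision


def train_model(
    model: ModelParams,
    train_set: list[Example],
    validation_set: list[Example],
    config: TrainConfig,
) -> tuple[ModelParams, list[dict]]:
    """Train with Adam on unweighted BCE; return the best-validation epoch.

    The log carries one row per epoch with the mean training loss and the
    validation molecular R-precision.  Fully deterministic given
    ``config.seed``.
    """
    if not train_set:
        raise ValueError("empty training set")
    if config.epochs == 0:
        return model.clone(), []
    train_feats = _featurize_examples(model, train_set)
    targets = [ex.labels for ex in train_set]
    opt = Adam(model.tensors(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    best = model.clone()
    best_score = -np.inf
    log: list[dict] = []
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(train_set))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            exs = [train_set[i] for i in idx]
            feats = [train_feats[i] for i in idx]
            ys = np.concatenate([targets[i] for i in idx])
            if model.mode == "bonds" and ys.size == 0:
                continue
            batch = BatchedGraph.from_graphs([ex.graph for ex in exs])
            x = Tensor(np.vstack(feats))
            probs = (_node_probs if model.mode == "atoms" else _bond_probs)(
                model, x, batch
            )
            loss = bce_loss(probs, ys.reshape(-1, 1))
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_rp = (
            _validation_r_precision(model, validation_set)
            if validation_set else float("nan")
        )
        log.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)),
             "val_molecular_r_precision": val_rp}
        )
        if validation_set and val_rp > best_score:
            best_score = val_rp
            best = model.clone()
    if not validation_set:
        best = model.clone()
    return best, log


# ---------------------------------------------------------------------------
# Grid search and ensembling


def default_grid(conv_type: str,
                 hidden=DEFAULT_HIDDEN_GRID,
                 depths=DEFAULT_DEPTH_GRID,
                 cheb_K=DEFAULT_CHEB_K_GRID,
                 mf_dmax=DEFAULT_MF_DMAX_GRID) -> list[dict]:
    grid = []
    for h in hidden:
        for d in depths:
            if conv_type == "cheb":
                for K in cheb_K:
                    grid.append({"hidden_width": h, "depth": d, "K": K})
            elif conv_type == "mf":
                for dm in mf_dmax:
                    grid.append({"hidden_width": h, "depth": d, "d_max": dm})
            else:
                grid.append({"hidden_width": h, "depth": d})
    return grid


def grid_search(
    grid: list[dict],
    train_set: list[Example],
    validation_set: list[Example],
    config: TrainConfig,
    conv_type: str = "cheb",
    feature_config: FeatureConfig | None = None,
    mode: str = "atoms",
) -> tuple[ModelParams, list[dict]]:
    """Train one model per combination; select by validation molecular
    R-precision, ties broken by grid enumeration order."""
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if feature_config is None:
        raise ValueError("feature_config is required")
    table: list[dict] = []
    best_model, best_score, errors = None, -np.inf, []
    for k, combo in enumerate(grid):
        try:
            model = build_model(
                conv_type,
                feature_config,
                mode=mode,
                hidden_width=combo.get("hidden_width", 64),
                depth=combo.get("depth", 3),
                K=combo.get("K", 3),
                d_max=combo.get("d_max", 4),
                seed=config.seed,
            )
            trained, log = train_model(model, train_set, validation_set, config)
            score = _validation_r_precision(trained, validation_set)
        except Exception as err:  # noqa: BLE001 - reported, not fatal
            errors.append((combo, err))
            table.append({"combo_index": k, **combo, "status": f"error: {err}"})
            continue
        table.append({"combo_index": k, **combo,
                      "val_molecular_r_precision": score, "status": "ok"})
        if score > best_score:
            best_score = score
            best_model = trained
    if best_model is None:
        raise RuntimeError(f"all {len(grid)} grid combinations failed: {errors[0][1]}")
    return best_model, table


def ensemble_predict(models: list[ModelParams], features, graph: MoleculeGraph) -> Predictions:
    """Arithmetic mean of per-model probabilities, per atom (or bond)."""
    if not models:
        raise ValueError("empty model list")
    mode = models[0].mode
    if any(m.mode != mode for m in models):
        raise ValueError("all ensemble members must share a mode")
    preds = [
        (node_forward if mode == "atoms" else bond_forward)(m, features, graph)
        for m in models
    ]
    keys = preds[0].values.keys()
    values = {k: float(np.mean([p.values[k] for p in preds])) for k in keys}
    return Predictions(mode=mode, values=values)


def ensemble_predict_examples(
    models: list[ModelParams], examples: list[Example]
) -> list[np.ndarray]:
    if not models:
        raise ValueError("empty model list")
    per_model = [predict_examples(m, examples) for m in models]
    return [
        np.mean([pm[i] for pm in per_model], axis=0) for i in range(len(examples))
    ]


# ---------------------------------------------------------------------------
# Checkpoints (single-file JSON archive)


def _layer_to_dict(layer) -> dict:
    if isinstance(layer, GINLayerParams):
        return {
            "kind": "gin",
            "epsilon": float(layer.epsilon.data),
            "mlp": [[W.data.tolist(), b.data.tolist()] for W, b in layer.mlp.layers],
        }
    if isinstance(layer, MFLayerParams):
        return {
            "kind": "mf",
            "D_max": layer.D_max,
            "W": [t.data.tolist() for t in layer.W],
            "H": [t.data.tolist() for t in layer.H],
        }
    if isinstance(layer, ChebLayerParams):
        return {
            "kind": "cheb",
            "K": layer.K,
            "laplacian_mode": layer.laplacian_mode,
            "theta": [t.data.tolist() for t in layer.theta],
        }
    if isinstance(layer, MLPParams):
        return {
            "kind": "mlp",
            "layers": [[W.data.tolist(), b.data.tolist()] for W, b in layer.layers],
        }
    raise TypeError(f"unknown layer {type(layer)!r}")


def _layer_from_dict(d: dict):
    kind = d["kind"]
    if kind == "gin":
        mlp = MLPParams(layers=[
            (Tensor(np.array(W), requires_grad=True), Tensor(np.array(b), requires_grad=True))
            for W, b in d["mlp"]
        ])
        return GINLayerParams(epsilon=Tensor(d["epsilon"], requires_grad=True), mlp=mlp)
    if kind == "mf":
        return MFLayerParams(
            W=[Tensor(np.array(w), requires_grad=True) for w in d["W"]],
            H=[Tensor(np.array(h), requires_grad=True) for h in d["H"]],
            D_max=d["D_max"],
        )
    if kind == "cheb":
        return ChebLayerParams(
            theta=[Tensor(np.array(t), requires_grad=True) for t in d["theta"]],
            K=d["K"],
            laplacian_mode=d["laplacian_mode"],
        )
    if kind == "mlp":
        return MLPParams(layers=[
            (Tensor(np.array(W), requires_grad=True), Tensor(np.array(b), requires_grad=True))
            for W, b in d["layers"]
        ])
    raise ValueError(f"unknown layer kind {kind!r}")


def save_checkpoint(model: ModelParams, path) -> None:
    doc = {
        "conv_type": model.conv_type,
        "mode": model.mode,
        "hidden_width": model.hidden_width,
        "seed": model.seed,
        "hyperparams": model.hyperparams,
        "feature_config": model.feature_config.to_dict(),
        "trunk": [_layer_to_dict(layer) for layer in model.trunk],
        "head": _layer_to_dict(model.head),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_checkpoint(path) -> ModelParams:
    with open(path) as fh:
        doc = json.load(fh)
    return ModelParams(
        conv_type=doc["conv_type"],
        mode=doc["mode"],
        trunk=[_layer_from_dict(d) for d in doc["trunk"]],
        head=_layer_from_dict(doc["head"]),
        hidden_width=doc["hidden_width"],
        feature_config=FeatureConfig(**doc["feature_config"]),
        seed=doc["seed"],
        hyperparams=doc["hyperparams"],
    )
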