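"""Downstream uses of a SOM scorer: screening rule-generated promiscuous
products and ranking synthesis pathways.

A rule engine proposes a biotransformation by applying a pattern at a
reaction center in a substrate.  The SOM probability of that center, under
the enzyme context of the rule, is a proxy for the likelihood of the
reaction actually occurring: candidates below a threshold are discarded,
and a pathway's likelihood is the product of its steps' best-center
probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import auroc
from .molgraph import EnzymeContext, MoleculeGraph
from .reaction import _graph_from_mapped_smiles, _graph_to_mapped_smiles

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))


@dataclass
class ProductCandidate:
    """A rule-generated product: the substrate, the enzyme context, and the
    substrate atoms at which the rule was applied."""

    substrate: MoleculeGraph
    ec2: EnzymeContext
    center_atoms: frozenset
    product_id: str
    category: str = ""

    def __post_init__(self) -> None:
        self.center_atoms = frozenset(self.center_atoms)
        if not self.center_atoms:
            raise ValueError("center_atoms must be non-empty")
        for i in self.center_atoms:
            if not 0 <= i < self.substrate.n_atoms:
                raise ValueError(f"center atom {i} not in substrate")


@dataclass
class PathwayStep:
    """One reaction step with one or more candidate reaction centers."""

    substrate: MoleculeGraph
    ec2: EnzymeContext
    center_options: list[frozenset]

    def __post_init__(self) -> None:
        if not self.center_options:
            raise ValueError("center_options must be non-empty")
        self.center_options = [frozenset(c) for c in self.center_options]
        for opt in self.center_options:
            if not opt:
                raise ValueError("every center option must be non-empty")
            for i in opt:
                if not 0 <= i < self.substrate.n_atoms:
                    raise ValueError(f"center atom {i} not in substrate")


@dataclass
class Pathway:
    steps: list[PathwayStep]
    pathway_id: str
    group: str = ""

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("pathway must have >= 1 step")


def as_atom_scorer(model_or_fn):
    """Normalize a scorer to a callable (graph, ec2) -> per-atom probabilities.

    Accepts a callable, a node-mode ModelParams, or a list of ModelParams
    (averaged as an ensemble).
    """
    from .molgraph import featurize
    from .nn.model import ModelParams, ensemble_predict, node_forward

    if callable(model_or_fn):
        return model_or_fn
    if isinstance(model_or_fn, ModelParams):
        models = [model_or_fn]
    else:
        models = list(model_or_fn)

    def score(graph: MoleculeGraph, ec2: EnzymeContext) -> np.ndarray:
        feats = featurize(graph, ec2, models[0].feature_config)
        if len(models) == 1:
            pred = node_forward(models[0], feats, graph)
        else:
            pred = ensemble_predict(models, feats, graph)
        return pred.as_array(graph)

    return score


def score_reaction_center(scorer, substrate: MoleculeGraph, ec2: EnzymeContext,
                          center_atoms) -> float:
    """Minimum per-atom SOM probability over the center atoms.

    A transformation requires every center atom to be reactive, so a
    multi-atom center is only as likely as its least likely atom.
    """
    center_atoms = frozenset(center_atoms)
    if not center_atoms:
        raise ValueError("empty reaction center")
    probs = as_atom_scorer(scorer)(substrate, ec2)
    return float(min(probs[i] for i in center_atoms))


def filter_products(scorer, candidates: list[ProductCandidate],
                    threshold: float) -> tuple[list[ProductCandidate], list[ProductCandidate]]:
    """Accept candidates whose center score is at or above the threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    score_fn = as_atom_scorer(scorer)
    accepted, rejected = [], []
    for c in candidates:
        s = score_reaction_center(score_fn, c.substrate, c.ec2, c.center_atoms)
        (accepted if s >= threshold else rejected).append(c)
    return accepted, rejected


def threshold_sweep(scorer, candidates: list[ProductCandidate],
                    thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Per-threshold, per-category retention fractions.

    Returns a tidy table (threshold, category, n_total, n_accepted,
    fraction); retention is computed once from cached center scores, so the
    sweep is monotone by construction of the filter rule.
    """
    if not candidates:
        raise ValueError("no candidates to sweep")
    score_fn = as_atom_scorer(scorer)
    scores = np.array([
        score_reaction_center(score_fn, c.substrate, c.ec2, c.center_atoms)
        for c in candidates
    ])
    cats = np.array([c.category for c in candidates])
    rows = []
    for t in thresholds:
        for cat in sorted(set(cats)):
            mask = cats == cat
            n_total = int(mask.sum())
            n_acc = int((scores[mask] >= t).sum())
            rows.append(
                {"threshold": float(t), "category": cat, "n_total": n_total,
                 "n_accepted": n_acc, "fraction": n_acc / n_total}
            )
    return pd.DataFrame(rows)


def retention_ratio(sweep: pd.DataFrame, numerator: str, denominator: str) -> pd.DataFrame:
    """Cross-category ratio of retention fractions per threshold."""
    num = sweep[sweep.category == numerator].set_index("threshold").fraction
    den = sweep[sweep.category == denominator].set_index("threshold").fraction
    ratio = (num / den).rename("ratio").reset_index()
    return ratio


@dataclass
class PathwayScore:
    pathway_id: str
    group: str
    likelihood: float
    chosen_centers: list[frozenset] = field(default_factory=list)


def pathway_likelihood(scorer, pathway: Pathway) -> PathwayScore:
    """Product over steps of the best center option's score.

    Step maxima factorize: maximizing each step independently equals the
    global maximum over all center combinations.
    """
    score_fn = as_atom_scorer(scorer)
    likelihood = 1.0
    chosen = []
    for step in pathway.steps:
        option_scores = [
            score_reaction_center(score_fn, step.substrate, step.ec2, opt)
            for opt in step.center_options
        ]
        best = int(np.argmax(option_scores))
        likelihood *= option_scores[best]
        chosen.append(step.center_options[best])
    return PathwayScore(
        pathway_id=pathway.pathway_id, group=pathway.group,
        likelihood=likelihood, chosen_centers=chosen,
    )


def rank_pathways(scorer, pathways: list[Pathway],
                  positive_group: str) -> tuple[float, pd.DataFrame]:
    """AUROC of the positive group's likelihoods against all others, plus the
    full ranked table."""
    scored = [pathway_likelihood(scorer, p) for p in pathways]
    labels = [1 if s.group == positive_group else 0 for s in scored]
    if sum(labels) == 0 or sum(labels) == len(labels):
        raise ValueError("both the positive group and its complement must be non-empty")
    value = auroc([s.likelihood for s in scored], labels)
    table = pd.DataFrame(
        [
            {"pathway_id": s.pathway_id, "group": s.group,
             "likelihood": s.likelihood,
             "chosen_centers": [sorted(c) for c in s.chosen_centers]}
            for s in scored
        ]
    ).sort_values("likelihood", ascending=False, kind="mergesort").reset_index(drop=True)
    return value, table


# ---------------------------------------------------------------------------
# JSON-lines serialization


def write_candidates_jsonl(candidates: list[ProductCandidate], path) -> None:
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(json.dumps({
                "product_id": c.product_id,
                "substrate_smiles": _graph_to_mapped_smiles(c.substrate),
                "ec2": c.ec2.ec2,
                "center_atoms": sorted(c.center_atoms),
                "category": c.category,
            }) + "\n")


def read_candidates_jsonl(path) -> list[ProductCandidate]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            out.append(ProductCandidate(
                substrate=_graph_from_mapped_smiles(rec["substrate_smiles"]),
                ec2=EnzymeContext(rec["ec2"]),
                center_atoms=frozenset(rec["center_atoms"]),
                product_id=rec["product_id"],
                category=rec.get("category", ""),
            ))
    return out


def write_pathways_jsonl(pathways: list[Pathway], path) -> None:
    with open(path, "w") as fh:
        for p in pathways:
            fh.write(json.dumps({
                "pathway_id": p.pathway_id,
                "group": p.group,
                "steps": [
                    {
                        "substrate_smiles": _graph_to_mapped_smiles(s.substrate),
                        "ec2": s.ec2.ec2,
                        "center_options": [sorted(o) for o in s.center_options],
                    }
                    for s in p.steps
                ],
            }) + "\n")


def read_pathways_jsonl(path) -> list[Pathway]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            steps = [
                PathwayStep(
                    substrate=_graph_from_mapped_smiles(s["substrate_smiles"]),
                    ec2=EnzymeContext(s["ec2"]),
                    center_options=[frozenset(o) for o in s["center_options"]],
                )
                for s in rec["steps"]
            ]
            out.append(Pathway(steps=steps, pathway_id=rec["pathway_id"],
                               group=rec.get("group", "")))
    return out
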