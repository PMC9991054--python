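"""Ranking metrics for SOM prediction and random-guess expectations.

Two views of every metric: "molecular" metrics average a per-molecule value
over molecules where it is defined, and "atomic" metrics pool all candidate
sites of all molecules into one ranking problem.  Ties in top-R selection
are broken deterministically by ascending candidate index.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def auroc(scores, labels) -> float | None:
    """Mid-rank AUROC: P(score_pos > score_neg) + 0.5 P(equal).

    Returns None (an explicit "undefined" result) when only one class is
    present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)  # average ranks give the tie = 0.5 convention
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _top_indices(scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k highest scores; ties broken by ascending index."""
    order = np.lexsort((np.arange(len(scores)), -scores))
    return order[:k]


def r_precision(scores, labels) -> float | None:
    """Fraction of positives among the top-R predictions, R = #positives."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    R = int(labels.sum())
    if R == 0:
        return None
    top = _top_indices(scores, R)
    return float(labels[top].sum() / R)


def top_two_rate(per_molecule: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """Fraction of molecules whose two top-ranked sites include a positive."""
    hits = 0
    for scores, labels in per_molecule:
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=int)
        if labels.sum() < 1:
            raise ValueError("top_two_rate requires >=1 positive per molecule")
        top = _top_indices(scores, min(2, len(scores)))
        hits += int(labels[top].any())
    return hits / len(per_molecule)


@dataclass
class EvalReport:
    molecular_r_precision: float
    molecular_auroc: float
    top_two_rate: float
    atomic_r_precision: float
    atomic_auroc: float
    n_molecules: int
    n_candidates: int
    n_positives: int
    per_molecule: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "molecular_r_precision": self.molecular_r_precision,
            "molecular_auroc": self.molecular_auroc,
            "top_two_rate": self.top_two_rate,
            "atomic_r_precision": self.atomic_r_precision,
            "atomic_auroc": self.atomic_auroc,
            "n_molecules": self.n_molecules,
            "n_candidates": self.n_candidates,
            "n_positives": self.n_positives,
        }


def evaluate(scores: list, labels: list, example_ids: list | None = None) -> EvalReport:
    """Score a prediction set: per-molecule metric means plus pooled metrics.

    ``scores``/``labels`` are aligned per-molecule arrays over candidate
    sites (atoms or bonds — the computation is identical).  Molecules where
    a per-molecule metric is undefined (no positives for R-precision, a
    single class for AUROC) are excluded from that metric's mean and flagged
    in the per-molecule breakdown.
    """
    if len(scores) == 0:
        raise ValueError("empty prediction set")
    if len(scores) != len(labels):
        raise ValueError("scores and labels length mismatch")
    if example_ids is None:
        example_ids = [str(k) for k in range(len(scores))]
    rows = []
    t2_input = []
    for eid, s, y in zip(example_ids, scores, labels):
        s = np.asarray(s, dtype=float)
        y = np.asarray(y, dtype=int)
        mol_auc = auroc(s, y)
        mol_rp = r_precision(s, y)
        if y.sum() >= 1:
            top = _top_indices(s, min(2, len(s)))
            t2 = bool(y[top].any())
            t2_input.append((s, y))
        else:
            t2 = None
        rows.append(
            {"example_id": eid, "n_candidates": len(s), "n_positives": int(y.sum()),
             "auroc": mol_auc, "r_precision": mol_rp, "top_two_hit": t2}
        )
    table = pd.DataFrame(rows)
    pooled_scores = np.concatenate([np.asarray(s, dtype=float) for s in scores])
    pooled_labels = np.concatenate([np.asarray(y, dtype=int) for y in labels])
    mol_aucs = [r["auroc"] for r in rows if r["auroc"] is not None]
    mol_rps = [r["r_precision"] for r in rows if r["r_precision"] is not None]
    return EvalReport(
        molecular_r_precision=float(np.mean(mol_rps)) if mol_rps else float("nan"),
        molecular_auroc=float(np.mean(mol_aucs)) if mol_aucs else float("nan"),
        top_two_rate=top_two_rate(t2_input) if t2_input else float("nan"),
        atomic_r_precision=(
            r_precision(pooled_scores, pooled_labels)
            if pooled_labels.sum() else float("nan")
        ),
        atomic_auroc=(
            a if (a := auroc(pooled_scores, pooled_labels)) is not None else float("nan")
        ),
        n_molecules=len(scores),
        n_candidates=int(len(pooled_labels)),
        n_positives=int(pooled_labels.sum()),
        per_molecule=table,
    )


def stratified_evaluate(
    scores: list, labels: list, example_ids: list, strata: dict
) -> dict[str, EvalReport]:
    """Independent evaluate() per stratum tag; empty strata are absent."""
    for eid in example_ids:
        if eid not in strata:
            raise ValueError(f"example {eid!r} has no stratum tag")
    out: dict[str, EvalReport] = {}
    for tag in sorted(set(strata[eid] for eid in example_ids)):
        idx = [k for k, eid in enumerate(example_ids) if strata[eid] == tag]
        out[tag] = evaluate(
            [scores[k] for k in idx],
            [labels[k] for k in idx],
            [example_ids[k] for k in idx],
        )
    return out


# ---------------------------------------------------------------------------
# Random-guess expectations


@dataclass(frozen=True)
class RandomBaselineQuery:
    R: int
    N: int

    def __post_init__(self) -> None:
        if not (0 <= self.R <= self.N and self.N >= 1):
            raise ValueError(f"need 0 <= R <= N, N >= 1; got R={self.R}, N={self.N}")


def expected_random(query: RandomBaselineQuery) -> tuple[float | None, float | None]:
    """Closed-form expectations for a random ranking of R positives among N.

    R-precision: (1/R) * sum_{i=0}^{R-1} (R - i) / (N - i); undefined at R=0.
    Top-two:     (1/2) * sum_{i=0}^{1}   (R - i) / (N - i); requires N >= 2.

    Implemented exactly as printed.  Note the summand models sequential
    draws that each hit a remaining positive; for some (R, N) this differs
    from the exhaustive-ordering average, which ``expected_random_enumerated``
    computes independently.
    """
    R, N = query.R, query.N
    rp = None
    if R >= 1:
        rp = sum((R - i) / (N - i) for i in range(R)) / R
    tt = None
    if N >= 2:
        tt = 0.5 * sum((R - i) / (N - i) for i in range(2))
    return rp, tt


def expected_random_enumerated(R: int, N: int) -> float:
    """Average R-precision over all N! orderings of the candidates (exact).

    Brute-force comparison estimator for the closed form; feasible for
    N <= 8.
    """
    if not (1 <= R <= N):
        raise ValueError("need 1 <= R <= N")
    labels = np.array([1] * R + [0] * (N - R))
    total = 0.0
    count = 0
    for perm in itertools.permutations(range(N)):
        # candidate at rank k is perm[k]; top-R = first R of the ordering
        total += labels[list(perm[:R])].sum() / R
        count += 1
    return total / count


def random_guess_auroc(
    n_candidates: int = 2000,
    positive_fraction: float = 0.1,
    repetitions: int = 200,
    seed: int = 0,
) -> float:
    """Mean pooled AUROC of i.i.d. uniform scores against fixed labels.

    A classifier guessing with no class bias has expected AUROC 0.5; this
    measures it empirically.
    """
    rng = np.random.default_rng(seed)
    n_pos = int(round(n_candidates * positive_fraction))
    labels = np.array([1] * n_pos + [0] * (n_candidates - n_pos))
    vals = []
    for _ in range(repetitions):
        scores = rng.uniform(size=n_candidates)
        vals.append(auroc(scores, labels))
    return float(np.mean(vals))
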