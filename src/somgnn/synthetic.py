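"""Seeded generators for molecule graphs, planted SOM rules, mapped reaction
pairs and application benchmarks.

The generators exist so every other module is testable without licensed
reaction data.  Molecules are valence-respecting random trees with optional
ring closures and double bonds; chemistry realism is deliberately minimal
(no aromaticity, no stereochemistry).  Planted labeling rules have a
controlled receptive-field depth:

* ``rule0`` (0-hop): an atom is a SOM iff it is oxygen, under the rule's
  enzyme context — decidable from a single feature row.
* ``rule2`` (2-hop): an atom is a SOM iff it is oxygen bonded to a carbon
  that has at least two further carbon neighbors — invisible to a row-wise
  classifier once environment-type features are removed.

All randomness flows from one seed through per-(stage, index) streams, so
generating more molecules never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .applications import Pathway, PathwayStep, ProductCandidate
from .molgraph import AtomRecord, BondRecord, EnzymeContext, MoleculeGraph
from .reaction import Example, MappedPair, SOMLabels, Transformation

#: Valence caps used by the generator (counting bond orders).
VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 3}

RULE_EC2 = {"rule0": "1.4", "rule2": "2.1"}

_STAGE_MOLECULES = 0
_STAGE_EDITS = 1
_STAGE_BENCHMARK = 2


@dataclass
class SynthConfig:
    n_molecules: int = 500
    atom_range: tuple[int, int] = (5, 25)
    elements: dict = field(
        default_factory=lambda: {"C": 0.60, "N": 0.15, "O": 0.15, "S": 0.05, "P": 0.05}
    )
    ring_prob: float = 0.30
    double_bond_prob: float = 0.15
    rule_id: str = "rule0"
    ec2_by_rule: dict = field(default_factory=lambda: dict(RULE_EC2))
    seed: int = 0
    # application-benchmark sizes
    n_candidates: int = 60
    n_pathways: int = 40
    pathway_depths: tuple[int, ...] = (2, 3)

    def __post_init__(self) -> None:
        if self.atom_range[0] < 2:
            raise ValueError("molecules need at least 2 atoms")
        if not 0 <= self.ring_prob <= 1 or not 0 <= self.double_bond_prob <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        for el in self.elements:
            if el not in VALENCE:
                raise ValueError(f"element {el!r} has no valence cap in this generator")
        if self.rule_id not in ("rule0", "rule2"):
            raise ValueError(f"unknown rule {self.rule_id!r}")

    @property
    def rule_ec2(self) -> str:
        return self.ec2_by_rule[self.rule_id]


def _sample_elements(rng, config: SynthConfig, n: int) -> list[str]:
    names = list(config.elements)
    w = np.array([config.elements[e] for e in names], dtype=float)
    return list(rng.choice(names, size=n, p=w / w.sum()))


def _gen_one_molecule(rng: np.random.Generator, config: SynthConfig,
                      molecule_id: str) -> MoleculeGraph:
    lo, hi = config.atom_range
    n = int(rng.integers(lo, hi + 1))
    for _attempt in range(50):
        elements = _sample_elements(rng, config, n)
        free = [VALENCE[e] for e in elements]
        bonds: list[tuple[int, int, int]] = []
        ok = True
        for k in range(1, n):
            anchors = [a for a in range(k) if free[a] >= 1]
            if not anchors:
                ok = False
                break
            a = int(rng.choice(anchors))
            bonds.append((a, k, 1))
            free[a] -= 1
            free[k] -= 1
        if not ok:
            continue
        adjacent = {(min(i, j), max(i, j)) for i, j, _ in bonds}
        # optional ring closure
        if n >= 4 and rng.random() < config.ring_prob:
            pool = [
                (i, j) for i in range(n) for j in range(i + 1, n)
                if (i, j) not in adjacent and free[i] >= 1 and free[j] >= 1
            ]
            if pool:
                i, j = pool[int(rng.integers(len(pool)))]
                bonds.append((i, j, 1))
                adjacent.add((i, j))
                free[i] -= 1
                free[j] -= 1
        # optional bond-order upgrades
        upgraded = []
        for (i, j, order) in bonds:
            if free[i] >= 1 and free[j] >= 1 and rng.random() < config.double_bond_prob:
                upgraded.append((i, j, 2))
                free[i] -= 1
                free[j] -= 1
            else:
                upgraded.append((i, j, order))
        atoms = [AtomRecord(index=k, element=e, degree=0) for k, e in enumerate(elements)]
        bond_records = [
            BondRecord(i=min(i, j), j=max(i, j), order=o) for i, j, o in upgraded
        ]
        return MoleculeGraph(atoms=atoms, bonds=bond_records, molecule_id=molecule_id)
    raise RuntimeError(
        f"cannot realize a valence-legal molecule of size {n} "
        f"from alphabet {sorted(config.elements)}"
    )


def gen_molecules(config: SynthConfig) -> list[MoleculeGraph]:
    """Connected, valence-legal random molecular graphs; seed-deterministic."""
    out = []
    for i in range(config.n_molecules):
        rng = np.random.default_rng([config.seed, _STAGE_MOLECULES, i])
        out.append(_gen_one_molecule(rng, config, molecule_id=f"synth-{i}"))
    return out


# ---------------------------------------------------------------------------
# Planted labeling rules


def _rule_positive_atoms(graph: MoleculeGraph, rule_id: str) -> set[int]:
    adj = graph.adjacency()
    pos = set()
    for a in graph.atoms:
        if rule_id == "rule0":
            # 0-hop: the focal element decides, so the label is a function of
            # the atom's own feature row.
            if a.element == "O":
                pos.add(a.index)
            continue
        # 2-hop: any atom bonded to a carbon that itself has >= 3 further
        # carbon neighbors (a quaternary-like carbon center).  The focal
        # element is unconstrained, so the label is independent of the atom's
        # own (environment-free) feature row by construction and requires two
        # hops of graph context to decide.
        for j in adj[a.index]:
            if graph.atoms[j].element != "C":
                continue
            c_neighbors = sum(
                1 for q in adj[j] if q != a.index and graph.atoms[q].element == "C"
            )
            if c_neighbors >= 3:
                pos.add(a.index)
                break
    return pos


def plant_soms(graphs: list[MoleculeGraph], rule_id: str, ec2: str,
               ec2_by_rule: dict | None = None) -> list[SOMLabels]:
    """Per-graph planted atomic SOM labels under an enzyme context.

    The rule fires only under its own EC context; under any other context
    every graph gets an empty label set (and would be dropped downstream).
    """
    if rule_id not in ("rule0", "rule2"):
        raise ValueError(f"unknown rule {rule_id!r}")
    tags = ec2_by_rule or RULE_EC2
    out = []
    for g in graphs:
        pos = _rule_positive_atoms(g, rule_id) if ec2 == tags[rule_id] else set()
        out.append(SOMLabels(target="atoms", positives=frozenset(pos), side="substrate"))
    return out


def make_planted_dataset(config: SynthConfig) -> list[Example]:
    """``n_molecules`` examples, each with >= 1 planted positive.

    Molecules whose planted label set is empty are discarded and replaced by
    continuing the molecule stream, so the emitted dataset is deterministic
    and free of degenerate examples.
    """
    examples: list[Example] = []
    i = 0
    ec2 = config.rule_ec2
    while len(examples) < config.n_molecules:
        rng = np.random.default_rng([config.seed, _STAGE_MOLECULES, i])
        g = _gen_one_molecule(rng, config, molecule_id=f"synth-{i}")
        i += 1
        if i > 100 * max(config.n_molecules, 1):
            raise RuntimeError("planted rule fires too rarely for this config")
        pos = _rule_positive_atoms(g, config.rule_id)
        if not pos:
            continue
        examples.append(
            Example(
                example_id=f"{g.molecule_id}:substrate:{ec2}",
                transformation_id=g.molecule_id,
                side="substrate",
                ec2=ec2,
                graph=g,
                target="atoms",
                positives=frozenset(pos),
            )
        )
    return examples


# ---------------------------------------------------------------------------
# Simulated atom-mapped reaction pairs


@dataclass
class PlantedTransformation:
    """A simulated transformation plus its ground-truth centers."""

    transformation: Transformation
    atom_soms: tuple[SOMLabels, SOMLabels]  # substrate, product
    bond_soms: tuple[SOMLabels, SOMLabels]
    edit_kind: str


def _free_valence(graph: MoleculeGraph) -> list[int]:
    used = [0] * graph.n_atoms
    for b in graph.bonds:
        w = 1 if b.order == "aromatic" else int(b.order)
        used[b.i] += w
        used[b.j] += w
    return [VALENCE.get(a.element, 4) - used[a.index] for a in graph.atoms]


def _clone_bonds(graph: MoleculeGraph):
    return [(b.i, b.j, b.order) for b in graph.bonds]


def _build(elements, bonds, molecule_id):
    atoms = [AtomRecord(index=k, element=e, degree=0) for k, e in enumerate(elements)]
    recs = [BondRecord(i=min(i, j), j=max(i, j), order=o) for i, j, o in bonds]
    return MoleculeGraph(atoms=atoms, bonds=recs, molecule_id=molecule_id)


def _apply_edit(rng, graph: MoleculeGraph, config: SynthConfig):
    """Sample one structural edit; returns (product graph before permutation,
    identity-map size, planted centers) or None when the edit is infeasible."""
    elements = [a.element for a in graph.atoms]
    free = _free_valence(graph)
    n = graph.n_atoms
    kinds = ["element_sub", "element_sub_order", "bond_order", "attach", "remove"]
    rng.shuffle(kinds)
    for kind in kinds:
        if kind == "element_sub":
            used = [VALENCE[e] - f for e, f in zip(elements, free)]
            options = [
                (a, e_new)
                for a in range(n)
                for e_new in VALENCE
                if e_new != elements[a] and VALENCE[e_new] >= used[a]
            ]
            if not options:
                continue
            a, e_new = options[int(rng.integers(len(options)))]
            new_elements = list(elements)
            new_elements[a] = e_new
            product = _build(new_elements, _clone_bonds(graph), graph.molecule_id + "p")
            return kind, product, {"atoms_sub": {a}, "atoms_prod": {a},
                                   "bonds_sub": set(), "bonds_prod": set()}
        if kind == "element_sub_order":
            used = [VALENCE[e] - f for e, f in zip(elements, free)]
            options = []
            for b in graph.bonds:
                if b.order != 1:
                    continue
                for (j, i) in ((b.j, b.i), (b.i, b.j)):
                    if free[i] < 1:
                        continue
                    for e_new in VALENCE:
                        if e_new != elements[j] and VALENCE[e_new] >= used[j] + 1:
                            options.append((i, j, e_new))
            if not options:
                continue
            i, j, e_new = options[int(rng.integers(len(options)))]
            new_elements = list(elements)
            new_elements[j] = e_new
            bonds = [
                (bi, bj, 2 if {bi, bj} == {i, j} else o)
                for bi, bj, o in _clone_bonds(graph)
            ]
            product = _build(new_elements, bonds, graph.molecule_id + "p")
            key = (min(i, j), max(i, j))
            return kind, product, {"atoms_sub": {j}, "atoms_prod": {j},
                                   "bonds_sub": {key}, "bonds_prod": {key}}
        if kind == "bond_order":
            options = []
            for b in graph.bonds:
                if b.order == 1 and free[b.i] >= 1 and free[b.j] >= 1:
                    options.append((b.i, b.j, 2))
                elif b.order == 2:
                    options.append((b.i, b.j, 1))
            if not options:
                continue
            i, j, new_order = options[int(rng.integers(len(options)))]
            bonds = [
                (bi, bj, new_order if {bi, bj} == {i, j} else o)
                for bi, bj, o in _clone_bonds(graph)
            ]
            product = _build(elements, bonds, graph.molecule_id + "p")
            key = (min(i, j), max(i, j))
            return kind, product, {"atoms_sub": {i, j}, "atoms_prod": {i, j},
                                   "bonds_sub": {key}, "bonds_prod": {key}}
        if kind == "attach":
            anchors = [a for a in range(n) if free[a] >= 1]
            if not anchors:
                continue
            a = int(rng.choice(anchors))
            e_new = str(rng.choice(["C", "O", "N"]))
            product = _build(elements + [e_new],
                             _clone_bonds(graph) + [(a, n, 1)],
                             graph.molecule_id + "p")
            return kind, product, {"atoms_sub": {a}, "atoms_prod": {a},
                                   "bonds_sub": set(), "bonds_prod": {(a, n)}}
        if kind == "remove":
            leaves = [
                a.index for a in graph.atoms
                if a.degree == 1 and graph.n_atoms >= 3
            ]
            if not leaves:
                continue
            leaf = int(rng.choice(leaves))
            neighbor = graph.adjacency()[leaf][0]
            keep = [k for k in range(n) if k != leaf]
            remap = {old: new for new, old in enumerate(keep)}
            bonds = [
                (remap[bi], remap[bj], o)
                for bi, bj, o in _clone_bonds(graph)
                if leaf not in (bi, bj)
            ]
            product = _build([elements[k] for k in keep], bonds,
                             graph.molecule_id + "p")
            key = (min(leaf, neighbor), max(leaf, neighbor))
            return ("remove_with_map", product,
                    {"atoms_sub": {neighbor}, "atoms_prod": {remap[neighbor]},
                     "bonds_sub": {key}, "bonds_prod": set(),
                     "map": {k: remap[k] for k in keep}})
    return None


def gen_reaction_pairs(config: SynthConfig) -> list[PlantedTransformation]:
    """Simulated mapped pairs with recorded ground-truth centers.

    Each base molecule receives one sampled structural edit (element
    substitution with or without a paired bond-order change, a bond-order
    change, or substituent attachment/removal); the product's atom order is
    then randomly permuted so the atom map is non-trivial.
    """
    molecules = gen_molecules(config)
    ec2_pool = sorted(set(RULE_EC2.values()) | {"3.2"})
    out: list[PlantedTransformation] = []
    for i, g in enumerate(molecules):
        rng = np.random.default_rng([config.seed, _STAGE_EDITS, i])
        edit = _apply_edit(rng, g, config)
        if edit is None:
            continue
        kind, product, planted = edit
        if kind == "remove_with_map":
            base_map = planted["map"]
            kind = "remove"
        else:
            base_map = {k: k for k in range(g.n_atoms)}
        # permute product atom order
        perm = list(rng.permutation(product.n_atoms))
        product = product.permuted(perm)
        atom_map = {s: perm[p] for s, p in base_map.items()}
        atoms_prod = {perm[p] for p in planted["atoms_prod"]}
        bonds_prod = {
            (min(perm[p], perm[q]), max(perm[p], perm[q]))
            for p, q in planted["bonds_prod"]
        }
        pair = MappedPair(substrate=g, product=product, atom_map=atom_map)
        ec2 = str(rng.choice(ec2_pool))
        t = Transformation(
            pair=pair,
            ec_contexts=[EnzymeContext(ec2)],
            transformation_id=f"T{i}",
        )
        out.append(
            PlantedTransformation(
                transformation=t,
                atom_soms=(
                    SOMLabels("atoms", frozenset(planted["atoms_sub"]), "substrate"),
                    SOMLabels("atoms", frozenset(atoms_prod), "product"),
                ),
                bond_soms=(
                    SOMLabels("bonds", frozenset(planted["bonds_sub"]), "substrate"),
                    SOMLabels("bonds", frozenset(bonds_prod), "product"),
                ),
                edit_kind=kind,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Application benchmarks


def gen_pathway_benchmark(
    config: SynthConfig,
) -> tuple[list[ProductCandidate], list[Pathway]]:
    """Product-screening candidates and pathway fixtures with group tags.

    "confirmed" candidates and "engineered" pathway steps carry a reaction
    center that satisfies the planted rule; "unconfirmed" candidates and
    "putative" steps carry uniformly random centers.  A scorer trained on
    the planted rule should therefore retain/rank the first group above the
    second.
    """
    labeled = make_planted_dataset(config)
    ec2 = EnzymeContext(config.rule_ec2)
    candidates: list[ProductCandidate] = []
    for k in range(config.n_candidates):
        rng = np.random.default_rng([config.seed, _STAGE_BENCHMARK, k])
        ex = labeled[int(rng.integers(len(labeled)))]
        if k % 2 == 0:
            center = {int(rng.choice(sorted(ex.positives)))}
            category = "confirmed"
        else:
            center = {int(rng.integers(ex.graph.n_atoms))}
            category = "unconfirmed"
        candidates.append(
            ProductCandidate(
                substrate=ex.graph, ec2=ec2, center_atoms=frozenset(center),
                product_id=f"P{k}", category=category,
            )
        )
    pathways: list[Pathway] = []
    for k in range(config.n_pathways):
        rng = np.random.default_rng([config.seed, _STAGE_BENCHMARK, 10_000 + k])
        depth = int(rng.choice(config.pathway_depths))
        group = "engineered" if k % 2 == 0 else "putative"
        steps = []
        for _ in range(depth):
            ex = labeled[int(rng.integers(len(labeled)))]
            random_center = frozenset({int(rng.integers(ex.graph.n_atoms))})
            if group == "engineered":
                good = frozenset({int(rng.choice(sorted(ex.positives)))})
                options = [random_center, good]
            else:
                options = [random_center,
                           frozenset({int(rng.integers(ex.graph.n_atoms))})]
            steps.append(PathwayStep(substrate=ex.graph, ec2=ec2,
                                     center_options=options))
        pathways.append(Pathway(steps=steps, pathway_id=f"PW{k}", group=group))
    return candidates, pathways
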