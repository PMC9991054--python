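"""Reaction-center labeling, symmetry adjustment and leakage-free splits.

A biotransformation is an atom-mapped substrate/product pair plus the EC
contexts of the enzymes known to catalyze it.  Sites of metabolism are
derived from what the atom map leaves changed: atoms whose element differs
across the map, atoms at the boundary of added/removed substructure, and
endpoints of bonds whose order or existence changes.  Labels on each side
are then widened to the atoms (bonds) indistinguishable from a labeled one
under the molecule's symmetry, and datasets are split at the transformation
level so both sides and all enzyme contexts of one reaction land in the
same partition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .molgraph import (
    AtomRecord,
    BondRecord,
    EnzymeContext,
    MoleculeGraph,
    MoleculeFormatError,
    from_rdkit,
)


@dataclass
class MappedPair:
    """Atom-mapped substrate/product pair.

    ``atom_map`` is a partial injective map substrate-atom-index ->
    product-atom-index; at least one atom must be mapped.
    """

    substrate: MoleculeGraph
    product: MoleculeGraph
    atom_map: dict[int, int]

    def __post_init__(self) -> None:
        if not self.atom_map:
            raise ValueError("atom map is empty")
        vals = list(self.atom_map.values())
        if len(set(vals)) != len(vals):
            raise ValueError("atom map is not injective")
        for i, j in self.atom_map.items():
            if not 0 <= i < self.substrate.n_atoms:
                raise ValueError(f"mapped substrate atom {i} does not exist")
            if not 0 <= j < self.product.n_atoms:
                raise ValueError(f"mapped product atom {j} does not exist")

    @property
    def inverse_map(self) -> dict[int, int]:
        return {j: i for i, j in self.atom_map.items()}


@dataclass
class Transformation:
    """A mapped pair with its enzyme contexts; the unit of splitting."""

    pair: MappedPair
    ec_contexts: list[EnzymeContext]
    transformation_id: str

    def __post_init__(self) -> None:
        if not self.ec_contexts:
            raise ValueError("ec_contexts must be non-empty")
        seen = [c.ec2 for c in self.ec_contexts]
        if len(set(seen)) != len(seen):
            raise ValueError("ec_contexts contains duplicates")


@dataclass
class SOMLabels:
    """Positive site set on one side of a pair.

    ``positives`` holds atom indices (``target="atoms"``) or bond endpoint
    pairs with i < j (``target="bonds"``).
    """

    target: str  # "atoms" | "bonds"
    positives: frozenset
    side: str  # "substrate" | "product"

    def __post_init__(self) -> None:
        if self.target not in ("atoms", "bonds"):
            raise ValueError(f"unknown target {self.target!r}")
        if self.side not in ("substrate", "product"):
            raise ValueError(f"unknown side {self.side!r}")
        self.positives = frozenset(self.positives)

    def validate_against(self, graph: MoleculeGraph) -> None:
        if self.target == "atoms":
            for i in self.positives:
                if not 0 <= i < graph.n_atoms:
                    raise ValueError(f"positive atom {i} not in graph")
        else:
            bonds = {(b.i, b.j) for b in graph.bonds}
            for e in self.positives:
                if tuple(e) not in bonds:
                    raise ValueError(f"positive bond {e} not in graph")


# ---------------------------------------------------------------------------
# SOM derivation from the atom map


def _boundary_and_element_positives(pair: MappedPair, side: str) -> set[int]:
    """Clauses (a) + (b): element changes and added/removed-substructure boundary."""
    if side == "substrate":
        this, other, fwd = pair.substrate, pair.product, pair.atom_map
    else:
        this, other, fwd = pair.product, pair.substrate, pair.inverse_map
    mapped_this = set(fwd)
    mapped_other = set(fwd.values())
    adj_this = this.adjacency()
    adj_other = other.adjacency()
    pos: set[int] = set()
    for i, ci in fwd.items():
        if this.atoms[i].element != other.atoms[ci].element:
            pos.add(i)
            continue
        if any(j not in mapped_this for j in adj_this[i]):
            pos.add(i)
            continue
        if any(q not in mapped_other for q in adj_other[ci]):
            pos.add(i)
    return pos


def _bond_changes(pair: MappedPair, side: str):
    """Bond-level changes visible from one side, between mapped endpoints.

    Returns (order_changes, existence_changes): lists of endpoint pairs in
    this side's indexing.  Existence changes cover both cleavage (bond on
    this side with no counterpart) and formation (counterpart bond on the
    other side with no bond here).
    """
    if side == "substrate":
        this, other, fwd = pair.substrate, pair.product, pair.atom_map
    else:
        this, other, fwd = pair.product, pair.substrate, pair.inverse_map
    inv = {v: k for k, v in fwd.items()}
    this_orders = this.bond_orders()
    other_orders = other.bond_orders()
    order_changes, existence_changes = [], []
    for (i, j), order in this_orders.items():
        if i in fwd and j in fwd:
            key = tuple(sorted((fwd[i], fwd[j])))
            if key not in other_orders:
                existence_changes.append((i, j))
            elif other_orders[key] != order:
                order_changes.append((i, j))
    for (p, q), _order in other_orders.items():
        if p in inv and q in inv:
            key = tuple(sorted((inv[p], inv[q])))
            if key not in this_orders:
                existence_changes.append(key)
    return order_changes, existence_changes


def _atom_soms_one_side(pair: MappedPair, side: str) -> SOMLabels:
    pos = _boundary_and_element_positives(pair, side)
    order_changes, existence_changes = _bond_changes(pair, side)
    for i, j in existence_changes:
        pos.update((i, j))
    for i, j in order_changes:
        # A pure order change is absorbed by an endpoint already marked by an
        # element change or a substructure boundary; only when neither
        # endpoint is marked do both endpoints become reaction centers.
        if i not in pos and j not in pos:
            pos.update((i, j))
    return SOMLabels(target="atoms", positives=frozenset(pos), side=side)


def derive_atom_soms(pair: MappedPair) -> tuple[SOMLabels, SOMLabels]:
    """Atomic SOMs on the substrate and product sides of a mapped pair."""
    return _atom_soms_one_side(pair, "substrate"), _atom_soms_one_side(pair, "product")


def _bond_soms_one_side(pair: MappedPair, side: str) -> SOMLabels:
    if side == "substrate":
        this, other, fwd = pair.substrate, pair.product, pair.atom_map
    else:
        this, other, fwd = pair.product, pair.substrate, pair.inverse_map
    other_orders = other.bond_orders()
    pos: set[tuple[int, int]] = set()
    for b in this.bonds:
        if b.i in fwd and b.j in fwd:
            key = tuple(sorted((fwd[b.i], fwd[b.j])))
            if other_orders.get(key) != b.order:
                pos.add((b.i, b.j))
        else:
            pos.add((b.i, b.j))
    return SOMLabels(target="bonds", positives=frozenset(pos), side=side)


def derive_bond_soms(pair: MappedPair) -> tuple[SOMLabels, SOMLabels]:
    """Bond SOMs: bonds whose order or existence changes, plus bonds touching
    unmapped (added/removed) substructure."""
    return _bond_soms_one_side(pair, "substrate"), _bond_soms_one_side(pair, "product")


# ---------------------------------------------------------------------------
# Symmetry adjustment


def refinement_classes(graph: MoleculeGraph) -> list[int]:
    """Equivalence classes of atoms under iterated neighborhood color
    refinement of the element+bond-order-labeled graph.

    Atoms sharing a final color are interchangeable under the graph's
    symmetry for labeling purposes.  Returns one class id per atom.
    """
    nb = graph.neighbor_bonds()
    colors = [a.element for a in graph.atoms]
    for _ in range(graph.n_atoms):
        keys = [
            (colors[i], tuple(sorted((colors[j], str(order)) for j, order in nb[i])))
            for i in range(graph.n_atoms)
        ]
        palette = {k: c for c, k in enumerate(sorted(set(keys), key=repr))}
        new_colors = [palette[k] for k in keys]
        if len(set(new_colors)) == len(set(colors)) and _same_partition(colors, new_colors):
            colors = new_colors
            break
        colors = new_colors
    return colors


def _same_partition(a: list, b: list) -> bool:
    groups_a: dict = {}
    groups_b: dict = {}
    for idx, (x, y) in enumerate(zip(a, b)):
        groups_a.setdefault(x, set()).add(idx)
        groups_b.setdefault(y, set()).add(idx)
    return set(map(frozenset, groups_a.values())) == set(map(frozenset, groups_b.values()))


def symmetry_adjust(graph: MoleculeGraph, labels: SOMLabels) -> SOMLabels:
    """Widen positives to all symmetry-equivalent atoms (or bonds).

    Idempotent and label-monotone: only ever adds positives.
    """
    labels.validate_against(graph)
    colors = refinement_classes(graph)
    if labels.target == "atoms":
        pos_colors = {colors[i] for i in labels.positives}
        new = {i for i in range(graph.n_atoms) if colors[i] in pos_colors}
    else:
        def bond_key(b: BondRecord):
            return (tuple(sorted((colors[b.i], colors[b.j]))), str(b.order))

        pos_keys = set()
        for (i, j) in labels.positives:
            b = next(b for b in graph.bonds if (b.i, b.j) == (i, j))
            pos_keys.add(bond_key(b))
        new = {(b.i, b.j) for b in graph.bonds if bond_key(b) in pos_keys}
    return SOMLabels(target=labels.target, positives=frozenset(new), side=labels.side)


# ---------------------------------------------------------------------------
# Reaction SMILES parsing


def parse_reaction_smiles(rxn: str) -> MappedPair:
    """Parse ``substrate>>product`` SMILES with atom-map numbers.

    Atoms sharing a map number across the two sides are mapped to each
    other; unmapped atoms are left out of the map.
    """
    parts = rxn.split(">>")
    if len(parts) != 2:
        raise MoleculeFormatError(f"not a two-sided reaction SMILES: {rxn!r}")

    def load(smiles: str):
        mol = Chem.MolFromSmiles(smiles, sanitize=True)
        if mol is None:
            raise MoleculeFormatError(f"cannot parse side {smiles!r}")
        mapnums = {}
        for atom in mol.GetAtoms():
            num = atom.GetAtomMapNum()
            if num:
                if num in mapnums:
                    raise MoleculeFormatError(f"duplicate atom-map number {num}")
                mapnums[num] = atom.GetIdx()
            atom.SetAtomMapNum(0)
        return from_rdkit(mol), mapnums

    sub, sub_nums = load(parts[0])
    prod, prod_nums = load(parts[1])
    atom_map = {
        sub_nums[n]: prod_nums[n] for n in sorted(sub_nums) if n in prod_nums
    }
    return MappedPair(substrate=sub, product=prod, atom_map=atom_map)


# ---------------------------------------------------------------------------
# Dataset examples and JSON-lines serialization


@dataclass
class Example:
    """One trainable unit: a molecule side under a single enzyme context."""

    example_id: str
    transformation_id: str
    side: str
    ec2: str
    graph: MoleculeGraph
    target: str
    positives: frozenset = field(default_factory=frozenset)

    @property
    def labels(self) -> np.ndarray:
        """Binary label vector over candidates (atoms or bonds, index order)."""
        if self.target == "atoms":
            y = np.zeros(self.graph.n_atoms)
            for i in self.positives:
                y[i] = 1.0
        else:
            y = np.zeros(len(self.graph.bonds))
            pos = {tuple(e) for e in self.positives}
            for k, b in enumerate(self.graph.bonds):
                if (b.i, b.j) in pos:
                    y[k] = 1.0
        return y


def build_examples(
    transformations: list[Transformation],
    target: str = "atoms",
    sides: tuple[str, ...] = ("substrate", "product"),
    apply_symmetry: bool = True,
    drop_zero_positive: bool = True,
    provided_labels: dict | None = None,
) -> list[Example]:
    """Expand transformations into (side, EC context) examples.

    Externally provided center annotations (``provided_labels``:
    (transformation_id, side) -> SOMLabels) take precedence; otherwise labels
    are derived from the atom map.  Zero-positive examples are dropped by
    default because molecular R-precision is undefined on them.
    """
    derive = derive_atom_soms if target == "atoms" else derive_bond_soms
    out: list[Example] = []
    for t in transformations:
        derived = dict(zip(("substrate", "product"), derive(t.pair)))
        for side in sides:
            graph = getattr(t.pair, side)
            labels = None
            if provided_labels is not None:
                labels = provided_labels.get((t.transformation_id, side))
            if labels is None:
                labels = derived[side]
            if apply_symmetry:
                labels = symmetry_adjust(graph, labels)
            if drop_zero_positive and not labels.positives:
                continue
            for ctx in t.ec_contexts:
                out.append(
                    Example(
                        example_id=f"{t.transformation_id}:{side}:{ctx.ec2}",
                        transformation_id=t.transformation_id,
                        side=side,
                        ec2=ctx.ec2,
                        graph=graph,
                        target=target,
                        positives=labels.positives,
                    )
                )
    return out


def _graph_to_mapped_smiles(graph: MoleculeGraph) -> str:
    from .molgraph import to_rdkit

    m = to_rdkit(graph)
    for atom in m.GetAtoms():
        atom.SetAtomMapNum(atom.GetIdx() + 1)
    mol = m.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def _graph_from_mapped_smiles(smiles: str, molecule_id: str = "") -> MoleculeGraph:
    mol = Chem.MolFromSmiles(smiles, sanitize=True)
    if mol is None:
        raise MoleculeFormatError(f"cannot parse {smiles!r}")
    order = sorted(range(mol.GetNumAtoms()),
                   key=lambda k: mol.GetAtomWithIdx(k).GetAtomMapNum())
    if [mol.GetAtomWithIdx(k).GetAtomMapNum() for k in order] != list(
        range(1, mol.GetNumAtoms() + 1)
    ):
        raise MoleculeFormatError("mapped SMILES must number atoms 1..n")
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
    mol = Chem.RenumberAtoms(mol, order)
    return from_rdkit(mol, molecule_id=molecule_id)


def write_examples_jsonl(examples: list[Example], path) -> None:
    """One example per line: atom positions encoded in map-numbered SMILES."""
    with open(path, "w") as fh:
        for ex in examples:
            rec = {
                "example_id": ex.example_id,
                "transformation_id": ex.transformation_id,
                "side": ex.side,
                "ec2": ex.ec2,
                "smiles": _graph_to_mapped_smiles(ex.graph),
                "target": ex.target,
                "positives": sorted(
                    [[int(a), int(b)] for a, b in ex.positives]
                    if ex.target == "bonds"
                    else [int(a) for a in ex.positives]
                ),
            }
            fh.write(json.dumps(rec) + "\n")


def read_examples_jsonl(path) -> list[Example]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            graph = _graph_from_mapped_smiles(rec["smiles"], rec["example_id"])
            positives = (
                frozenset(tuple(e) for e in rec["positives"])
                if rec["target"] == "bonds"
                else frozenset(rec["positives"])
            )
            out.append(
                Example(
                    example_id=rec["example_id"],
                    transformation_id=rec["transformation_id"],
                    side=rec["side"],
                    ec2=rec["ec2"],
                    graph=graph,
                    target=rec["target"],
                    positives=positives,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Splits


@dataclass
class SplitSpec:
    """Shuffle-split specification over transformations."""

    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    n_splits: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.ratios):
            raise ValueError("split fractions must be positive")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")


def make_splits(
    transformations: list[Transformation], spec: SplitSpec
) -> list[dict[str, str]]:
    """Partition transformations into train/validation/test, ``n_splits`` times.

    Each split shuffles the transformation list with its own seeded stream and
    cuts it by the ratios with floor rounding for validation and test and the
    remainder to train.  Splitting whole transformations keeps both reaction
    sides and all enzyme contexts of one transformation in one partition, so
    no information leaks across partitions.
    """
    if not transformations:
        raise ValueError("no transformations to split")
    ids = [t.transformation_id for t in transformations]
    if len(set(ids)) != len(ids):
        raise ValueError("transformation_ids must be unique")
    n = len(ids)
    n_val = int(np.floor(spec.ratios[1] * n))
    n_test = int(np.floor(spec.ratios[2] * n))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(
            f"ratios {spec.ratios} infeasible for {n} transformations "
            f"(sizes {n_train}/{n_val}/{n_test})"
        )
    splits = []
    for k in range(spec.n_splits):
        rng = np.random.default_rng([spec.seed, k])
        perm = rng.permutation(n)
        assignment: dict[str, str] = {}
        for pos, idx in enumerate(perm):
            if pos < n_train:
                part = "train"
            elif pos < n_train + n_val:
                part = "validation"
            else:
                part = "test"
            assignment[ids[idx]] = part
        splits.append(assignment)
    return splits


def partition_examples(
    examples: list[Example], assignment: dict[str, str], partition: str
) -> list[Example]:
    return [e for e in examples if assignment[e.transformation_id] == partition]
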