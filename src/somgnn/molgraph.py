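"""Molecular graph data model, parsing, and per-atom feature construction.

Molecules are heavy-atom-only undirected graphs ``G = (V, E)``: nodes are
atoms, edges are bonds with an order in {1, 2, 3, aromatic}.  Hydrogens are
implicit.  Per-atom feature vectors are a concatenation of exactly-one-hot
blocks: element, 1-hop environment type (optional) and the first two levels
of the EC number of the enzyme context, each block carrying an explicit
out-of-vocabulary slot.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import yaml

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

#: Allowed bond orders.  Aromatic bonds are kept as a distinct order rather
#: than kekulized so that environment types do not depend on an arbitrary
#: kekulization choice.
BOND_ORDERS = (1, 2, 3, "aromatic")

_EC2_RE = re.compile(r"^\d+\.(\d+|-)$")


class MoleculeFormatError(ValueError):
    """Raised when a molecule record cannot be parsed or is multi-fragment."""


@dataclass(frozen=True)
class AtomRecord:
    """A heavy atom: 0-based ``index``, element symbol and heavy-atom degree."""

    index: int
    element: str
    degree: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "index", int(self.index))
        object.__setattr__(self, "degree", int(self.degree))


@dataclass(frozen=True)
class BondRecord:
    """An undirected bond stored once with endpoint indices ``i < j``."""

    i: int
    j: int
    order: object  # 1 | 2 | 3 | "aromatic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "i", int(self.i))
        object.__setattr__(self, "j", int(self.j))
        if self.order != "aromatic":
            object.__setattr__(self, "order", int(self.order))
        if not self.i < self.j:
            raise ValueError(f"bond endpoints must satisfy i < j, got ({self.i}, {self.j})")
        if self.order not in BOND_ORDERS:
            raise ValueError(f"bond order {self.order!r} not in {BOND_ORDERS}")


@dataclass
class MoleculeGraph:
    """Connected undirected heavy-atom graph.

    Invariants (checked at construction): bonds reference valid atoms, are
    stored once with ``i < j``, contain no self-loops or duplicates, and the
    graph is connected.  Atom ``degree`` fields are recomputed from the bond
    list, so callers may pass records with degree 0.
    """

    atoms: list[AtomRecord]
    bonds: list[BondRecord]
    molecule_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if n == 0:
            raise ValueError("molecule has no atoms")
        seen: set[tuple[int, int]] = set()
        deg = [0] * n
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond ({b.i}, {b.j}) references a missing atom")
            if (b.i, b.j) in seen:
                raise ValueError(f"duplicate bond ({b.i}, {b.j})")
            seen.add((b.i, b.j))
            deg[b.i] += 1
            deg[b.j] += 1
        self.bonds = sorted(self.bonds, key=lambda b: (b.i, b.j))
        self.atoms = [
            AtomRecord(index=k, element=a.element, degree=deg[k])
            for k, a in enumerate(self.atoms)
        ]
        if not self._connected():
            raise MoleculeFormatError(
                f"molecule {self.molecule_id!r} is not a single connected fragment"
            )

    def _connected(self) -> bool:
        n = len(self.atoms)
        if n == 1:
            return True
        adj = self.adjacency()
        seen = {0}
        stack = [0]
        while stack:
            for j in adj[stack.pop()]:
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        return len(seen) == n

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def adjacency(self) -> list[list[int]]:
        """Neighbor lists indexed by atom."""
        adj: list[list[int]] = [[] for _ in self.atoms]
        for b in self.bonds:
            adj[b.i].append(b.j)
            adj[b.j].append(b.i)
        return adj

    def neighbor_bonds(self) -> list[list[tuple[int, object]]]:
        """Per-atom list of (neighbor index, bond order)."""
        nb: list[list[tuple[int, object]]] = [[] for _ in self.atoms]
        for b in self.bonds:
            nb[b.i].append((b.j, b.order))
            nb[b.j].append((b.i, b.order))
        return nb

    def bond_orders(self) -> dict[tuple[int, int], object]:
        return {(b.i, b.j): b.order for b in self.bonds}

    def edge_index(self) -> np.ndarray:
        """Directed expansion of the undirected bond list, shape (2, 2|E|)."""
        if not self.bonds:
            return np.zeros((2, 0), dtype=np.int64)
        src, dst = [], []
        for b in self.bonds:
            src += [b.i, b.j]
            dst += [b.j, b.i]
        return np.array([src, dst], dtype=np.int64)

    def permuted(self, perm: list[int]) -> "MoleculeGraph":
        """Relabel atoms: new index of old atom ``k`` is ``perm[k]``."""
        if sorted(perm) != list(range(self.n_atoms)):
            raise ValueError("perm is not a permutation of atom indices")
        atoms = [AtomRecord(0, "", 0)] * self.n_atoms
        for k, a in enumerate(self.atoms):
            atoms[perm[k]] = AtomRecord(index=perm[k], element=a.element, degree=0)
        bonds = [
            BondRecord(min(perm[b.i], perm[b.j]), max(perm[b.i], perm[b.j]), b.order)
            for b in self.bonds
        ]
        return MoleculeGraph(atoms=atoms, bonds=bonds, molecule_id=self.molecule_id)


@dataclass(frozen=True)
class EnzymeContext:
    """First two levels of an EC number, e.g. ``"1.4"`` or ``"3.-"``."""

    ec2: str

    def __post_init__(self) -> None:
        if not _EC2_RE.match(self.ec2):
            raise ValueError(f"not a two-level EC prefix: {self.ec2!r}")


_ORDER_CODE = {1: "1", 2: "2", 3: "3", "aromatic": "a"}


def _rdkit_order(bond: Chem.Bond) -> object:
    if bond.GetIsAromatic() or bond.GetBondType() == Chem.BondType.AROMATIC:
        return "aromatic"
    table = {
        Chem.BondType.SINGLE: 1,
        Chem.BondType.DOUBLE: 2,
        Chem.BondType.TRIPLE: 3,
    }
    order = table.get(bond.GetBondType())
    if order is None:
        raise MoleculeFormatError(f"unsupported bond type {bond.GetBondType()}")
    return order


def from_rdkit(mol: Chem.Mol, molecule_id: str = "") -> MoleculeGraph:
    """Convert an RDKit molecule (hydrogens implicit) to a MoleculeGraph."""
    if mol.GetNumAtoms() == 0:
        raise MoleculeFormatError("empty molecule")
    atoms = [
        AtomRecord(index=a.GetIdx(), element=a.GetSymbol(), degree=0)
        for a in mol.GetAtoms()
    ]
    bonds = []
    for b in mol.GetBonds():
        i, j = sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        bonds.append(BondRecord(i=i, j=j, order=_rdkit_order(b)))
    return MoleculeGraph(atoms=atoms, bonds=bonds, molecule_id=molecule_id)


def to_rdkit(graph: MoleculeGraph) -> Chem.RWMol:
    """Build an RDKit molecule mirroring the graph (no sanitization-sensitive
    aromaticity re-perception; aromatic orders map to the aromatic bond type)."""
    m = Chem.RWMol()
    for a in graph.atoms:
        m.AddAtom(Chem.Atom(a.element))
    table = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
             3: Chem.BondType.TRIPLE, "aromatic": Chem.BondType.AROMATIC}
    for b in graph.bonds:
        m.AddBond(b.i, b.j, table[b.order])
    return m


def canonical_smiles(graph: MoleculeGraph) -> str:
    m = to_rdkit(graph)
    mol = m.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def parse_molecule(text: str, format: str = "smiles", molecule_id: str = "") -> MoleculeGraph:
    """Parse a single SMILES or SDF (MOL V2000) record into a MoleculeGraph.

    The graph keeps the input's atom order and only heavy atoms.  Aromatic
    perception follows RDKit, with aromatic bonds recorded as order
    ``"aromatic"``.  Multi-fragment inputs are rejected.
    """
    if format == "smiles":
        mol = Chem.MolFromSmiles(text, sanitize=True)
    elif format == "sdf":
        mol = Chem.MolFromMolBlock(text, sanitize=True, removeHs=True)
    else:
        raise ValueError(f"unknown format {format!r}")
    if mol is None:
        raise MoleculeFormatError(f"cannot parse {format} record: {text[:80]!r}")
    if len(Chem.GetMolFrags(mol)) > 1:
        raise MoleculeFormatError(f"multi-fragment input rejected: {text[:80]!r}")
    return from_rdkit(mol, molecule_id=molecule_id)


def read_smiles_file(path) -> list[MoleculeGraph]:
    """One molecule per line; optional tab-separated molecule_id after the SMILES."""
    graphs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"line{lineno}"
            graphs.append(parse_molecule(smiles, "smiles", molecule_id=mol_id))
    return graphs


def environment_atom_type(graph: MoleculeGraph, atom_index: int) -> str:
    """Canonical 1-hop environment label of an atom.

    Encodes the tuple (element, degree, sorted multiset of (neighbor element,
    bond order)).  Deterministic for isomorphic neighborhoods and invariant
    under atom relabeling.
    """
    if not 0 <= atom_index < graph.n_atoms:
        raise IndexError(f"atom index {atom_index} out of range [0, {graph.n_atoms})")
    atom = graph.atoms[atom_index]
    nb = graph.neighbor_bonds()[atom_index]
    parts = sorted(
        (graph.atoms[j].element, _ORDER_CODE[order]) for j, order in nb
    )
    env = ",".join(f"{el}{code}" for el, code in parts)
    return f"{atom.element}|{atom.degree}|{env}"


# ---------------------------------------------------------------------------
# Feature construction


@dataclass
class FeatureConfig:
    """Vocabularies defining the fixed one-hot feature layout.

    Each block (element, environment type, EC context) carries one extra
    out-of-vocabulary slot at its end; unseen symbols map there.  Setting
    ``use_envtype`` to False drops the environment-type block, the ablation
    that removes local-environment information from the per-atom row.
    """

    element_vocab: list[str]
    envtype_vocab: list[str]
    ec2_vocab: list[str]
    use_envtype: bool = True

    def __post_init__(self) -> None:
        for name in ("element_vocab", "envtype_vocab", "ec2_vocab"):
            vocab = getattr(self, name)
            if len(set(vocab)) != len(vocab):
                raise ValueError(f"{name} contains duplicates")

    @property
    def width(self) -> int:
        w = len(self.element_vocab) + 1 + len(self.ec2_vocab) + 1
        if self.use_envtype:
            w += len(self.envtype_vocab) + 1
        return w

    @classmethod
    def from_dataset(
        cls,
        graphs: list[MoleculeGraph],
        ec2_values: list[str],
        use_envtype: bool = True,
    ) -> "FeatureConfig":
        """Build vocabularies from a training collection (sorted for stability)."""
        elements: set[str] = set()
        envtypes: set[str] = set()
        for g in graphs:
            for a in g.atoms:
                elements.add(a.element)
                envtypes.add(environment_atom_type(g, a.index))
        return cls(
            element_vocab=sorted(elements),
            envtype_vocab=sorted(envtypes),
            ec2_vocab=sorted(set(ec2_values)),
            use_envtype=use_envtype,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "element_vocab": list(self.element_vocab),
                    "envtype_vocab": list(self.envtype_vocab),
                    "ec2_vocab": list(self.ec2_vocab),
                    "use_envtype": self.use_envtype,
                },
                fh,
                sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path) -> "FeatureConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "element_vocab": list(self.element_vocab),
            "envtype_vocab": list(self.envtype_vocab),
            "ec2_vocab": list(self.ec2_vocab),
            "use_envtype": self.use_envtype,
        }


@dataclass
class FeatureMatrix:
    """Per-atom feature rows in atom-index order."""

    values: np.ndarray
    width: int = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        self.width = self.values.shape[1]

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]


def _one_hot(symbol: str, vocab: list[str]) -> np.ndarray:
    v = np.zeros(len(vocab) + 1)
    try:
        v[vocab.index(symbol)] = 1.0
    except ValueError:
        v[-1] = 1.0  # OOV slot
    return v


def featurize(
    graph: MoleculeGraph, enzyme: EnzymeContext, config: FeatureConfig
) -> FeatureMatrix:
    """Per-atom row = one-hot(element) || one-hot(env type) || one-hot(ec2).

    The EC block is identical on every row of a molecule; unseen symbols land
    in the OOV slot of their block.
    """
    if not config.element_vocab or not config.ec2_vocab:
        raise ValueError("feature vocabularies must be non-empty")
    ec_block = _one_hot(enzyme.ec2, config.ec2_vocab)
    rows = []
    for a in graph.atoms:
        blocks = [_one_hot(a.element, config.element_vocab)]
        if config.use_envtype:
            blocks.append(
                _one_hot(environment_atom_type(graph, a.index), config.envtype_vocab)
            )
        blocks.append(ec_block)
        rows.append(np.concatenate(blocks))
    return FeatureMatrix(values=np.vstack(rows))
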