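import numpy as np
import pytest

from somgnn.molgraph import EnzymeContext
from somgnn.reaction import (
    Example,
    MappedPair,
    SOMLabels,
    SplitSpec,
    Transformation,
    build_examples,
    derive_atom_soms,
    derive_bond_soms,
    make_splits,
    parse_reaction_smiles,
    partition_examples,
    read_examples_jsonl,
    symmetry_adjust,
    write_examples_jsonl,
)
from somgnn.synthetic import SynthConfig, gen_molecules, gen_reaction_pairs

from conftest import make_graph


def amine_to_carbonyl_pair():
    """C-N single bond becomes C=O: the amine-to-carbonyl biotransformation
    where the heteroatom changes element and the shared bond gains order."""
    return parse_reaction_smiles("[CH3:1][NH2:2]>>[CH2:1]=[O:2]")


class TestAtomSOMs:
    def test_amine_to_carbonyl_labels_heteroatom_only(self):
        sub, prod = derive_atom_soms(amine_to_carbonyl_pair())
        assert sub.positives == frozenset({1})  # the nitrogen
        assert prod.positives == frozenset({1})  # the oxygen
        pair = amine_to_carbonyl_pair()
        assert pair.substrate.atoms[1].element == "N"
        assert pair.product.atoms[1].element == "O"

    def test_dehydrogenation_labels_both_carbons(self):
        pair = parse_reaction_smiles("[CH3:1][CH3:2]>>[CH2:1]=[CH2:2]")
        sub, prod = derive_atom_soms(pair)
        assert sub.positives == frozenset({0, 1})
        assert prod.positives == frozenset({0, 1})

    def test_identity_pair_has_no_soms(self):
        pair = parse_reaction_smiles("[CH3:1][OH:2]>>[CH3:1][OH:2]")
        sub, prod = derive_atom_soms(pair)
        assert sub.positives == frozenset()
        assert prod.positives == frozenset()

    def test_attachment_marks_anchor_on_both_sides(self):
        pair = parse_reaction_smiles("[CH3:1][CH3:2]>>[CH3:1][CH2:2]O")
        sub, prod = derive_atom_soms(pair)
        assert sub.positives == frozenset({1})
        assert prod.positives == frozenset({1})

    def test_empty_map_rejected(self):
        g = make_graph(["C", "C"], [(0, 1, 1)])
        with pytest.raises(ValueError):
            MappedPair(substrate=g, product=g, atom_map={})

    def test_equivariance_under_relabeling(self):
        pairs = gen_reaction_pairs(SynthConfig(n_molecules=20, seed=4))
        rng = np.random.default_rng(0)
        for pt in pairs[:10]:
            pair = pt.transformation.pair
            perm = list(rng.permutation(pair.substrate.n_atoms))
            sub_p = pair.substrate.permuted(perm)
            new_map = {perm[i]: j for i, j in pair.atom_map.items()}
            permuted = MappedPair(substrate=sub_p, product=pair.product,
                                  atom_map=new_map)
            sub0, prod0 = derive_atom_soms(pair)
            sub1, prod1 = derive_atom_soms(permuted)
            assert sub1.positives == frozenset(perm[i] for i in sub0.positives)
            assert prod1.positives == prod0.positives


class TestBondSOMs:
    def test_amine_to_carbonyl_marks_modified_bond(self):
        sub, prod = derive_bond_soms(amine_to_carbonyl_pair())
        assert sub.positives == frozenset({(0, 1)})
        assert prod.positives == frozenset({(0, 1)})

    def test_cleavage_marks_substrate_side_only(self):
        sub = make_graph(["C", "C", "O"], [(0, 1, 1), (1, 2, 1)])
        prod = make_graph(["C", "C"], [(0, 1, 1)])
        pair = MappedPair(substrate=sub, product=prod, atom_map={0: 0, 1: 1})
        bsub, bprod = derive_bond_soms(pair)
        assert (1, 2) in bsub.positives  # bond to the removed oxygen
        assert bprod.positives == frozenset()

    def test_identity_pair_empty(self):
        pair = parse_reaction_smiles("[CH3:1][OH:2]>>[CH3:1][OH:2]")
        bsub, bprod = derive_bond_soms(pair)
        assert bsub.positives == bprod.positives == frozenset()


class TestSymmetryAdjust:
    def test_glycol_oxygens_equivalent(self, glycol):
        labels = SOMLabels(target="atoms", positives={0}, side="substrate")
        out = symmetry_adjust(glycol, labels)
        assert out.positives == frozenset({0, 3})

    def test_asymmetric_graph_unchanged(self):
        g = make_graph(["C", "N", "O"], [(0, 1, 1), (1, 2, 1)])
        labels = SOMLabels(target="atoms", positives={0}, side="substrate")
        assert symmetry_adjust(g, labels).positives == frozenset({0})

    def test_idempotent_and_monotone_on_random_fixtures(self):
        mols = gen_molecules(SynthConfig(n_molecules=60, seed=9))
        rng = np.random.default_rng(1)
        for g in mols:
            k = int(rng.integers(1, g.n_atoms))
            labels = SOMLabels(
                target="atoms",
                positives=set(map(int, rng.choice(g.n_atoms, size=k, replace=False))),
                side="substrate",
            )
            once = symmetry_adjust(g, labels)
            twice = symmetry_adjust(g, once)
            assert labels.positives <= once.positives  # only ever adds
            assert once.positives == twice.positives  # idempotent

    def test_bond_mode_on_symmetric_graph(self, glycol):
        labels = SOMLabels(target="bonds", positives={(0, 1)}, side="substrate")
        out = symmetry_adjust(glycol, labels)
        assert out.positives == frozenset({(0, 1), (2, 3)})

    def test_all_positive_unchanged(self, glycol):
        labels = SOMLabels(target="atoms", positives={0, 1, 2, 3}, side="substrate")
        assert symmetry_adjust(glycol, labels).positives == frozenset({0, 1, 2, 3})


def _transformations(n):
    g = make_graph(["C", "O"], [(0, 1, 1)])
    pair = MappedPair(substrate=g, product=g, atom_map={0: 0, 1: 1})
    return [
        Transformation(pair=pair, ec_contexts=[EnzymeContext("1.4")],
                       transformation_id=f"T{i}")
        for i in range(n)
    ]


class TestSplits:
    def test_ten_transformations_split_8_1_1(self):
        splits = make_splits(_transformations(10), SplitSpec(n_splits=3, seed=0))
        for assignment in splits:
            counts = {p: sum(1 for v in assignment.values() if v == p)
                      for p in ("train", "validation", "test")}
            assert counts == {"train": 8, "validation": 1, "test": 1}

    def test_deterministic_given_seed(self):
        a = make_splits(_transformations(20), SplitSpec(n_splits=2, seed=5))
        b = make_splits(_transformations(20), SplitSpec(n_splits=2, seed=5))
        assert a == b
        c = make_splits(_transformations(20), SplitSpec(n_splits=2, seed=6))
        assert a != c

    def test_partitions_disjoint_and_exhaustive(self):
        ts = _transformations(23)
        for assignment in make_splits(ts, SplitSpec(n_splits=4, seed=1)):
            assert set(assignment) == {t.transformation_id for t in ts}

    def test_both_sides_share_partition(self):
        pts = gen_reaction_pairs(SynthConfig(n_molecules=30, seed=2))
        ts = [pt.transformation for pt in pts]
        examples = build_examples(ts, target="atoms")
        for assignment in make_splits(ts, SplitSpec(n_splits=2, seed=0)):
            for part in ("train", "validation", "test"):
                sub = partition_examples(examples, assignment, part)
                for ex in sub:
                    assert assignment[ex.transformation_id] == part

    def test_infeasible_ratio_raises(self):
        with pytest.raises(ValueError):
            make_splits(_transformations(5), SplitSpec(ratios=(0.8, 0.1, 0.1)))


class TestExamplesAndIO:
    def test_zero_positive_examples_dropped(self):
        ts = _transformations(3)  # identity pairs: no SOMs anywhere
        assert build_examples(ts, target="atoms") == []

    def test_ec_contexts_multiply_examples(self):
        pair = amine_to_carbonyl_pair()
        t = Transformation(
            pair=pair,
            ec_contexts=[EnzymeContext("1.4"), EnzymeContext("2.1")],
            transformation_id="T0",
        )
        examples = build_examples([t], target="atoms")
        # 2 sides x 2 EC contexts
        assert len(examples) == 4
        assert {e.ec2 for e in examples} == {"1.4", "2.1"}

    def test_provided_labels_take_precedence(self):
        pair = amine_to_carbonyl_pair()
        t = Transformation(pair=pair, ec_contexts=[EnzymeContext("1.4")],
                           transformation_id="T0")
        provided = {("T0", "substrate"): SOMLabels("atoms", {0}, "substrate")}
        examples = build_examples([t], target="atoms", sides=("substrate",),
                                  apply_symmetry=False, provided_labels=provided)
        assert examples[0].positives == frozenset({0})

    def test_jsonl_roundtrip(self, tmp_path):
        pts = gen_reaction_pairs(SynthConfig(n_molecules=15, seed=8))
        examples = build_examples([pt.transformation for pt in pts], target="atoms")
        path = tmp_path / "ds.jsonl"
        write_examples_jsonl(examples, path)
        loaded = read_examples_jsonl(path)
        assert len(loaded) == len(examples)
        for a, b in zip(examples, loaded):
            assert a.example_id == b.example_id
            assert a.positives == b.positives
            assert [x.element for x in a.graph.atoms] == [
                x.element for x in b.graph.atoms
            ]
            assert [(x.i, x.j, x.order) for x in a.graph.bonds] == [
                (x.i, x.j, x.order) for x in b.graph.bonds
            ]
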