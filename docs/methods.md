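# Methods

## Problem setting

Enzymes modify substrates at specific atoms or bonds — sites of metabolism
(SOMs).  Given a molecule and an enzyme class (the first two levels of an
EC number), the package scores every candidate site with a probability of
being a SOM.  Atomic prediction is node classification on the heavy-atom
molecular graph; bond prediction is link classification on its edges.  The
enzyme class enters only through the feature vector, so one model serves
all enzyme classes and the same substrate can be scored under different
enzymatic contexts.

Assumptions baked into the data model:

- Graphs are heavy-atom only, hydrogens implicit, consistent with
  connection-table style reaction databases where SOM candidates are heavy
  atoms.
- Molecules are single connected fragments; multi-fragment records are
  rejected rather than silently split, so data problems surface early.
- Aromatic bonds keep a distinct `"aromatic"` order instead of being
  kekulized, which keeps environment types independent of an arbitrary
  kekulization choice.

## Features

Each atom row is a concatenation of exactly-one-hot blocks, each with a
trailing out-of-vocabulary slot:

1. element symbol;
2. 1-hop environment type — the canonical string of (element, degree,
   sorted multiset of (neighbor element, bond order)).  This is the
   package's stand-in for curated atom-type labels from licensed
   databases: it captures an atom's local chemical environment, is
   deterministic for isomorphic neighborhoods, and is invariant under atom
   relabeling.  Its 1-hop radius is a design choice; a coarser or finer
   typing would slot into the same vocabulary mechanism.
3. the ec2 context (identical on every row of a molecule).

`use_envtype=False` removes block 2 — the ablation that measures how much
of the models' performance rides on precomputed local-environment
information versus what graph convolutions infer natively.

## Convolutions and heads

- **GIN**: `x'_i = MLP((1+ε)x_i + Σ_{j∈N(i)} x_j)`, ε learnable, MLP of
  depth 2 with ReLU inside.
- **MF**: `x'_i = W(deg i)·x_i + H(deg i)·Σ_j x_j` with separate learnable
  matrices per node degree, capped at 5 (organic heavy-atom degrees).
  Degree-0 nodes (single-atom molecules) reuse the degree-1 W with a zero
  neighbor term rather than crashing.
- **Cheb**: `x' = Σ_{k=1..K} Z(k)·Θ_k`, `Z(1)=x`, `Z(2)=L̄x`,
  `Z(k)=2L̄Z(k-1)−Z(k-2)`.  The normalized Laplacian is taken in the
  standard Chebyshev-convolution convention `L̄ = 2L_sym/λ_max − I` with
  λ_max fixed at 2, i.e. `L̄ = L_sym − I`, which keeps the spectrum inside
  [−1, 1]; the convention is recorded in the layer parameters
  (`laplacian_mode`).  Isolated nodes get an L_sym row of zero, hence
  L̄ = −I there.

Message passing uses the directed expansion of each undirected bond, the
standard realization of Σ_{j∈N(i)}.  A ReLU follows every trunk layer.
The node head is a final single-output convolution of the same type
followed by a logistic sigmoid.  The bond head drops that final
convolution and applies a classifier MLP to both endpoint concatenations;
the sigmoid is applied to each orientation's output *before* averaging, so
the reported bond value is an average of two probabilities.  The
orientation average makes the prediction exactly symmetric in endpoint
order (addition of two floats is commutative, so it is bit-exact).

All layers and training run on a small reverse-mode autodiff core over
numpy (`somgnn.nn.autograd`).  At this package's model sizes (hidden
64–512, depth 1–5, molecules of 5–25 atoms) training takes seconds per
model on one CPU, so no external deep-learning framework is required.

## Training and model selection

Adam (lr 0.01 by default, β = (0.9, 0.999)) minimizes unweighted binary
cross-entropy over all atoms (or bonds) of the training molecules;
probabilities are clipped at 1e−7 inside the loss for numerical safety.
No class reweighting is applied.  Batches are molecules (default 32),
assembled block-diagonally.  After each epoch the validation **molecular
R-precision** is logged, and the returned parameters are those of the best
validation epoch (ties keep the earlier epoch).  Batch size, learning
rate and epoch budget are surfaced in `TrainConfig`, not hard-coded; the
defaults were chosen once for the synthetic study conditions below.

Grid search trains one model per hyperparameter combination and selects by
validation molecular R-precision, ties broken by grid enumeration order.
Default grids: hidden {64, 128, 256, 512}, trunk depth 1–5, Cheb K 1–10,
MF degree cap 1–5; baseline grids: 100/250/500/1000 trees for the
ensemble methods, hidden {32, 64, 128, 256, 512} × depth 1–5 for the MLP.
The ensemble helper averages per-atom probabilities over a list of trained
models.  Checkpoints are single-file JSON archives carrying all parameter
tensors, the convolution type, the feature configuration, the seed and the
hyperparameters.

Baselines (random forest with Gini splitting, AdaBoost, MLP with Adam) are
fit on the identical per-atom feature rows with no graph context, via
scikit-learn, and scored with the same metric suite by grouping rows back
into molecules.  AdaBoost probabilities map the staged decision function
through the logistic function; no calibration is applied anywhere.
Current scikit-learn provides only the SAMME boosting variant, which is
what the package uses.

## Reaction-center labeling

From an atom-mapped substrate/product pair, per side:

- **atomic SOMs**: (a) mapped atoms whose counterpart has a different
  element; (b) mapped atoms at the boundary of added/removed substructure
  (adjacent to an unmapped atom on their own side, or whose counterpart is
  adjacent to an unmapped atom on the other side); (c) endpoints of bonds
  between mapped atoms whose existence changes.  For a *pure order
  change*, an endpoint already positive under (a)/(b) absorbs the change
  and the opposite endpoint is not added; only when neither endpoint is
  otherwise marked do both become centers.  The absorbing rule makes the
  canonical amine→carbonyl example come out right: when C–N becomes C=O,
  the heteroatom (N on the substrate side, O on the product side) is the
  SOM and the shared carbon is not.
- **bond SOMs**: bonds between mapped atoms whose counterpart bond differs
  in order or does not exist, plus bonds with an unmapped endpoint.

Externally provided center annotations, when present, are taken verbatim
and bypass the derivation.

A **symmetry adjustment** widens positives to all sites indistinguishable
from a labeled one under the molecule's symmetry.  Equivalence is computed
by iterated 1-hop color refinement over the element+bond-order-labeled
graph (the equitable partition that canonical atom ranking uses); the
operation is idempotent and only ever adds positives.  Refinement classes
can in principle merge non-equivalent atoms in highly regular graphs, but
coincide with automorphism orbits on molecule-like graphs at this scale.
Examples left with zero positives after labeling are dropped, because
molecular R-precision is undefined on them.

Splits are shuffle splits over whole *transformations*: both reaction
sides and all EC contexts of a transformation land in one partition, so no
information leaks between train and test via the mirrored molecule or a
shared enzyme annotation.  Validation and test sizes round down and the
remainder goes to train (80/10/10 on 10 transformations gives 8/1/1);
each split has its own seeded stream.

## Metrics

- AUROC with the mid-rank tie convention.
- R-precision: fraction of positives in the top-R, R = number of
  positives; ties in top-R selection break by ascending candidate index
  (a deterministic choice; any fixed rule would do).
- Top-two correctness: fraction of molecules whose two top-ranked sites
  include a positive.
- *Molecular* versions average per molecule, skipping molecules where a
  metric is undefined (single-class for AUROC, zero positives for
  R-precision) rather than imputing; skipped molecules are flagged in the
  per-molecule breakdown.  Molecules are weighted equally, not by atom
  count.  *Atomic* versions pool all candidates.
- Random-guessing expectations: the closed forms
  `Rprec = (1/R)·Σ_{i<R} (R−i)/(N−i)` and
  `TopTwo = (1/2)·Σ_{i<2} (R−i)/(N−i)` are implemented exactly as
  written.  For R ≥ 2 the summand models sequential draws that each hit a
  remaining positive and therefore differs from the exhaustive average
  over uniform orderings (e.g. R=2, N=4: 5/12 vs 1/2); both numbers are
  useful, so a brute-force enumeration estimator is provided separately
  and neither is substituted for the other.
- Stratified evaluation applies the full report independently per caller
  supplied stratum tag (e.g. CYP-like vs other enzyme classes); empty
  strata are reported as absent, never as zeros.

## Applications

A trained atom scorer turns into two decision tools:

- **Product screening**: a rule engine proposes a transformation at a
  reaction center; the candidate is kept iff the center's SOM probability
  is at or above a threshold (boundary inclusive).  Multi-atom centers
  aggregate by *minimum* — a transformation needs all of its center atoms
  to be reactive, so the center is only as likely as its least likely
  atom.  The threshold sweep reports per-category retention over
  0.0…1.0 in 0.1 steps from cached scores, so retention is non-increasing
  by construction.
- **Pathway ranking**: a pathway's likelihood is the product over steps of
  the best center option's score.  Because steps share no choices, taking
  the max per step equals the global max over all center combinations at
  linear cost.  Ranking quality against a reference group is summarized
  by AUROC.

## Synthetic study conditions

The generator exists to exercise the algorithms without licensed reaction
data; its defaults are the package's study conditions:

- molecules of 5–25 heavy atoms from {C, N, O, S, P} with weights
  0.60/0.15/0.15/0.05/0.05 (carbon-heavy), built as random spanning trees
  with ring probability 0.3 and double-bond upgrade probability 0.15,
  respecting valence caps C4/N3/O2/S2/P3;
- `rule0` (0-hop): oxygen atoms under EC context 1.4 — decidable from a
  single feature row, so every model class should learn it;
- `rule2` (2-hop): any atom bonded to a carbon that itself has at least
  three further carbon neighbors, under EC context 2.1.  The focal element
  is deliberately unconstrained so that the label is independent of the
  atom's own environment-free feature row: a row-wise classifier has
  nothing to learn from, while a graph model with a 2-hop receptive field
  can decide the label exactly.  (An element-restricted variant would
  leak most of the label through the element one-hot — with positives
  confined to one element at ≤ 20% abundance, row-wise baselines get a
  ~0.9 molecular AUROC floor from element identity alone, and the
  graph-context comparison would measure nothing.)  The three-neighbor
  count keeps label prevalence near 15%, inside the 4–20% band the
  generator targets;
- simulated reaction pairs: one sampled edit per base molecule (element
  substitution, element substitution with a paired bond-order change,
  bond-order change, substituent attachment or removal) with the full
  atom map and the planted centers recorded; product atom order is
  randomly permuted so maps are non-trivial;
- application fixtures: "confirmed" candidates / "engineered" pathway
  steps carry rule-satisfying centers, "unconfirmed"/"putative" ones carry
  uniformly random centers.

All randomness flows from one seed through per-(stage, index) streams, so
generating more molecules never perturbs earlier ones.  Study sizes used
by the test suite and the acceptance script: 500-molecule datasets with an
80/10/10 split, a Chebyshev model of hidden width 64, depth 3, K = 3,
trained ≤ 30 epochs; single-configuration baselines (100 trees; MLP
64×2).  These sizes were chosen once as the desk-scale conditions for the
package.

What the generator does **not** emulate: aromaticity, stereochemistry,
realistic functional-group chemistry, enzyme mechanism, or the label noise
of curated reaction databases.  Passing tests on planted rules therefore
demonstrates that the machinery is correct and that graph context is
learned where row features cannot suffice — not that any particular
real-data accuracy will be achieved.

## Numerical choices

- Glorot-uniform initialization from a per-model seeded generator; full
  determinism given the seed (numpy RNG only, single-threaded).
- BCE on probabilities with 1e−7 clipping; gradient masked inside the
  clipped region.
- Validation-epoch and grid ties keep the earlier candidate.
- `epochs=0` returns the initial parameters unchanged.
- Mid-rank AUROC via average ranks (scipy `rankdata`); degenerate inputs
  return an explicit undefined result (`None`), never a silent 0.

## Known limitations

- The 1-WL refinement used by the symmetry adjustment is a sound
  approximation of automorphism orbits for molecular graphs but not a
  proof-carrying one for arbitrary regular graphs.
- The bond head's MLP width equals the hidden width by default and is not
  part of the default search grid.
- The reaction-center derivation is a reconstruction from the atom map;
  curated center annotations, where available, should be passed through
  the `provided_labels` hook instead.
- No uncertainty calibration, GPU support, pre-training, or attention
  architectures.
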