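# Methods

## Reaction model

Educts and products are each one undirected, possibly disconnected graph.
Vertices carry element, formal charge and lone-pair count; edges carry
integer bond orders 1–3. Stereochemistry, isotopes, radicals and aromatic
perception beyond kekulisation are out of scope; aromatic input is
kekulised or rejected, because the electron bookkeeping needs integer bond
orders. Lone pairs are never parsed but derived as
`max(0, (valence_electrons − charge − Σ bond orders) / 2)`; an odd
remainder (a radical) is an error. Conceptually the lone pairs sit on the
diagonal of the adjacency matrix, so a broken bond (−1 off-diagonal) can be
balanced by a gained lone pair (+1 on the diagonal) in the row sums of the
reaction matrix ℛ<sup>m</sup> = 𝓞 − (𝓘 ∘ m).

**Hydrogen completion.** SMILES suppresses most hydrogens, but real
mechanisms usually shuffle at least one, so the production representation
is explicit-hydrogen. Each heavy atom is saturated to the smallest allowed
valence ≥ its bond-order sum: H 1, C 4, N 3, O 2, F/Cl/Br/I 1, P 3/5,
S 2/4/6. Charges shift the allowed valences by +q for N, P, O, S cations
and by q (i.e. down) for all anions; other charged species are rejected
rather than guessed. Exceeding every allowed valence is a "hypervalent
input" error.

**Atom ordering.** Vertex ids are the SMILES parse order; completed
hydrogens are appended afterwards, grouped behind their heavy-atom parent
in parent order. This fixed total order is what the symmetry-breaking
constraint and master-hydrogen selection refer to (any fixed order works;
this one is reproducible from the input text alone).

**Hydrogen-suppressed mode** keeps heavy atoms only and records the
implicit hydrogen count per atom; lone pairs are computed from the full
(implicit-inclusive) bond-order sum so that they agree with the explicit
representation. Worked examples printed without hydrogens are handled in
this mode; neighbourhood signatures then contain no `1H` entries, matching
how such examples are printed.

## Layout catalog

A layout is the pair (c₁..c_k, d₁..d_k): bond-order changes on the cycle
edges (c_k closes the cycle) and lone-pair changes at the vertices, valid
iff c_{i−1} + c_i + d_i = 0 at every vertex and some c_i ≠ 0. The shipped
catalog contains

* homovalent alternating cycles k ∈ {4, 6, 8}: c = (−1, +1, …), d = 0;
* for k ∈ {3, 5, 7}, the odd pseudo-bond layout — an alternating path
  closed by a 0-change edge whose endpoints carry d = +1 and −1 (the
  N⁺/O⁻-type pair) — and its sign-inverted variant;
* for k ∈ {3, 5, 7}, an odd cycle with every edge changing and a single
  defect vertex absorbing d = ±2 (one oxidation-state step), in both signs.

The precise numeric labels of the published odd-cycle sketches are not
machine-readable, so these are the minimal electron-balanced completions of
the described patterns; the catalog is deliberately loadable/overridable
from a YAML config rather than claimed exhaustive. Bond-change magnitude is
fixed to 1 in the shipped catalog.

## The CSP

Variables X<sup>I</sup>₁..X<sup>I</sup>_k over educt vertices and
X<sup>O</sup>₁..X<sup>O</sup>_k over product vertices. Constraints:
all-different per side; position-wise element equality; lone-pair change
lp(X<sup>O</sup>_i) − lp(X<sup>I</sup>_i) = d_i; degree compatibility
|degree(X<sup>I</sup>_i) − degree(X<sup>O</sup>_i)| ≤ 1; and per cycle edge
𝓞(X<sup>O</sup>_i, X<sup>O</sup>_j) − 𝓘(X<sup>I</sup>_i, X<sup>I</sup>_j) =
c_i, with 0-change pseudo bonds required present with equal positive order
on both sides.

* **Degree** means number of incident edges (distinct neighbours, bond
  order ignored). The alternative reading, bond-order sum, is implemented
  behind `degree_mode="bond_order_sum"`; the published candidate counts
  reproduce exactly under the incident-edge semantics, so that is the
  default.
* **Chord edges** (non-consecutive cycle pairs) are deliberately left
  unconstrained: CSP solutions are candidates, and chord changes are
  rejected later by the isomorphism stage, which tolerates no bond change
  outside the marked cycle.
* **Symmetry breaking**: for layouts invariant under rotation (the
  homovalent ones, period 2) the order constraint X<sup>I</sup>₁ <
  X<sup>I</sup>_i for all i > 1 is posted. Ambivalent layouts are anchored
  by their distinguished edge/vertex instead and get no order constraint.
  Note a factual point established while validating: the order constraint
  removes a factor of exactly k, not k/2 — each geometric alternating cycle
  admits k pattern-compatible traversals (k/2 phase-preserving rotations ×
  2 directions), because a direction-reversed traversal also begins with a
  breaking edge; fixing c₁ = −1 therefore does *not* exclude the reversal.
  The solution set without the constraint is closed under this free group
  action, and the measured count ratios are exactly 4 and 6 for k = 4, 6.
* **Solution counting** is over distinct (X<sup>I</sup>, X<sup>O</sup>)
  assignments, explicit hydrogens, symmetry breaking on. Under these
  semantics the five published basic-model counts (346; 73,924; 26,178;
  194,210; 20,640) and the extended count 36 reproduce bit-exactly.

**Extended model.** Three additions derived from comparing the two sides:
(1) per heavy atom only the lowest-index attached hydrogen (the "master")
remains in the domains — hydrogens in H₂ are never pruned; (2) from the
occurrence-wise multiset difference N_I ∖ N_O of neighbourhood signatures
(computed on the same representation the search uses, i.e. with explicit
hydrogens in production), the element multiset N^L is a lower bound on the
cycle's labels, enforced as counting constraints; (3) on complete
assignments, N_I ∖ N_O ⊆ ⟨N(A<sup>I</sup>_i)⟩ and the product-side
equivalent are checked. The extended count for the smallest benchmark
reaction comes out 76 where the original implementation reports 80; the
four-solution gap is consistent with a minor difference in its (unstated)
hydrogen-mastering tie-breaks and does not affect any reproduced target.

**Search** is depth-first with propagation to a fixpoint after each
assignment (trail-based undo): all-different on assignment, support
filtering for the paired label/lone-pair/degree constraint, presence and
exact-order filtering for cycle edges once endpoints are fixed. Branching
takes the variable with the smallest current domain (ties: lowest index)
and tries non-hydrogen values in ascending id before hydrogens, making
enumeration order deterministic.

**Oracle.** `brute_force_candidates` restates the solution set
declaratively — plain nested generate-and-test over ordered vertex tuples
with incremental checks, no domains, no propagation — and is guarded to
≤ 16 educt atoms. Solver/oracle set equality is asserted in the tests on
every small fixture and all catalog layouts.

## Map extension

The candidate's cycle edges are overwritten with markers f (formed),
b (broken), p (pseudo) at the same positions in both matrices; everything
else is untouched. Non-cycle hydrogens attached to heavy atoms are
collapsed into their neighbour's label together with a count (`C·3H`);
cycle atoms are never collapsed and additionally carry their cycle position
as a unique label, which pins the candidate correspondence — VF2 then
cannot remap the cycle, only the remainder. On cycle atoms the
charge/lone-pair fields are excluded from the node label (they
legitimately change in ambivalent layouts; the candidate already validated
them). Each VF2 isomorphism is expanded to a full bijection by pairing
absorbed hydrogens in ascending atom-id order (any pairing is valid by
symmetry; ascending makes it deterministic), deduplicated, and re-verified
atom by atom (element preservation, zero row sums). Atom maps reachable
from different candidates are deduplicated at the reaction level; both the
candidate count and the distinct-map count are reported.

## Synthetic generator

`plant_random_reaction` builds the cycle first — elements at d ≠ 0
positions are forced to N⁺ (d = +1) or O⁻ (d = −1), breaking/pseudo bonds
are wired in, forming pairs left absent — then decorates with random C/N/O
atoms under shared educt/product valence capacity, occasionally with double
bonds, completes hydrogens and applies the layout to obtain the products
under a random vertex permutation. The ground-truth map is the permutation
plus ascending hydrogen pairing; the planted candidate is normalised to the
solver's symmetry convention. Deterministic per seed.

What it emulates: valence-correct, mass-balanced single-step reactions with
a known cycle, including the hydrogen-interchange symmetry that dominates
real search spaces. What it does not: realistic functional-group
distributions, rings outside the planted cycle, charge chemistry beyond the
N⁺/O⁻ pattern, and multi-step mechanisms — so passing recovery tests shows
soundness and completeness of the pipeline on in-model inputs, not
mechanism selectivity on arbitrary chemistry.

## Problem sizes and determinism

The test suite enumerates the five benchmark reactions completely
(the largest, 44 atoms at k = 4, yields 194,210 candidates in seconds) and
runs 100 seeded planted-recovery instances with 6–8 heavy atoms at
k ∈ {4, 6} in the extended model, the package's production configuration.
All randomness flows through explicit seeds; identical inputs give
identical outputs, including enumeration order.

## Known limitations

* Elementary (single-cycle) mechanisms only; fused multi-step layouts are
  not modelled.
* The valence model covers common organic species (H, C, N, O, P, S,
  halogens); exotic charge states are rejected, not approximated.
* Candidate-level feasibility is weaker than mappability: e.g. the
  hydrogen-suppressed Diels-Alder example has 37 four-cycle candidates
  (double bonds may lose one order), none of which extends — minimal
  feasible cycle size is therefore defined by complete maps, not by CSP
  feasibility.
* Symmetric spectator groups (e.g. two methyls on one nitrogen) yield
  several equivalent atom maps; no molecular-symmetry quotient is applied
  beyond hydrogen collapsing.
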