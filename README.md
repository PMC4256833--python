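# itsmap

Atom–atom mapping of chemical reactions by explicit search for the cyclic
**imaginary transition state (ITS)**, using finite-domain constraint
programming followed by graph-isomorphism extension.

## The problem

A chemical reaction transforms educt molecules into product molecules while
every atom is conserved, so there is a bijection — the *atom map*
m : V_I → V_O — between the atoms of the educt graph I = (V_I, E_I) and the
product graph O = (V_O, E_O). Reaction databases rarely record this map,
yet it carries the entire mechanism: which bonds break, which form. Most
computational approaches recover m by maximum-common-subgraph optimisation,
whose objective is chemically arbitrary and provably misses true maps.

`itsmap` instead searches directly for the chemically constrained object:
for elementary reactions the changing bonds form a small *alternating
cycle* — bonds broken and formed in strict alternation over k ≈ 4–8 atoms.
Writing 𝓘 and 𝓞 for the bond-order adjacency matrices (lone electron pairs
on the diagonal), a chemically correct atom map satisfies

* l(x) = l(m(x)) for every atom x (element preservation), and
* ℛ<sup>m</sup> · **1** = **0**, where ℛ<sup>m</sup> = 𝓞 − (𝓘 ∘ m) is the
  *reaction matrix*: every broken bond is compensated by a formed bond or a
  lone-pair (oxidation-state) change, atom by atom.

The nonzero entries of ℛ<sup>m</sup> are the ITS. *Homovalent* reactions
(no oxidation-state changes) have even alternating ITS cycles; *ambivalent*
reactions admit odd cycles with charged atoms joined by an unchanging
pseudo bond.

## How it works

1. **`chem_graph`** — reaction SMILES in and out (via RDKit), explicit
   hydrogen completion under a charge-adjusted standard-valence model, and
   lone-pair annotation from `(valence_electrons − charge − Σ bond orders)/2`.
2. **`its_layouts`** — a validated, config-extensible catalog of cycle
   layouts: per cycle edge a bond-order change c_i ∈ {−1, 0, +1}, per vertex
   a lone-pair change d_i, with c_{i−1} + c_i + d_i = 0 everywhere.
3. **`its_search`** — the CSP. Variables X<sup>I</sup>, X<sup>O</sup> place
   the cycle in educts and products under all-different, label equality,
   lone-pair change, degree compatibility (|Δdegree| ≤ 1), the cyclic
   bond-change pattern, and an order constraint breaking rotation symmetry.
   The *extended* model adds master-hydrogen domain pruning, label
   cardinalities from the neighbourhood multiset difference N_I ∖ N_O, and a
   post-assignment neighbourhood check (**`neighborhoods`**). Search is DFS
   with propagation, min-domain branching, non-hydrogens first. A
   generate-and-test oracle independently rechecks the solution set on
   small inputs.
4. **`map_extension`** — each candidate's cycle edges are relabelled with
   f/b/p markers identically on both sides; non-cycle hydrogens are
   collapsed into their heavy atom's label; VF2 enumerates the
   label-preserving isomorphisms, which are exactly the complete atom maps
   extending the candidate.

## Worked example

The Diels-Alder cycloaddition of isoprene and vinylamine
(hydrogen-suppressed, as usually drawn):

```
$ itsmap map --reaction "C=C(C)C=C.C=CN>>NC1CCC(C)=CC1" \
             --suppress-hydrogens --mode basic --layouts homovalent --all
# homovalent-4	k=4	candidates=37	extendable=0	maps=0
# homovalent-6	k=6	candidates=18	extendable=1	maps=1
# homovalent-8	k=8	candidates=0	extendable=0	maps=0
# minimal_k=6
homovalent-6	6	[CH2:1]=[C:2]([CH3:3])[CH:4]=[CH2:5].[CH2:6]=[CH:7][NH2:8]>>[NH2:8][CH:7]1[CH2:6][CH2:1][C:2]([CH3:3])=[CH:4][CH2:5]1
```

Reading the output: 37 four-cycle candidates satisfy the local CSP
constraints but none extends to a full atom map; the six-membered
alternating cycle — the pericyclic mechanism — admits exactly one, and the
annotated SMILES assigns each educt atom (`:n`) to its product image. The
methyl carbon (`:3`) and the amine nitrogen (`:8`) stay outside the
transition state, as expected for spectator substituents.

The same pipeline is available as a library:

```python
from itsmap import RunConfig, parse_reaction, run_mapping

rxn = parse_reaction("C(=O)=O.C(C(=O)O)(C=O)O>>C(=O)(C=O)O.C(=O)(C=O)O")
res = run_mapping(RunConfig(reaction=rxn, mode="extended", output="first"))
print(res.minimal_k)          # 6
print(res.mapped_smiles[0][2])  # annotated reaction SMILES
```

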