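# monomerizer

Infer the **monomeric structure** of a small biological polymer from its
**atomic structure** (SMILES).

Nonribosomal peptides, glycopeptides and other secondary metabolites are
assembled enzymatically from building blocks — amino acids (often
non-proteinogenic), sugars, lipids — yet chemical databases usually record
only their atomic structure. Knowing which monomers a polymer contains, and
which atoms belong to each, is what lets curators annotate compounds in
monomer-centric databases, compare polymers at the building-block level, and
connect genome-mining predictions to chemistry. `monomerizer` reconstructs
that decomposition automatically, for curators and cheminformaticians working
with peptide-like polymers.

## Method

Monomers lose atoms when they bond (a carboxylic acid loses OH in a peptide
bond; an amine loses H). Truncated monomers are called *residues*. The
pipeline:

1. **Residue families** — chemical reaction rules (SMARTS functional group +
   atoms lost + link atom) are applied recursively to each monomer. All
   residues of a monomer form a DAG; deeper residues have more bonds formed,
   and the unique smallest one is the *root*. A residue of level *i* is
   totally included in its parents of level *i − 1*.
2. **Indexed search** — molecules are transformed into *line graphs* (nodes =
   covalent bonds, adjacent when sharing an atom), which multiplies label
   diversity (element pair × bond order × hydrogen counts). Strict bond-label
   frequencies learned on a polymer corpus drive a dynamic program that picks,
   per root residue, the connected node order minimising the expected number
   of surviving partial embeddings, `Σ_k Π_{j≤k} p(label_j)`. A
   branch-and-bound subgraph isomorphism then enumerates *every* occurrence of
   the root; larger family members are found by localised extension of the
   matches of their smaller descendants, and an absent residue prunes all of
   its ancestors. Two bond predicates are available: **strict** (elements,
   multiplicity, hydrogen counts as lower bounds) and **light** (elements
   only; tolerates tautomery).
3. **Tiling** — from the overlapping matches, a greedy algorithm ranked by
   size ↓, attachment points ↑, bond-rule priority ↓ selects a pairwise
   disjoint cover. If atoms remain uncovered, *modulation* removes tiles
   bordering the gap, re-searches the region with light matching and re-tiles;
   a local branch-and-bound then refines each remaining gap exactly under a
   node budget. Coverage never decreases across stages.

Outputs per polymer: the selected tiles (monomer name + atom ids), the
**coverage rate** (covered atoms / total heavy atoms) and, when a curated
structure is known, the **correctness rate** (atoms in exactly-agreeing tiles
/ total heavy atoms), with per-polymer classes TP / FP / FN and
recall = TP/(TP+FN), precision = TP/(TP+FP).

## Worked example

Glutathione is the tripeptide γ-Glu–Cys–Gly; the glutamate links through its
*side-chain* carboxyl, so a naive sequence view fails but the graph search
does not:

```python
from monomerizer import default_monomers, default_rules
from monomerizer.pipeline import Annotator

ann = Annotator(default_monomers(), default_rules())
res = ann.annotate("NC(CCC(=O)NC(CS)C(=O)NCC(=O)O)C(=O)O", name="glutathione")
print(res.to_dict())
```

prints (abridged):

```
{'polymer': 'glutathione',
 'tiles': [{'monomer': 'Glutamate', 'residue_level': 1, 'atoms': [0, 1, 2, 3, 4, 5, 17, 18, 19], 'mode': 'strict'},
           {'monomer': 'Cysteine',  'residue_level': 2, 'atoms': [6, 7, 8, 9, 10, 11], 'mode': 'strict'},
           {'monomer': 'Glycine',   'residue_level': 1, 'atoms': [12, 13, 14, 15, 16], 'mode': 'strict'}],
 'coverage_rate': 1.0,
 'uncovered_atoms': []}
```

Every heavy atom is assigned (`coverage_rate` 1.0). The cysteine tile is a
level-2 residue — it lost atoms to two bonds (amide on each side) — while the
terminal glutamate and glycine are level-1 residues. Atom ids refer to the
input SMILES order.

The same pipeline is scriptable from the shell:

```bash
monomerizer simulate --n 10 --seed 1 --out polymers.json     # ground-truth set
monomerizer annotate --input polymers.json --out ann.json    # annotate it
monomerizer evaluate --annotations ann.json --truth polymers.json
monomerizer build --out families.json                        # families + indexes
```

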