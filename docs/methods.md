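# Methods

## Molecular graph model

Molecules are hydrogen-suppressed graphs: nodes are heavy atoms (element,
folded hydrogen count, aromatic flag, formal charge), edges are covalent bonds
with order ∈ {single, double, triple, aromatic}. SMILES parsing and writing,
aromaticity perception and SMARTS matching are delegated to RDKit; input atom
order is preserved (no canonicalisation of targets), so every match is
reported in the coordinates of the submitted SMILES. Stereochemistry and
formal charge are parsed but ignored by both matching predicates: the matching
semantics are purely constitutional, and charge-sensitive matching would make
tautomer tolerance (the point of light matching) harder, not easier.

The search operates on the *line graph* — one node per bond, nodes adjacent
when bonds share an atom, atom origins retained inside each node. Natural
organic polymers use only a handful of element labels, which makes atom-level
labels unselective; bond-level labels (element pair × order × hydrogen
counts) are far more discriminating, and keeping atom origins preserves exact
structure (cyclopropane vs isobutane).

### Matching predicates

* **strict** — element pair and bond order must agree (aromatic is its own
  order), and each query endpoint's hydrogen count is a *lower bound* on the
  target atom's. The lower-bound (not equality) semantics is deliberate: a
  residue models a monomer that has already lost hydrogens to the bonds its
  rules formed, while the polymer atom may additionally carry substituents
  only outside the residue — never extra hydrogens inside it.
* **light** — element pair only. Order, aromaticity and hydrogens are ignored,
  tolerating proton/electron moves (tautomery) and unusual bonding.
  Strict ⇒ light by construction.

Single-atom residues have an empty line graph; they are matched directly on
polymer atoms with the same endpoint predicate. This is the minimal extension
consistent with the bond-level semantics.

## Reaction rules and residue families

A rule is: a SMARTS pattern with atom maps for the functional group, the map
numbers of atoms deleted on bond formation (mapped hydrogens become
hydrogen-count decrements on their heavy neighbour), the map number of the
attachment atom, a `standalone` flag (can this bond type occur as a monomer's
only bond?) and a positive `priority` (relative frequency of the bond type in
the target polymer class). Pattern embeddings are collapsed by *effect* —
deleting either hydrogen of an NH₂ is one site.

A family is generated by enumerating every subset of pairwise-compatible
(rule, site) applications on the intact monomer: compatible means disjoint
heavy-atom deletions, jointly satisfiable hydrogen decrements, and no
application deleting another's attachment atom. A subset's residue is the
monomer minus the union of deletions; its level is the subset size. Subsets
whose every member is non-standalone are excluded — the corresponding level-1
residues cannot exist, so nothing built only on them is reachable. Residues
reached by different subsets are merged when their graphs are isomorphic
(label-preserving, via VF2), giving a DAG whose edges add one application.
The *root* is the unique residue of minimal size (heavy atoms + hydrogens);
with mutually compatible applications it is the all-applications residue.
Applying the same rule at several distinct sites is allowed and enumerated in
full; the number of same-type applications is bounded only by site
compatibility. The untruncated monomer (level 0) is never searched: inside a
polymer a monomer has always lost atoms to at least one bond.

The packaged default rules are peptide bond from NH₂ (priority 10), peptide
bond from C(=O)OH (priority 10) and the disulfide SH bond (non-standalone,
priority 1); the packaged monomer database holds the 20 proteinogenic amino
acids. Aromatic ring nitrogens (indole, imidazole) are deliberately excluded
from the amine rule by the aliphatic-N SMARTS.

## Index construction

Strict bond-label frequencies are counted over the line graphs of a learning
polymer set, with add-one smoothing over the observed alphabet plus one
unseen slot: `p(ℓ) = (count(ℓ) + s) / (total + s·(|observed| + 1))`, default
s = 1. Unseen labels therefore get the smallest — maximally selective —
probability, never zero. Without a learning set a uniform no-information
model is used; every index order remains valid because the order affects
speed only.

The index of a residue is a connected ordering of its line-graph nodes
minimising

    cost(order) = Σ_k Π_{j≤k} p(label_j)

— the first-order (Markovian independence) estimate of the number of partial
embeddings alive after each prefix, summed over prefixes. Because the product
over a prefix depends only on the prefix *set*, subsets are valid DP states:
`cost(S) = Π_{j∈S} p_j + min_v cost(S∖v)` over removable nodes keeping the
prefix connected. The exact subset DP runs for components of ≤16 nodes
(65 536 states); larger components fall back to a greedy rarest-extension
order. Ties are broken toward the lexicographically smallest order, making
index construction deterministic. Disconnected residues are indexed per
component and concatenated rarest-component-first. The safety contract —
verified by test — is that search results are identical under any valid
connected order.

## Search

The branch-and-bound walks the index order, assigning each query bond to a
compatible polymer bond. Atom origins give the pruning: an endpoint already
mapped forces the image bond to be incident to its image (candidates come
from the anchor atom's incident bonds), injectivity is enforced at the atom
level, and any predicate violation abandons the partial assignment. The
enumeration is complete; embeddings mapping to the same polymer atom set are
reported once (automorphism collapse), since the tiler consumes atom sets. A
per-residue match cap (default 10 000) turns pathological self-similarity
into a warning rather than unbounded runtime.

Family search starts at the root. A residue with children in the DAG is
searched only if every child matched (a parent's embedding restricts to an
embedding of each child), and only inside the union of its children's match
atom sets dilated by the parent/child atom-count difference — for a connected
parent every embedding containing a child match lies inside that dilation, so
locality costs no completeness. The design searches a *region* around child
atom sets rather than re-anchoring one stored atom map because automorphism
collapse keeps a single arbitrary mapping per atom set; on symmetric residues
that one mapping need not extend to every parent embedding, whereas the
dilated-region search provably finds them all. Disconnected parents (rare:
a deletion can split a residue) fall back to full search.

## Tiling

Tiles are ranked by: size descending (large residues rarely match by
chance), attachment-point count ascending (few formed bonds is the more
probable configuration), aggregate bond-rule priority descending (polymers
are built mainly by one bond chemistry), then a canonical key (monomer name,
sorted atom ids, level) so the whole pipeline is deterministic. The greedy
pass accepts tiles in rank order when disjoint from everything accepted.
A tile's attachment count equals its residue's number of rule applications —
each application creates exactly one link point.

Modulation (when coverage < 1): tiles sharing a bond with an uncovered atom
are removed, the light family search runs over the uncovered region plus the
removed tiles' atoms, the greedy pass re-runs over retained + newly found
tiles, and the better tiling (coverage, then rank-score, i.e. the sorted tile
rank keys) of before/after is kept — so coverage is non-decreasing by
construction. One round is the default; the small minority of polymers that
remain partially covered go to refinement.

Refinement: per connected uncovered component (dilated by adjacent selected
tiles), an exact include/exclude branch-and-bound over the candidate tiles
touching the region, with tiles outside the region frozen, objective =
covered atoms with rank-score tie-break, optimistic bound = current cover +
total size of remaining candidates, node budget 100 000 (exceeding it keeps
the best solution found and warns). On pools of ≤15 candidates this equals
exhaustive subset enumeration (tested); in general the result is adequate
rather than provably optimal, which is the intended trade-off.

## Synthetic ground truth

The generator assembles polymers by executing the same reaction rules the
search assumes: draw monomers, pick a rule pairing per bond (default
experiment: acid ↔ amine), delete each side's lost atoms, join the attachment
atoms with a single bond, and record each unit's surviving atoms as a truth
tile. Topologies: linear chains, branched trees (parents chosen among units
with free sites), cycles. The default experimental condition — used by the
acceptance script and the recovery tests — is 100 polymers of 3–8 units,
alternating linear/branched, over the complete 20-amino-acid database; with a
complete database and no tautomeric distortion the pipeline should and does
reconstruct every polymer exactly, which is the upper bound that real curated
data (with database errors, exotic monomers and tautomery) approaches from
below. What the generator does **not** emulate: wrong or inconsistent SMILES,
monomers absent from the database (probed separately by deleting one monomer),
non-single inter-monomer bond orders, ring-forming intramolecular reactions,
and tautomeric rewriting of the assembled structure — so perfect recovery here
bounds, but does not guarantee, accuracy on real curated databases.

Correctness is all-or-nothing per tile: an atom counts as correct only inside
a predicted tile whose monomer name *and* atom set exactly match a truth
tile. This is the stricter of the defensible readings of per-atom
correctness; partial-overlap credit would only raise reported rates. All
rates are over heavy atoms.

## Numerical and degenerate-input choices

* Ties anywhere (rank, index order, DAG ids) break by canonical sort keys;
  the pipeline is fully deterministic given a seed.
* Probabilities are exact floats in (0, 1]; the index DP compares sums of
  products of ≤ ~30 factors, far from underflow for realistic residues.
* Empty learning set → explicit error (or use the uniform model); monomers
  matching no rule → empty family, reported via `unreactive_monomers`,
  skipped in search.
* Bond-free polymers (single atoms) are annotatable; only bond-free residues
  can match them.
* Cyclic topology needs ≥3 units; assembly resamples incompatible draws and
  fails loudly after bounded retries.

## Known limitations

* The index cost model is a first-order independence approximation; it
  optimises expected search effort, not worst case.
* Light matching ignores bond orders entirely, so it can propose chemically
  implausible matches in gap regions; modulation only accepts them when they
  improve coverage.
* Inter-monomer bonds are not labeled with their rule type in the output, and
  unknown monomers are not proposed for uncovered regions; both are natural
  extensions of the residue machinery but out of scope here.
* Matching is constitutional only: stereoisomers are indistinguishable.
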