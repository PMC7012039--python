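# Methods

## Reaction curation and hashing

Input records are Daylight reaction SMILES `reactants>agents>products`
(UTF-8, one record per line, optionally tab-separated with an id and a
class label; `#` comments and blank lines are skipped).  Because the
reactant/agent distinction is ambiguous and templates are driven by atom
maps alone, agents are folded into the reactant list at parse time.
Records with more than two `>` separators (multi-step dumps) are rejected
as unparseable, as are records with a duplicated atom-map index on one
side.  Curation then rejects records that (a) lack a reactant or product
side, (b) have more than one product, or (c) are identities — the two
sides compared as sorted multisets of de-mapped standard InChIs.

Reaction identity is a SHA-256 digest of the de-mapped per-species
standard InChIs, sorted lexicographically within each side and
concatenated reactants-then-products.  The sort realizes order invariance
deterministically; de-mapping first makes the digest independent of the
mapper's numbering.  Stereochemistry stays in the standard InChI layers,
so enantiomeric reactions hash apart.  Template SMIRKS are hashed the same
way after canonical renumbering of their atom maps.  Deduplication keeps
the first record per digest, so input order determines which duplicate
survives (their chemistry is identical by construction).

## Template extraction

The reaction center is the set of product atoms whose environment differs
from their mapped reactant counterpart: formal charge, total H count,
stereo-specification flag, the multiset of (mapped-neighbor, bond-order)
pairs, or the count of unmapped neighbors.  Charge-only changes therefore
count as center atoms.  Extraction requires a fully mapped product whose
map indices all appear on the reactant side; anything else is a per-record
extraction failure and the reaction is discarded (mirroring corpus
practice, where species lost by the mapper make a template unusable).

The product-side pattern covers the center, atoms within `radius` bonds
(default 1), and — regardless of radius — all atoms of any group-library
match that overlaps that neighborhood.  Pattern atoms carry element,
aromaticity, total H count, and formal charge; this makes templates
moderately specific (an alcohol O with one H will not match an ether O),
which is exactly the specificity knob the radius sweep studies.  The
reactant side keeps the corresponding mapped atoms plus connected leaving
atoms absent from the product, written with explicit H counts so that
application restores the correct protonation; reactant species
contributing no product atom (agents, spectators) are dropped.  Atom maps
are canonically renumbered from the canonical fragment-output order, so
the same chemistry extracted from different reactions yields the same
SMIRKS text and hash.

Atom-level stereo tags are not emitted into the pattern atoms: the
synthetic corpora used for development are achiral and the query-atom
writer keeps only element/H/charge.  Templates from stereo-rich corpora
will conflate enantiomeric transforms; this is a known limitation.

The shipped group library (`data/protecting_groups.smarts`, ~75 entries)
covers the protecting groups and functional groups common in organic
synthesis.  Variable-length variants (silyl/ester alkyl chains) are
matched by a representative core pattern rather than an exhaustive
enumeration; the file is user-replaceable.

Application compiles the SMIRKS with RDKit and runs it on the query
compound; each distinct substructure-match outcome becomes one precursor
set, outcomes with unparseable precursors are dropped, and outcomes equal
as de-mapped InChI multisets are merged.  A match cap (default 100)
guards degenerate symmetric inputs.  Validation re-applies a template to
its own source product: *precise* if only the source reactants come back,
*selective* if they come back among others, *unselective* if never,
*failed* if nothing matches.

Template libraries accumulate occurrence counts per template hash over
the deduplicated corpus and drop templates below `min_count` (the sweep
values 1–100 are a configuration, not a constant).  Ordering is by
descending count then ascending hash, making label indices reproducible
under input permutation.

## Policy network

Products are ECFP4 fingerprints: Morgan radius 2 folded to 2048 binary
bits (the fingerprint width has little effect and is configurable).
Records whose template fell below the occurrence cut-off are excluded so
the label space equals the library.  The data are shuffled and split
90/5/5 with a fixed seed (42 by default).

The classifier is input → 512 ELU units → softmax, L2 coefficient 0.001,
dropout 0.04 after the hidden layer, trained with Adam at learning rate
0.001 on categorical cross-entropy.  The validation loss drives both the
plateau schedule (×0.5 after 5 stale epochs, floored at 10⁻⁶ — the floor
avoids underflow on long runs) and early stopping (10 stale epochs, best
weights restored).  Top-1/5/10/50 accuracies are recorded every epoch.
The network is implemented directly on NumPy: at these sizes a
hand-written forward/backward pass with a single seeded RNG for
initialization, shuffling, and dropout gives bitwise-reproducible training
on one device.  Batch size 128 and an epoch cap of 500 are desk-scale
defaults, both configurable.  Weight initialization is uniform
Glorot-style.

## Applicability

`assess_applicability` ranks the library for each compound, applies each
of the top N templates (N = 50 by default), and counts those producing at
least one valid precursor set — a template counts once regardless of how
many sites it matches, since the metric asks whether a disconnection is
available at all.  "Successful" means subgraph match plus valid SMILES;
chemical feasibility is deliberately out of scope.  The exhaustive
variant applies the whole library and doubles as the independent oracle
in the tests.  Assessment sets are prepared by salt stripping (largest
fragment by heavy-atom count) followed by a seeded random subset.

## Tree search

States hold the molecules still to be made and each molecule's transform
count from the root.  Expansion queries the policy for every molecule
below the transform cap and keeps the smallest ranked prefix reaching
cumulative probability 0.995, capped at 50, storing actions at the parent
with Q = 0.5 and N = 1 (expansion counts as a first visit).  Priors are
recorded but not used in selection.  Children are instantiated lazily;
when a template produces several distinct outcomes the lexicographically
smallest precursor set is taken, keeping instantiation deterministic.  A
failing action gets Q = −10⁶ and no child.

Selection uses the standard UCT score `q/n + C·sqrt(ln N_parent / n)`
(C = 1.4); the terminal reward is

    r = 0.95 · N_in_stock/N + 0.05 · (1 − depth/max_transforms)

where depth is the maximum per-molecule transform count.  The reward is
1 exactly when the target itself is purchasable, increases with the
in-stock fraction, and prefers shallower terminal states at equal stock
fraction; the stock weight is configurable.  Ties in selection and
rollout are broken uniformly with the run seed.  Rollout re-uses ordinary
node creation, so its expansions remain in the tree for later
iterations.  Backpropagation adds the terminal reward to every traversed
action (Q += r, N += 1) and bumps each node's visit count.

`max_transforms` defaults to 7 — deep enough for typical 4-step routes
with headroom — and the iteration/time limits default to 1000 and 120 s.
Search ends early when a fully-in-stock state is found (optional).  Stock
membership is full 27-character standard InChIKey equality; no
connectivity-only relaxation is applied.

## Synthetic worlds

The generator emulates a reaction corpus with known ground truth.
Seventeen coupling families (acid/acid-chloride esterification and
amidation, O/N/S-alkylations split by Br/Cl/I leaving group, sulfonamide,
sulfonate, carbamate, biaryl coupling, Boc deprotection) are instantiated
over homologous building-block series; the transform itself writes the
atom maps, so mapping is correct by construction.  Within a family every
block shares the attachment shell (a primary CH2), making the radius-1
template unique per family — planted multiplicities are therefore exact —
while radius ≥ 2 splits families by the blocks' outer shells, giving the
radius sweep its ground truth.  Block pools are partitioned between
families whose products would otherwise coincide (acid vs acid-chloride
acylation; Br vs Cl vs I alkylation of the same partners), so the
product → template-class mapping is single-valued for policy training.
Long unbranched homologs are excluded from the substituent set because
their folded binary fingerprints coincide, which would blur class labels.

Routes are planted by elaborating bi-/tri-functional cores (amino-alcohol,
amino-thiol-alcohol) step by step with mono-functional blocks; each step's
reaction joins the corpus and the stock is the set of all blocks and
cores, so every route terminates in stock.  A corruption pass injects
permuted-and-renumbered duplicates, identity records, multi-product
records, and scrambled atom maps in known quantities for curation tests.

What the toy worlds do **not** emulate: reagent/condition effects,
yield, selectivity conflicts, stereochemistry, ring-forming
disconnections, and the heavy-tailed template frequency and noise of
mined corpora.  Passing tests therefore demonstrate the correctness of
the machinery (curation, hashing, extraction, ranking, search
bookkeeping), not wet-lab viability of proposed routes — the same caveat
that applies to template-based CASP baselines generally.

## Problem sizes and numerics

The test suite and the acceptance script run on worlds of 100–750
reactions, policies of ≤ 2048×512×~20 weights trained ≤ 60 epochs, and
searches of ≤ 500 iterations — sizes chosen so a complete from-scratch run
is a desk-scale job while still exercising every code path.  Softmax is
computed with max-shift; cross-entropy clips probabilities at 10⁻¹².
Library label order, split indices, training, and search are all driven
by explicit seeds, and regenerating any artifact with the same seed is
bitwise identical.
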