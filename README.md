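# retrotree

A baseline template-based computer-assisted synthesis planning (CASP)
toolkit.  Given a corpus of atom-mapped reaction SMILES, `retrotree`

1. **curates** the records (single product, complete, non-identity) and
   deduplicates them with an order- and atom-map-invariant InChI hash,
2. **extracts retro-direction SMIRKS templates** around the reaction
   center at a configurable radius, augmented with ~75 functional and
   protecting groups (Boc, Cbz, Fmoc, silyl ethers, esters, sulfonyls, ...),
   and validates each template by re-applying it to its own product
   (*precise* / *selective* / *unselective* / *failed*),
3. trains a single **template-prioritization policy network** — ECFP4
   fingerprint → 512 ELU units → softmax over the occurrence-filtered
   template library,
4. measures **top-N template applicability**, the task-specific
   complement to test accuracy: how many of the N highest-ranked templates
   actually produce valid precursors for a compound, and
5. runs a **Monte-Carlo tree search** that recursively deconstructs a
   target until every precursor is in a purchasable-stock set keyed by
   InChIKey.

It is aimed at method developers who want a small, fully inspectable
baseline for retrosynthesis experiments: every stage is a plain Python
function over RDKit molecules, and a built-in synthetic-world generator
makes the whole pipeline testable without any external dataset.

## The model in brief

A retro template is a rewrite rule `product_pattern >> reactant_patterns`
covering the reaction center (atoms whose bonds, H count, charge or stereo
flag change), all atoms within `radius` bonds of it (default radius 1, the
first-degree neighbors), and every matched functional/protecting group
overlapping that neighborhood.  Template prioritization is multi-class
classification: the policy network `f(ECFP4(product)) → p(template)` is
trained with Adam (lr 10⁻³, categorical cross-entropy, L2 10⁻³, dropout
0.04, plateau decay ×0.5 after 5 stale epochs, early stopping after 10) on
a seeded 90/5/5 split.

The search maintains states of unmade molecules.  Selection descends by

    UCB(a) = Q(a)/N(a) + C · sqrt(ln N_parent / N(a)),    C = 1.4

with Q initialized at 0.5 and N at 1 per action; expansion keeps the top
50 templates per molecule or until their cumulative probability reaches
0.995; an action whose template yields no outcome gets Q = −10⁶ and is
never revisited; rollout picks random live actions to a terminal state,
whose reward (increasing in the in-stock fraction, decreasing in route
depth) is backpropagated (Q += r, N += 1).

## Worked example

Generate a toy reaction world and run the entire pipeline:

```
$ retrotree make-fixtures --out world --n-reactions 120 --n-families 6 \
      --max-depth 2 --n-targets 4 --seed 7
wrote 120 reactions, 142 stock compounds, 4 targets to world

$ retrotree extract --reactions world/reactions.smi --out library.tsv --groups none
{
  "n_records": 120,
  "n_curated": 120,
  "n_unique": 118,
  "n_templates": 6,
  ...
  "category_counts": { "precise": 104, "selective": 14 }
}
```

118 of 120 records survive curation and deduplication (two route-step
records duplicate corpus reactions), and the six planted template families
come back as exactly six radius-1 templates, 88% of extractions *precise*
(they regenerate only their own source reactants) and the rest
*selective*.

```
$ retrotree train --reactions world/reactions.smi --library library.tsv \
      --out model.npz --history history.csv --groups none --epochs 30 --seed 0
{ "test_top1": 1.0, "test_top5": 1.0, "test_top10": 1.0, "test_top50": 1.0 }

$ retrotree search --model model.npz --library library.tsv \
      --stock world/stock.smi --target world/targets.smi --out routes.json \
      --iterations 200 --seed 1
{ "n_targets": 4, "n_solved": 4 }
```

On this deliberately separable world the policy reaches perfect test
accuracy and the search recovers a route for every planted target.  The
first entry of `routes.json` solves in a single iteration:

```
CCCCSCc1ccccc1  <-  ['CCCCBr', 'SCc1ccccc1']      (thioether disconnection)
```

both precursors being stock compounds.  `retrotree assess` reports the
top-N applicability of a trained model on any compound list.

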