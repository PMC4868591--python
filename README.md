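# cladesort

Screen directories of phylogenetic trees for strongly supported clades
uniting user-defined target taxa. Trees are treated as unrooted: both
leaf-set sides of every internal edge are assessed as candidate clades,
sharing that edge's support value. Each candidate is classified as

- **Exclusive** — contains only target leaves (and at least two of them),
- **Non-Exclusive** — contains a small, bounded fraction of interrupting
  non-target leaves (within-clade target proportion at or above
  `clade_exclusivity`, but below 1),

subject to a minimum support threshold and to `min_prop_target`, the
minimum fraction of *all* target leaves in the tree that the clade must
hold. Trees whose every leaf is a target are additionally labeled
**All Exclusive**. Target terms are matched against tip labels by
exact, case-sensitive substring search.

Both standard Newick (`(A:1,B:1)99:0.5`) and the extended-Newick
support placement (`(A:1,B:1):0.5[99]`) are read; a standalone
converter rewrites the latter into the former. A seeded benchmark
simulator generates tree sets with a known embedded Exclusive clade
(or negative controls without one).

## Command-line usage

```sh
# classify every .tre file in a directory (list mode: non-destructive)
cladesort sort --targets "Rhodophyta,Viridiplantae,Stramenopiles" \
    --in-dir trees/ --min-support 90 --min-prop-target 1.0 --clades E

# move hits into trees/Sorted_Trees/{Exclusive[,All_Exclusive],Non_Exclusive}/
cladesort sort --targets "Rhodophyta" --in-dir trees/ --mode m

# convert an eNewick file to standard Newick
cladesort convert --in tree.etre --out tree.tre

# generate a benchmark set: 1000 eNewick trees of 100 tips + manifest.tsv
cladesort simulate --x 100 --n 1000 --seed 1 --out-dir sim/
```

Defaults: `--min-support 0`, `--min-prop-target 0.7`,
`--clade-exclusivity 0.9`, `--clades E,NE`, `--extension .tre`,
`--out-dir Sorted_Trees`, `--mode l`. `--targets` is the only required
sorting option; `--clade-exclusivity 1.0` is rejected (a fully-target
clade is Exclusive, not Non-Exclusive). Every run writes a tab-separated
log (`<out-dir>.log` in the input directory) with one row per qualifying
clade: support, target / non-target tallies, proportions, and leaf names.

## Library

```python
from cladesort import (
    parse_tree, classify_tree, sort_trees,
    TargetSpec, SortCriteria, SortJob,
)

tree = parse_tree("((A_Rhodophyta:1,B_Rhodophyta:1)99:0.5,(C:1,D:1):0.5);")
result = classify_tree(tree, TargetSpec.from_string("Rhodophyta"),
                       SortCriteria(min_support=90))
result.labels                 # frozenset({'EXCLUSIVE'})
```

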