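# aftree

Alignment-free phylogenetic inference and phylogeny-aware community
statistics for 16S-like marker genes.

The toolkit covers a complete pipeline:

* **Alignment-free distances** (`aftree.afdist`) — three methods over a
  shared exact-substring engine (a suffix automaton):
  * `acs`: average-common-substring distance from matching statistics,
    symmetrized, with a self-term correction so identical sequences are
    at distance 0. Natural logarithms are used; the self-average has the
    closed form `(n+1)/2`.
  * `kr`: a shortest-unique-substring (shustring) estimator. The mean
    shustring length gives a directed mismatch estimate
    `pi = 1/mean(sl(X,Y)) - 1/mean(sl(X,X))`; the symmetrized estimate is
    capped at 0.74 and passed through the Jukes–Cantor transform
    `-(3/4) ln(1 - 4 pi / 3)`. This is a simplified stand-in for the
    original coalescent-corrected estimator: it keeps the defining
    quantity (average shustring length) and the JC evolution model but
    replaces the original expectation-based inversion with a direct
    mismatch estimate.
  * `cv`: composition vectors of Markov-background-corrected k-word
    frequencies (default `k=6`, configurable 3–9), compared by cosine,
    scaled to `[0, 1]` as `(1 - C)/2`.

  `N` never matches anything: query positions holding `N` have matching
  statistic 0, subject substrings containing `N` are unreachable, and
  k-mer windows containing `N` are skipped.

* **Trees** (`aftree.phylo`) — deterministic neighbor joining (ties in
  the Q criterion broken by smallest label pair), bipartition machinery,
  Robinson–Foulds (raw count and normalized) and branch-score distances.

* **Consensus ensemble** (`aftree.consensus`) — majority-rule consensus
  (extended by default), zero-length resolution of multifurcations,
  FITCH-style non-negative weighted least-squares branch fitting
  (weights `1/d^power`, default power 2), and per-branch averaging of
  the lengths fitted against each method's distance matrix.

* **Taxonomy gold standard** (`aftree.taxonomy`) — a tree generator for
  Greengenes-style rank strings. Empty rank labels create no node;
  identical labels under different parents stay distinct; unary chains
  are collapsed.

* **Community statistics** (`aftree.community`) — weighted UniFrac (raw
  by default, `normalized` optional; unrooted trees are midpoint-rooted
  first), classical PCoA, per-group centering, and PERMANOVA with
  pseudo-F, R², the bias-adjusted effect size ω² (reported raw, may be
  negative), optional strata, and a sequential conditional test
  `B | A` with permutations restricted within the levels of A.
  P-values use the add-one estimator over seeded permutations, so they
  are never zero and are reproducible bit-for-bit.

* **Simulation harnesses** (`aftree.simulate`) — Yule trees with unit
  mean root-to-tip depth, Jukes–Cantor sequence evolution, taxonomy
  derivation by depth cuts, two-group community simulation whose effect
  is injected by permuting a prescribed number of OTU labels, a
  replicated tree-inference evaluation against the taxonomy gold
  standard, and a PERMANOVA power study across effect sizes.

## Command line

All functionality is wired through a single `aftree` entry point:

```sh
aftree dist --method acs --in seqs.fasta --out dist.phylip
aftree nj --in dist.phylip --out tree.nwk
aftree consensus --trees a.nwk --trees k.nwk --trees c.nwk \
                 --dms a.phylip --dms k.phylip --dms c.phylip --out cons.nwk
aftree taxtree --in taxonomy.tsv --out gold.nwk
aftree compare --metric rf tree.nwk gold.nwk
aftree unifrac --tree cons.nwk --table abundance.tsv --out unifrac.phylip
aftree permanova --dm unifrac.phylip --meta meta.tsv --factor antibiotic \
                 --condition-on location --perms 10000 --seed 1
aftree pcoa --dm unifrac.phylip --out coords.tsv
aftree simulate eval --taxa 64 --length 500 --replicates 10 --seed 1 --out report.tsv
aftree simulate power --levels 0,10,25,50,100 --sims 20 --seed 7 --out power.tsv
```

Exit codes: 0 success, 1 data error, 2 usage error. Every stochastic
command takes an explicit seed; reruns with the same inputs and seed
produce byte-identical outputs.

## File formats

FASTA (DNA; non-ACGT characters map to `N`), Newick (branch lengths,
internal labels, quoted labels, multifurcations), square PHYLIP distance
matrices (tab-separated `relaxed` dialect by default, 10-character
`strict` dialect available), and TSV taxonomy / abundance / metadata
tables.

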