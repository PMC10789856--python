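# wgdtiming

Relative timing of gene duplications from branch-length ratios on
outgroup-rooted phylogenies, with the supporting tooling to run the whole
analysis loop offline:

- **io_formats** — strict FASTA / Newick / neighbourhood-TSV readers and
  writers with located error reporting.
- **distances** — pairwise evolutionary distances with pairwise deletion of
  gapped/ambiguous columns: p-distance, Poisson / gamma / Kimura-protein /
  JC69 / K2P corrections, and a maximum-likelihood distance under an
  empirical reversible matrix (JTT shipped as packaged data, optional
  discrete-gamma rate heterogeneity). Saturated pairs are flagged, never
  clipped.
- **njtree** — deterministic neighbour-joining, column-bootstrap support,
  outgroup rooting, MRCA and path-length queries.
- **timing** — the core statistic: on a rooted tree, locate the
  outgroup-split node *a* and the duplication node *b*, compute the mean
  duplication-to-tip length *bc* and the stem length *ab*, and classify the
  duplication from the bc/ab ratio (≥ 1 ancient, ≤ 0.5 recent by default).
  Multi-case, multi-outgroup reports with a concordance column.
- **synteny** — shared-neighbour counts and Jaccard indices between gene
  neighbourhoods, diagnostic ("witness") neighbours unique to one
  paralogue, and an exhaustive one-to-one orthology assignment with an
  explicit ambiguity flag.
- **simulate** — gene families evolved under a continuous-time Markov
  substitution process through duplication events at known heights, with
  rate multipliers, duplicate loss and ancestral- vs lineage-specific
  resolution presets; exact ground-truth ratios for every inference stage.
- **pipeline / cli** — YAML-configured end-to-end runs with reproducible
  artifacts.

## CLI

```bash
# simulate a family with a known duplication time (truth ratio 1.25)
wgdtiming simulate --preset ancient_2R --seed 7 --length 500 --out fam/

# distances and an NJ tree with bootstrap supports
wgdtiming distances --aln fam/alignment.fasta --model ml_uniform
wgdtiming njtree --aln fam/alignment.fasta --model ml_uniform \
    --bootstrap 500 --seed 17 --out tree.nwk

# the timing statistic (tree mode or alignment mode)
wgdtiming timing --tree tree.nwk --paralog1 p1.txt --paralog2 p2.txt \
    --outgroup og.txt

# synteny comparison of neighbourhood tables
wgdtiming synteny --queries q.tsv --refs r.tsv --window 10

# a configured end-to-end run
wgdtiming report --config run.yaml --set seed=7
```

Tip-list files contain one tip label per line.  Neighbourhood tables are
TSV with header `focal_id  chromosome  symbol  offset` where offsets are
signed gene ranks (… −2, −1, +1, +2 …).

## Notes

- NJ is deterministic: Q-ties are broken by lexicographic cluster keys;
  negative branch estimates are clamped with the deficit moved to the
  sister branch.
- `root_with_outgroup` keeps an input root that already separates the
  outgroup; otherwise it inserts a root mid-branch (50/50) and marks it so
  the timing statistic uses the real divergence node below it, which makes
  bc/ab independent of both outgroup branch length and root placement.
- All randomness (bootstrap, simulation, loss) is driven by explicit seeds
  and reproduces bit-for-bit.
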