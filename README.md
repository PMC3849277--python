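# gofunsim

Gene Ontology functional analysis from information-content measures:

- **Ontology / annotations** — OBO 1.2 parsing restricted to `is_a`/`part_of`
  (`gofunsim.ontology`), GAF 2.x parsing with NOT-qualifier and evidence
  filtering, true-path closures and term usage counts
  (`gofunsim.annotations`).
- **Term IC** — four models: corpus annotation frequencies, Zhang
  descendant-leaf counts, Wang per-anchor semantic values and the
  GO-universal topological position (`gofunsim.ic`), all in natural-log
  units with uniformized (max-normalized) variants.
- **Term similarity** — Resnik, Lin, Relevance, Li, XGraSM (Resnik and Lin
  flavors), Wang, Zhang and GO-universal approaches, every score in [0,1]
  (`gofunsim.termsim`).
- **Protein similarity** — Avg/Max/BMA/ABM combiners, the direct
  set-overlap measures SimGIC/SimDIC/SimUIC/SimUI, and a registry of the
  27 canonical measure configurations (`gofunsim.protsim`).
- **Fuzzy term statistics** — agreement-level fuzzy scores and frequencies,
  binomial gene retrieval and hypergeometric term enrichment with
  Bonferroni correction (`gofunsim.stats`).
- **Clustering** — hierarchical clustering with Newick export and spectral
  k-means on protein similarity matrices (`gofunsim.cluster`).
- **Synthetic data** — a deterministic 6-term/5-protein toy fixture and
  seeded random OBO/GAF generators (`gofunsim.simulate`), so the whole test
  suite runs without downloads.

## CLI

All commands read plain-text inputs (OBO, GAF, one item or pair per line)
and write TSV. Exit codes: 0 success, 2 input limit exceeded, 3 parse
error, 4 lookup error, 5 parameter error. Size limits mirror the original
service defaults (5000 ids for IC, 3000 pairs, 20/2000/200 for
retrieve/enrich/cluster) and can be lifted with `--force`.

```sh
gofunsim fixtures demo/                      # write toy t6.obo + c5.gaf
gofunsim ic terms.txt        --obo go.obo --gaf ann.gaf --model annotation
gofunsim termsim pairs.txt   --obo go.obo --gaf ann.gaf --approach lin
gofunsim protsim ppairs.txt  --obo go.obo --gaf ann.gaf \
    --approach lin --combiner bma
gofunsim retrieve query.txt  --obo go.obo --gaf ann.gaf \
    --approach universal --agreement 0.3
gofunsim enrich target.txt   --obo go.obo --gaf ann.gaf --approach universal
gofunsim cluster prots.txt   --obo go.obo --gaf ann.gaf \
    --approach lin --combiner bma                  # Newick dendrogram
gofunsim cluster prots.txt   --obo go.obo --gaf ann.gaf \
    --approach lin --method kmeans --k 3 --seed 7  # assignments TSV
```

`--agreement` takes a value in (0,1] or a preset name: `moderate` (0.3),
`high` (0.7), `perfect` (1.0).

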