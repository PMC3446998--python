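# prorank

Directional PageRank analysis of signal-directed protein interaction
networks, with the downstream comparison and annotation statistics needed
to characterise the rankings.

A directed interactome (edges kept when their directional score exceeds a
strict threshold, default 2.0) is ranked three ways:

* **forward** — PageRank on the signal-flow direction; high scores mark
  broad information *receivers* ("authorities");
* **reverse** — PageRank on the transposed network; high scores mark broad
  information *emitters* / regulators ("hubs");
* **undirected** — PageRank on the symmetrised network; tracks interaction
  count (at damping 1 it equals degree / 2·|edges| exactly).

On top of the rankings the package provides: Pearson/Spearman correlations
between rankings (on scores or positions), top/middle/bottom group
extraction, top-k overlaps and common sets, top-vs-bottom fold ratios,
one-way ANOVA with Duncan's multiple-range compact letter display,
subcellular-location cross-tabs with a reference-ratio chi-square, a
BLAST-tabular best-hit reader, and a synthetic-network generator that
plants few key emitters, relatively even receivers and a conservation
gradient — so the whole pipeline is testable without any external data.

Two Monte-Carlo oracles back the analytic code: a random surfer whose
visit frequencies converge to the stationary scores, and a return-time
simulator verifying Kac's identity (score = 1 / expected return time).

## CLI

```sh
# reproducible synthetic fixture: edges.tsv + annotations.tsv + roles.tsv
prorank simulate --n-nodes 500 --emitters 5 --seed 1 -o fixture/

# rank all three directions (alpha 0.85, dangling policy "stay")
prorank rank fixture/edges.tsv -d all -o ranks/

# pairwise correlations, overlap@k, fold ratios, common top-k
prorank compare ranks/ranking_*.tsv --k 50 -o comparison.tsv

# conservation / category / location summaries for one ranking
prorank summarize ranks/ranking_reverse.tsv fixture/annotations.tsv \
    --k 50 --reference-ranking ranks/ranking_forward.tsv -o summary/
```

All outputs are TSV with `# key=value` provenance headers. Exit codes:
0 ok, 2 input error, 3 convergence failure.

Dangling nodes (no outgoing links) default to the `stay` policy (the walker
stays put); `--dangling teleport` selects the uniform-jump convention used
by many standard implementations. Results are policy-dependent and the
policy used is recorded in every output header.

## Layout

```
src/prorank/
  network_io.py        edge-table / ranking-table I/O, InteractionNetwork
  pagerank.py          transition matrices, power iteration, MC oracles
  ranking_analysis.py  groups, correlations, overlaps, fold ratios
  annotation_stats.py  BLAST reader, ANOVA, Duncan MRT, cross-tabs, chi-square
  synthetic.py         planted-structure network & annotation generator
  cli.py               simulate / rank / compare / summarize
tests/                 unit + property + acceptance suites
scripts/acceptance.py  acceptance report runner
```
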