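# level2ppi

Disease-candidate gene prioritization from **level-2 protein–protein
interactions** — the common interacting partners that a gene's protein
shares with the proteins of known disease genes.

Classical guilt-by-association screens over a PPI network only consider
*level-1* neighbors: genes whose proteins directly bind a known disease
protein. That misses genes with no direct link that nonetheless share many
interaction partners with the disease set — a strong signal of functional
association (the motivating case is the kinase PRKCD in abdominal aortic
aneurysm, which touches no known disease gene directly but reaches many of
them through hubs such as MAPK1 and SHC1). `level2ppi` scores every gene in
an undirected PPI network against a seed set *S* of known disease genes by
two integer counts:

* **direct (level-1) score** of gene *g*: |N(g) ∩ S \ {g}| — the number
  of seed genes it directly interacts with;
* **indirect (level-2) score** of *g*: Σ_{s ∈ S\{g}} |N(g) ∩ N(s) \ {g, s}|
  — the number of length-2 paths *g–x–s* to seed genes through common
  interactors *x*.

Non-seed genes are ranked by indirect score; candidates with indirect score
\> 50 (level-2) or direct score > 4 (level-1) are flagged as *prior
candidates*. The package also provides:

* leave-*k*-out **cross-validation**: repeatedly delete *k* seeds, rescore,
  and compare the held-out genes' mean score to the candidate background's
  (a ratio > 1 means the network re-discovers hidden disease genes), with a
  paired *t*-test of level-2 vs level-1 performance;
* **coincidence-ratio profiles** of ranked candidates against an external
  reference list (e.g. differential-expression hits) in rank bins;
* **hypergeometric gene-set enrichment** (GMT input, optional
  Benjamini–Hochberg) and the intersection of sets enriched in both
  candidates and seeds (functional coherence);
* a **synthetic planted-module generator** producing networks, seed lists,
  reference lists and GMT files with known ground truth, in exactly the
  file dialects the readers accept (generic 2-column TSV and the HPRD
  binary-interaction flat file).

## Worked example

Seed gene A binds B, C and D directly. Gene F never touches A but shares
all three partners; E shares one. Running
`python examples/score_worked_example.py`:

```
gene    direct  indirect  membership
F            0         3  level-2 only
E            0         1  level-2 only
B            1         0  level-1
C            1         0  level-1
D            1         0  level-1
```

F tops the ranking with indirect score 3 — three common interactors with
the seed — although a level-1 screen would never surface it.

On a synthetic network with a planted module (20 seeds and 30 true
candidates sharing 15 hubs over a 500-gene random background),
`python examples/cross_validation.py` prints:

```
replicates           : 100 (k=5 deleted each)
mean ratio, level-1  : 2.92
mean ratio, level-2  : 10.73
paired t-test        : t=71.8, p=3.43e-87
```

Held-out seeds score ~11× the candidate background by indirect
interactions versus ~3× by direct ones: the level-2 network is the better
recovery instrument on this structure. The other examples demonstrate
enrichment coherence, coincidence profiles, and fixture generation.

## Command line

The same workflow is exposed as a thin CLI:

```sh
level2ppi simulate --out-dir fixture --rng-seed 7
level2ppi score    fixture/edges.tsv fixture/seeds.txt --out-dir results
level2ppi validate fixture/edges.tsv fixture/seeds.txt --rng-seed 7 --out-dir results
level2ppi overlap  results/candidates.tsv fixture/reference.txt --out overlap.tsv
level2ppi enrich   fixture/seeds.txt fixture/genesets.gmt background.txt --out enr.tsv
# background.txt: one gene symbol per line, e.g. all genes of the network
```

All randomized commands take `--rng-seed` (or log an auto-chosen one);
tables go to files, logs to stderr.

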