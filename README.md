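# snpanel

Minimal SNP panels for crop variety fingerprinting, and identity-score
screening of essentially derived varieties (EDVs).

Large genotype resources routinely type hundreds of thousands of SNPs per
variety, but routine variety identification — seed certification, plant
variety protection, EDV disputes — needs a panel small enough to assay
cheaply while still (a) giving every registered variety a unique genotype
signature and (b) discriminating essentially derived varieties from merely
related ones. `snpanel` implements a randomized greedy procedure,
**Conditional Random Selection (CRS)**, that reduces a genotype matrix of
inbred varieties to a few irreducible "simplified SNP combinations", and the
**identity score (IS)** machinery used to calibrate the reduced panel's EDV
threshold against the full marker set.

## The statistics

For diploid genotypes coded 0 (hom-ref), 1 (het), 2 (hom-alt), the allele
distance to the reference is `Ds ∈ {0, 0.5, 1}` and the identity score of
two varieties over `N` jointly called SNPs is

    IS = Σᵢ (1 − |Ds₁ᵢ − Ds₂ᵢ|) / N

computed per 20-kb window or pooled genome-wide (the default; on complete
data pooling makes IS independent of the window size). Two varieties with
genome-wide IS ≥ 0.975 are treated as EDVs of each other; EDV groups are
connected components of the thresholded IS graph and one random
representative per group is retained.

Per-marker polymorphism is summarised as PIC = 1 − Σ fᵢ² over genotype-class
frequencies, and minor allele frequency in the usual way.

**CRS** then works in two stages on the distinct (representative) varieties:

1. *Screening* — repeatedly draw random triples of unselected markers, keep
   the triple that gives the most varieties a *specific haplotype* (a
   genotype vector unique to one variety), until all varieties are resolved;
2. *Pruning* — shield one marker at a time in random order and drop it if
   the remainder still distinguishes every variety, iterating to a fixed
   point, so the returned set is irreducible.

Disjoint repetitions yield several simplified sets; unions of 1–4 of them
are swept over IS thresholds (95.5%–99.5%) against full-panel EDV truth, and
the best F1 cell (ties → smaller panel, lower threshold) selects the
operational panel. Baselines: uniform random selection (RS) and random
selection among markers with PIC > 0.4 (HPS).

## Worked example

Simulate a 40-founder panel (families of related lines, 8 derived lines at
mutation fraction 0.01), select disjoint CRS sets, and sweep thresholds:

```
$ snpanel simulate --n-founders 40 --n-snps 2000 --n-derived 8 \
    --family-size 4 --seed 1 --out-dir demo/sim
wrote 48 varieties x 2000 markers to demo/sim

$ snpanel crs-select --matrix demo/sim/matrix.tsv --markers demo/sim/markers.tsv \
    --runs 3 --seed 1 --out-dir demo/sel
selected 3 sets of sizes [20, 22, 20]

$ snpanel evaluate --matrix demo/sim/matrix.tsv --markers demo/sim/markers.tsv \
    --runs 3 --seed 1 --sweep 0.955:0.995:0.01 --out-dir demo/eval
best union 0+1+2 (53 markers) at IS >= 0.955: F1=0.968 PR=0.938 RC=1.000
```

So 53 of 2,000 markers (the union of three irreducible sets of 16/16/21
markers found on the 45 distinct varieties) recover the full-panel EDV/non-EDV
labels with F1 = 0.97; `demo/eval/grid.tsv` holds the whole
composition × threshold grid and `demo/eval/best.json` the winning cell.
`evaluate` reports smaller per-run sizes than `crs-select` because it first
collapses EDV groups to one representative each.

The same machinery is available as a library, including scikit-learn
estimators that compose with pipelines and model selection:

```python
from snpanel import CRSSelector, EDVClassifier, simulate_panel, SimulationConfig

panel, truth = simulate_panel(SimulationConfig(seed=1))
sel = CRSSelector(n_runs=3, random_state=0).fit(panel.codes)
reduced = sel.transform(panel.codes)          # varieties x union-of-sets
clf = EDVClassifier(threshold=0.985).fit(reduced)
labels = clf.predict(reduced)                 # EDV call per variety
```

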