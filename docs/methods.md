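# Methods

## Scope and model

`snpanel` operates on panels of predominantly inbred, bi-allelic-SNP-typed
varieties, coded per cell as 0/1/2 (reference-allele dosage classes) with −1
for missing. Three pieces of machinery interlock:

1. **Identity score (IS).** For two varieties, each jointly called SNP
   contributes `1 − |Ds₁ − Ds₂|`, with allele distance `Ds = code / 2 ∈
   {0, 0.5, 1}`. Windows tile each chromosome half-open from bp 1 in 20-kb
   steps. Genome-wide aggregation is *pooled* by default: total score over
   total jointly called SNPs, i.e. the SNP-count-weighted mean of window
   scores. The unweighted mean of per-window scores (`window_mean`) is
   available; the two coincide only when every window holds equally many
   jointly called SNPs. Pooled IS on complete data is exactly
   `1 − (score-weighted differing fraction)` and therefore independent of
   the window size — a property the tests exploit as a closed form.
2. **EDV calling.** Varieties with genome-wide IS at or above a threshold
   (default 0.975, inclusive — a tie is a call) are essentially derived;
   groups are connected components of the thresholded IS graph (the minimal
   transitive closure consistent with group retention), and one
   seeded-random representative per component is retained for
   distinct-variety analysis. Missing genotypes are handled by pairwise
   per-SNP deletion.
3. **CRS selection.** On the representatives, stage 1 repeatedly scores
   `trials_per_round` random `k`-subsets of the unselected candidates by
   the number of varieties *newly* given a specific (unique) haplotype and
   appends the best (ties go to the earliest draw, so output is a pure
   function of the seed); stage 2 shields markers one at a time in seeded
   random order, dropping redundant ones, iterating whole passes to a fixed
   point. The output therefore always distinguishes all varieties and is
   irreducible: removing any single marker merges at least one pair.
   Selection demands complete genotypes — a wildcard reading of missing
   calls would silently alter the distinguishability relation.

Reduced panels are evaluated at the variety level: ground truth is EDV
membership under the full marker set at the reference threshold; a
candidate (union, threshold) cell predicts a variety EDV iff its best
union-restricted IS against any other variety reaches the threshold.
Undefined metrics (empty denominators) propagate as NaN and are excluded
from, never coerced into, the best-cell search; ties on F1 prefer the
smaller union, then the lower threshold.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `window_bp` | 20,000 | window width in bp for per-window IS |
| `threshold` | 0.975 | genome-wide IS for an EDV call, inclusive |
| `k_per_round` | 3 | markers per stage-1 draw; small draws keep rounds informative |
| `trials_per_round` | 10 | draws scored per round; more trials → slightly smaller sets, linear cost |
| `n_runs` | 5 | disjoint simplified sets; unions of 1–4 are evaluated |
| `pic_min` | 0.4 | HPS baseline eligibility, strict inequality |
| sweep grid | 0.955–0.995 step 0.01 | thresholds tested for reduced panels |
| `max_missing` / `min_maf` | 0.2 / 0.01 | marker QC before any analysis |

PIC is computed over genotype classes, `1 − Σ fᵢ²` (maximum 2/3 for three
classes), missing cells excluded from every denominator.

## The synthetic generator

`simulate_panel` emulates the structure of a real fingerprinting panel at
desk scale: 12 chromosomes, positions uniform then sorted, per-site alt
frequency uniform in [0.05, 0.5], fully homozygous genotypes by default
(`het_rate` adds hets), and derived lines built by copying a parent and
flipping a random fraction `q` (default 0.01) of sites to the *opposite*
homozygote, so each mutation costs exactly one unit of identity and pooled
parent–child IS equals `1 − realized_mutated_fraction` bit-exactly.

Founders are drawn in **families** (default size 4): members of a family
share an ancestral genotype and each diverges from it by a uniform-random
fraction of opposite-homozygote flips, giving a within-family pairwise IS
continuum of roughly 0.90–0.97. This is deliberate: actual breeding panels
are dense with related-but-distinct varieties just below the EDV threshold,
and both the size of CRS sets (tens of markers rather than the ~⌈log₃ n⌉
floor) and the behaviour of reduced panels near the threshold depend
entirely on that relatedness. Construction enforces the margins that make
ground truth exact: every within-family pair is padded to differ at ≥ 2.8%
of sites (IS ≤ 0.972 < 0.975) and every derived line is resampled until its
realized mutated fraction is < 2.5% (IS > 0.975), so full-panel EDV calling
recovers the generative labels deterministically. `family_size=1` disables
relatedness (background IS ≈ 0.6) and is used wherever a clean closed form
is wanted.

What the generator does **not** emulate: linkage disequilibrium and
recombination (sites are independent), genotyping error, imputation
artifacts, population structure beyond the two-level family hierarchy, and
non-uniform marker density. Passing tests therefore demonstrate algorithmic
correctness and the qualitative economics of panel reduction, not
performance on any particular crop resource.

The EDV-polymorphic candidate pre-filter (restricting CRS candidates to
markers segregating inside some EDV group) is implemented and tested but
off by default in the simulation study: under the private-mutation
derivation model those markers are exactly the parent–child mutations, so
the filter would concentrate the panel on them and systematically drag
derived-pair similarity down — an artefact of the synthetic derivation
model, not a property of real coding-SNP panels.

## A structural property of disjoint-union panels

Because every one of the `c` disjoint CRS sets independently distinguishes
all representatives, any two distinct varieties differ at ≥ `c` markers of a
`c`-set union of size `m`, capping their union-restricted IS at about
`1 − c/m = 1 − 1/m_set`. With ~100 varieties the irreducible sets run to
~28 markers, the cap sits near 0.964, and false EDV calls at thresholds ≥
0.975 are *impossible*: precision is identically 1 there, recall is
non-increasing in the threshold, and the F1 optimum can never move above
the reference threshold. Reduced panels only need a *stricter* threshold
than the full set once per-set sizes exceed `1/(1 − threshold)` (≈ 67
markers at 0.985) — the regime of thousands-of-varieties panels with
100+-marker sets, not of desk-scale simulations. The acceptance suite
states the raised-threshold expectation for the 100-founder study anyway
and the corresponding test documents this bound by failing.

## Numerical and design choices

* Marker order is always (chromosome lex, position, id); coordinates are
  1-based inclusive (BED converted on read); multi-allelic VCF records are
  skipped, not split.
* The pairwise IS matrix is computed with one-hot indicator matrix products
  (float32 accumulators; counts are exact integers well inside float32
  range), which handles missing calls pairwise and keeps the all-pairs cost
  at a few GEMMs; scalar `genome_is` uses float64 and is the reference in
  tests (agreement demanded to 1e-6, float32 round-off).
* All randomness flows from integer seeds through `numpy` `SeedSequence`
  derivations with fixed stage keys, so stages re-run independently give
  identical draws; every CLI run echoes its resolved configuration to a
  manifest and repeated seeded runs are byte-identical.
* Degenerate inputs: all-missing columns give NaN statistics in tables and
  raise in scalar form; an all-markers-removed filter warns rather than
  errors; a panel with duplicate varieties fails selection with the
  offending group named.
* Study sizes in the test suite (100 founders + 20 derived, 10,000 SNPs,
  20 replicates; 200 random panels for the postcondition sweep) were chosen
  so margins hold with large slack while each suite stage completes in
  seconds on one core.

## Limitations

* CRS is a randomized greedy heuristic: outputs are irreducible but not
  minimum; the exhaustive oracle is exponential and only used at ≤ ~20
  candidates.
* `window_mean` aggregation across two different panels is unsupported
  (cross-panel labelling is pooled only).
* The EDV graph's connected components can chain varieties whose direct IS
  is below threshold; that is the intended retention semantics but can
  surprise on dense near-threshold panels.
* No genotyping-error or missing-data model in selection: the
  distinguishability relation treats every called genotype as exact.
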