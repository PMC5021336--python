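# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `methylite`. All coordinates are 1-based
inclusive internally and in cytosine reports and GFF3; BED output is
0-based half-open.

## Generative model of the synthetic data

The generator emulates a plant WGBS experiment at the level of
per-cytosine read counts; it does not simulate reads, alignment, or
sequencing error beyond bisulfite conversion failure.

* **Reference.** Chromosomes are i.i.d. base draws at a configurable GC
  content (default 0.36, Arabidopsis-like). Every C on the plus strand
  and every G on the minus strand (a C read 5'→3' on that strand) enters
  the cytosine inventory with a CG/CHG/CHH context from the local
  trinucleotide; within two bases of a chromosome end the missing bases
  are treated as H and the trinucleotide is N-padded.
* **Truth methylome.** Each cytosine has a true methylation probability
  *m*: the per-context baseline (defaults CG 0.28, CHG 0.10, CHH 0.03, an
  Arabidopsis wild-type-shoot-like profile) outside planted regions, and
  the planted rates (defaults 0.1 vs 0.8) for target-context cytosines
  inside. Planted regions are disjoint, of fixed length, and must contain
  at least `min_sites` target-context cytosines; placement is rejection
  sampling with a deterministic seed, erroring out if the constraint
  cannot be met.
* **Counts.** Depth per site is Poisson(`depth`), default 30 (a typical
  modern WGBS depth; the mean depth such studies report is of the same
  order). A read is called methylated with probability *m* + (1 − *m*)·*f*
  where *f* is the conversion-failure rate (default 0.005). Sites,
  strands and samples are independent; no CG strand symmetry is imposed,
  matching the strand-separate reporting of the CX dialect.
  Over-conversion of methylated cytosines is not modelled, since the QC
  the pipeline performs only measures under-conversion.
* **Chloroplast.** An organellar chromosome (named `ChrC`) is generated
  with *m* = 0 everywhere, so its methylated calls are pure conversion
  failures and the estimated conversion rate converges to 100·(1 − *f*).
* **F2 pools.** A single-chromosome genetic map (default 100 cM, 100
  markers, causal locus at 40 cM) is traversed gamete by gamete under the
  Haldane model: the recombination fraction between loci *d* cM apart is
  r = (1 − e^(−2d/100))/2, with no interference. An F2 individual is two
  independent gametes. The "high" pool takes individuals homozygous for
  the mutant allele at the causal locus (recessive phenotype); the
  "normal" pool is drawn from the phenotypically normal classes, which
  are homozygous wild type and heterozygous in the 1:2 Mendelian ratio.
  The composition of the normal pool is a modelling choice — a study
  could also have selected low-phenotype individuals only — and the 1:2
  model gives the textbook expectation Δ = 2/3 at the causal locus.
  Allele counts tally 2 × pool-size chromosomes per marker; pool sizes
  default to 40 individuals each. The original array-based experiment
  measured pooled hybridisation intensities; the idealised count model
  here has strictly smaller measurement error.

What passing tests on this generator do **not** show: robustness to
non-uniform coverage (PCR duplicates, mappability), to context
misannotation near structural variation, to partial methylation of
organellar DNA contaminating the QC, or to segregation distortion in real
crosses.

## Quantification conventions

* Site-level methylation is defined only at ≥4× coverage. Context
  summaries are **weighted** levels (pooled methylated reads over pooled
  total reads), not means of per-site levels: the weighted form is robust
  when many sites sit near the coverage floor. The two differ whenever
  coverage and methylation are correlated.
* Density profiles sum site-level methylation of qualifying sites per bin
  (default 100 kb) and normalise each context to its maximum bin (100%).
  Summed site-level mass is used rather than a count of "methylated
  sites", which would require inventing a binary call threshold; at
  constant depth the two are monotone-related. An all-zero context stays
  at zero rather than dividing by zero.
* The conversion-rate estimate uses **all** covered organellar cytosines
  with no 4× floor: the coverage rule exists to stabilise per-site
  levels, while the conversion rate is a single pooled ratio whose
  precision comes from the total call count.

## The DMR caller

* Windows hold exactly five consecutive same-context cytosines in
  chromosome order — consecutive in the *union* reference inventory of
  the two samples (uncovered sites are allowed as non-qualifying
  members), so window coordinates are sample-independent.
* "Coverage" of a window is the fraction of its five sites with ≥4×
  coverage in **both** samples; the pass criterion is strict (> 0.6,
  i.e. at least 4 of 5). The pooled 2×2 table sums only qualifying
  members, in both samples symmetrically.
* The two-sided Fisher p sums hypergeometric probabilities of all tables
  no more likely than the observed one, with the standard 1 + 1e−7
  relative tolerance on probability comparisons. It is computed
  vectorised over all windows via log-gamma binomials; tests pin it to an
  exact-rational enumeration oracle (≤ 1e−9 on all tables with total
  ≤ 30) and to `scipy.stats.fisher_exact`. Degenerate margins give p = 1.
* BH adjustment (delegated to `statsmodels.multipletests`) is applied
  within one (comparison × context) family containing every window that
  meets the covered-fraction criterion; windows failing it are never
  tested, keeping the family honest. The pass threshold is
  adjusted p ≤ 0.05 (inclusive).
* Fold change is max/min of the pooled window levels with no
  pseudocounts; 0 vs positive gives +∞ (which passes > 2), 0 vs 0 or an
  uncovered sample fails the window. Pseudocounts would silently change
  the meaning of the printed "> 2" criterion.
* Merging is transitive over genomically overlapping passing windows of
  the **same** direction; a mixed-direction region would have no
  assignable direction for gene-level classification. DMR bounds are the
  outermost member-cytosine positions; pooled DMR levels are recomputed
  over the union of member sites (not by double-counting shared sites
  across windows). Regions under 200 bp are dropped, with counts logged.
  Should opposite-direction candidates ever overlap (not observed under
  any tested condition), the smaller best-adjusted-p candidate survives,
  keeping same-context DMRs non-overlapping.

## DMG annotation

1 bp of DMR–region intersection suffices. Flanks are 2,000 bp,
strand-aware, clipped at chromosome ends rather than discarded.
Transposable elements participate in feature-level methylation summaries
but not in DMG calling. Direction exclusivity (each DMG hyper or hypo,
never both) is resolved DMR-wise by the best adjusted p, with ties broken
by larger span and then hyper; a gene-level pooled test would be an
alternative design. The body/upstream/downstream partition is the 7-way
Venn decomposition and always sums to the DMG count.

## BSA scan

Δ = f_high − f_normal per marker; markers with an empty pool are flagged
undefined and break smoothing runs. Smoothing is a centered moving
average over k markers (default k = 5, odd required), shrinking at
chromosome ends; the interval threshold defaults to Δ ≥ 0.4, roughly the
midpoint between the causal expectation (2/3) and the null. Both are
configurable; no confidence intervals are attached beyond the binomial
SE flags the tests use.

## Benchmark problem sizes

The test and acceptance benchmarks use: 200 kb genomes for null
false-positive checks (≈ 70k cytosines, ≈ 65k windows over three
contexts) at depth 30 over 3 seeds; 300 kb genomes with six planted 2 kb
CG regions for recovery; 20 kb chloroplasts (≈ 2×10⁵ calls) for
conversion QC; 800 kb for the ≥ 5×10⁴-CG-site summary check; and 20
seeds of 101-marker pools for BSA. Planted recovery regions are 2 kb
because the caller's boundary resolution is inherently about one window
(± a few cytosines, ~70 bp at Arabidopsis-like CG density): a passing
boundary window needs only ~2 of 5 planted members, so emitted DMRs
overhang truth edges by that much regardless of region size. At 2 kb —
the upper end of realistic plant CG DMRs — base-pair precision measures
recovery fidelity rather than the overhang.

## Known limitations

* No replicate-aware testing; one sample per condition, as in the
  underlying window/Fisher design.
* Window membership follows the reference inventory, not covered sites;
  sparse coverage can therefore dilute windows below the covered-fraction
  cut-off rather than stretching them.
* The BH family is per context and comparison; other family scopes
  (genome-wide across contexts) are defensible and not implemented.
* BSA models allele counts directly; array-intensity noise of
  hybridisation-based genotyping is out of scope.
* The CLI's `all` pipeline is single-threaded and intended for synthetic
  or small real inputs; the library functions accept arbitrary-size
  tables but hold them in memory.
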