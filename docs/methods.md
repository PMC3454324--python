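# Methods

This note records the model, the defaults, and the design decisions made
where the procedure admitted more than one reasonable reading. It is the
companion to the API documentation; nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## PWM model and scoring

Counts are converted to probabilities with a background-distributed
pseudocount, p(b,i) = (f(b,i) + c·p(b)) / (Nᵢ + c). The pseudocount
weight defaults to c = √Nᵢ per column — the standard TRANSFAC/MATCH
choice — and is configurable (including c = 0, in which case zero-count
bases carry −∞ log-odds weights; windows containing such a base simply
score 0 after normalization). Column totals Nᵢ are taken per column, not
globally, because JASPAR matrices are occasionally ragged.

Information content is the per-position relative entropy against the
background (Stormo), which reduces to 2 + Σ p·log₂p for a uniform
background. The IC mask used by the conservation filter marks positions
with Dᵢ ≥ 0.60·D_max, where D_max = −log₂(min_b p(b)) is the maximal
relative entropy attainable under the background (2 bits when uniform).
Defining the cutoff as a fraction of the attainable maximum keeps the
mask meaningful for skewed backgrounds.

Window scores are Σᵢ Dᵢ·W(bᵢ,i), min-max normalized by the best and
worst attainable windows. Degenerate matrices whose score range is zero
(every window equally good) normalize to 1 by convention, so the
detection contract of minFN calibration ("all samples detected") holds
trivially. Windows containing N are flagged unscannable and score 0
rather than being skipped, keeping per-region window counts exact.

## Threshold calibration

* **minFN**: 10,000 sequences are sampled position-wise from the
  *corrected* probabilities (not raw frequencies — the scored model and
  the sampling model should agree; the difference vanishes for
  well-populated matrices). The threshold is the interpolated
  (1 − 0.90)-quantile of their normalized scores, so the detection rate
  is 90% up to a 1/n tie correction.
* **minFP**: the smallest normalized score at which scanning the corpus
  leaves at most one hit per 10,000 bp. The default corpus is i.i.d.
  DNA at 52% GC (coding-like), 100 kb unless supplied; any FASTA corpus
  can be passed instead. Calibration counts hits under the same strand
  policy later used for scanning. For short or low-content matrices no
  threshold may reach the rate (a specific 6-mer already occurs more
  than once per 10 kb by chance); the calibrator then returns 1.0 with a
  warning.
* **minSum**: 100 evenly spaced candidates between minFN and minFP;
  FN(t) is the sampled false-negative fraction, FP(t) the corpus hit
  rate normalized by the rate at minFN and clipped to [0, 1] (false
  positive *rates per bp* and false-negative *fractions* are not
  natively commensurable; normalizing by the low-stringency rate is the
  package's choice and is exposed as an option). Ties resolve to the
  lowest threshold.

Ordering: for near-deterministic matrices the raw minFP (a background
tail quantile) can fall *below* minFN (a motif-sample quantile). Nested
stringencies are a structural requirement — hit sets must satisfy
hits(minFP) ⊆ hits(minSum) ⊆ hits(minFN) — so the combined calibrator
clamps minFP to at least minFN; the raw value is preserved in the
calibration metadata.

## Conservation filter

A hit is conserved when at least `min_species` = 4 species (counting the
reference) carry the reference base at every IC-masked motif position,
and all `required_species` (default: reference and mouse) are among
them. Gaps and unknown bases are mismatches. The species threshold
counts the reference because the underlying phrase "conservation in
four mammalian species, including mouse" is ambiguous on that point;
both knobs are parameters. Minus-strand hits are tested on the same
alignment columns with the mask reversed — base identity is
strand-symmetric. RCGTG consensus scanning defaults to both strands
(HREs are orientation-independent); PWM scanning defaults to the
reference strand only, matching the calibration default. Coordinates
are 0-based half-open throughout; BED on disk.

## Region sets

Core regions start from RCGTG instances that lie wholly inside a
conserved element and pass the conservation filter, are kept when the
associated gene passes the FDR-0.02 combined induction gate, and are
extended symmetrically in 10 bp steps while conserved elements cover
more than 50% of the whole candidate span (stop at 2 kb). The growth
step, symmetry and cap are the package's choices — a bare ">50%
coverage" rule does not pick a unique maximal interval. Note a
consequence of the whole-span rule: an HBS centered in an isolated
element grows to just under twice the element's length before coverage
drops to one half.

Background candidates are regions around conserved RCGTG motifs in
genes whose every probe stays within 0.25 SD of the per-dataset global
mean fold value in *every* dataset (the global mean/SD are computed per
dataset over all probes; the veto applies if any single dataset shows
movement). Candidates sharing a gene with the core set are excluded,
then sampled **without replacement** per location class (promoter /
5'UTR / intron / 3'UTR) to match the core set's class proportions.
Base-composition matching is reported (GC summaries per class in the
matching report) rather than enforced; the location-annotation promoter
window is 2 kb upstream of the TSS, strand-aware, with precedence
promoter > 5'UTR > intron > 3'UTR and a logged nearest-promoter
fallback for regions overlapping no feature.

## Tiling-array analysis

Replicate log-ratios are variance-stabilized with an asinh glog
transform (x → asinh(x/s), s = per-replicate MAD) and median-centered;
quantile normalization and a pass-through are also available. Per-probe
evidence is a one-sample t test against zero with variances shrunk
toward a prior: the prior df d₀ and prior variance s₀² are fitted by
moments on log s² (Fisher-z moments of the scaled-F model, inverted by
Newton on the trigamma function), the posterior variance is
(d₀s₀² + ds²)/(d₀ + d) and p values use d₀ + d degrees of freedom,
BH-adjusted across probes. Smoothing takes the 0.75 quantile (linear
interpolation) of replicate-mean levels within ±100 bp. The null upper
bound reflects the sub-mode half of the smoothed distribution around a
KDE-estimated mode (center of the near-maximal density plateau) and
takes its 0.99 quantile; an empirical-quantile fallback is available.
Enriched regions are runs of above-threshold probes with center spacing
≤ 200 bp, ≥ 4 probes, at least one probe with adjusted p < 0.02, and
≥ 8 probes counting flanking probes within 200 bp of the run ends
(the "total probes" reading of the coverage filter); ranking is best
adjusted p, then maximal smoothed level. Probe position is the interval
midpoint; repetitive-probe exclusion is expressed as an optional
blocklist.

## Expression analysis

Replicate averages are null when at least half the replicates are null.
A probe is induced when its log₂ ratio exceeds the dataset mean by 2.6
SD — mean and SD over probes with non-null ratios — or when it has a
null normoxic but non-null hypoxic signal; basal expression is null when
the averaged normoxic signal is null. Log base 2 throughout. Gene-level
rules: best probe for induction, any probe for basal significance (both
configurable). Cross-dataset combination standardizes each gene's best
log-ratio within its dataset and combines one-sided by Stouffer
(Fisher's method optional), BH-adjusting over genes; this is a
deliberately simple stand-in feeding the same downstream FDR-0.02 gate
as a full effect-size meta-analysis would. The association analyses
compare induction percentages between basal strata with a paired
Wilcoxon signed-rank test across datasets and a pooled 2×2 chi-square
without continuity correction, and tabulate the four-way
HBS × induction classification of basal-expressed genes per dataset.

## Enrichment statistics

Fisher tests are one-sided ("greater"), uncorrected at p < 0.05 — the
analysis looks for over-representation and deliberately reports
uncorrected values, with a BH column alongside for transparency.
Constant presence columns get p = 1 and an undefined odds ratio. CFS
uses symmetrical uncertainty SU = 2I(X;Y)/(H(X)+H(Y)) on binary
variables, merit k·r̄_cf / √(k + k(k−1)·r̄_ff), and a deterministic
best-first search (open list ordered by merit, ties to smaller then
lexicographically smaller subsets, termination after 5 non-improving
expansions — the patience is a parameter). Stratified folds allocate
each class round-robin after a seeded shuffle. One behavioral caveat:
CFS always returns its best non-empty subset, so on data with *no*
informative feature the chance-best feature can be selected in most
folds; selection counts discriminate informative from noise features
only when real signal is present.

## Synthetic data

The generators are pure functions of (config, seed) and emulate the
structure the analysis assumes, at the study's scale (120 core and
3,500 background regions; 80 bp probe spacing with four replicates; a
5% induced fraction across five datasets):

* **Alignments**: 200 bp regions at 45% GC over five species (human,
  chimp, dog, cow, mouse), each with a central conserved RCGTG inside a
  150 bp conserved element; a cooperating 8-mer (TGACGTCA-like, a
  CRE/AP-1-style positive control) planted at rate 0.30 in core and
  0.10 in background regions, instances sampled from the matrix model;
  non-conserved instances get the mouse row scrambled (not deleted, so
  alignment geometry is preserved); other species mutate at a 10%
  substitution rate outside protected positions, a low-end mammalian
  non-coding divergence reflecting that such regions are pre-selected
  for conservation. Decoy PWMs are column-shuffled, base-permuted
  copies with identical information content.
* **Tiling tracks**: probes every 80 bp, baseline N(0, 0.25) per
  replicate, planted bound regions of 5 probes with a +3·SD mean shift.
* **Expression**: log-normal normoxic signals, log-ratio noise
  SD 0.5, induced genes shifted +4 SD (the same genes in all datasets,
  emulating robust induction), 10% of entries nulled at random.

What the generators do **not** emulate: phylogenetic substitution
models or indels, probe-specific affinity and spatial artifacts on
arrays, platform-specific missingness, correlated motif co-occurrence
beyond the single planted factor, and base-composition confounds
between the sets. Passing tests therefore demonstrate correctness of
the algorithms and calibration contracts under the stated statistical
structure — not robustness to every artifact of real data.

## Numerical choices and degenerate inputs

Quantiles use numpy's linear interpolation everywhere. The minFN
threshold uses an interpolated quantile so detection is exact up to
ties. Score normalization guards a zero score range (→ 1.0) and −∞ raw
scores (→ 0.0). BH adjustment delegates to statsmodels. Fisher p values
delegate to scipy's exact routine and are verified in the tests against
a brute-force hypergeometric tail sum. The trigamma inversion in the
variance-prior fit runs Newton from a 1/evar start and falls back to
infinite prior df (complete shrinkage) when the observed log-variance
spread is below its sampling floor. Probes with fewer than two non-null
replicates get p = 1 and a flag; empty strata are excluded from paired
tests with a log message.

## Problem sizes

The test suite and acceptance script run at the scales above: 10,000
calibration samples, a 1 Mbp corpus for the spacing check (100 kb for
batteries), 20 seeds of the full 3,620-region enrichment recovery, and
20,000 genes for the null induction rate. These sizes make every
stochastic contract measurably tight while keeping the default suite in
the low minutes on one CPU.

## Known limitations

The vsn and moderated-t steps of the original tiling analysis are
represented by the glog transform and the moments-fitted shrinkage t
described above — behavioral equivalents, not re-implementations of
those packages. The cross-dataset induction combination is a Stouffer
stand-in, not a published meta-analysis method. Real-genome steps
(phastCons computation, UCSC alignment retrieval, probe remapping) are
out of scope; the package consumes their standard file formats instead.
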