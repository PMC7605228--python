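# Methods

`hexanull` implements the inference chain by which a whole-chromosome
loss (aneuploidy) is detected and dissected in an allohexaploid such as
bread wheat (2n = 6x = 42; subgenomes A, B, D in seven homeologous
groups). Because homeologous chromosomes buffer gene loss, a nullisomic
plant can be viable yet show a distinct phenotype — classically dwarfism
and male sterility — and the causal chromosome can be found without a
mapping population, from three mutually independent signals plus a
candidate-gene screen and transmission genetics. This note documents the
models behind each stage, the defaults, and what the synthetic generator
does and does not emulate.

## Genetic model of the segregating family

A plant monosomic for one chromosome produces chromosome-bearing and
null gametes in equal numbers at meiosis. Transmission, however, is
asymmetric: null gametes compete with normal ones with a null:normal
success ratio `t`, so a transmitted gamete is null with probability
`q = t/(1+t)`. Selfing a monosomic with female ratio `f` and male ratio
`m` yields disomic (T), monosomic (M) and nullisomic (D) progeny with

    P(T) = (1−q_f)(1−q_m),  P(D) = q_f·q_m,  P(M) = 1 − P(T) − P(D).

Defaults are `f = 1` (null egg cells transmit normally) and `m = 0.5`
(null pollen succeeds at half the normal rate), giving P(D) = 1/6.
Both rates are exposed because the observed nullisomic frequency in
real families of this kind is itself ambiguous between a 1:3
fertile:sterile reading and lower counts; the package estimates rates
from data (`estimate_transmission` for the euploid-female × monosomic-
male F1 design, where D offspring cannot occur and M/T estimates `m`
directly; `estimate_transmission_selfed` for a grid-ML fit on T/M/D
counts) and does not adjudicate.

## Synthetic data generator

One `SimulationConfig` seed determines every output; each stage draws
from an independent child of the seed's `SeedSequence`, so regenerating
any one stage reproduces it exactly.

* **Genome.** 21 chromosomes with near-uniform expression weights
  (log-normal jitter, sd 0.05; each chromosome carries ≈ 1/21 ≈ 5% of
  expression). Genes are placed multinomially by weight; within each
  homeologous group a `triad_fraction` (default 0.78, the approximate
  share of triaded genes on a wheat chromosome) of genes are joined
  into A/B/D triads. Focal-chromosome genes without a homeolog group
  are the planted "chromosome-specific" truth. Tissue labels:
  `stamen_specific` (5%), `other_tissue_specific` (10%), else
  constitutive.
* **Expression.** Gene g in sample s has expectation proportional to
  its base mean times a dosage factor `d = c/2 + κ(1 − c/2)` for copy
  number c and compensation κ ∈ [0,1], with `d = 0` forced at c = 0 (a
  lost chromosome is silent regardless of compensation). Expectations
  are renormalized per library to `mean_library_size` (default 10⁶
  fragments), and counts are negative-binomial with one shared
  dispersion (default 0.05). Renormalization leaves per-sample
  *fractions* untouched, so the euploid:monosomic focal read-fraction
  ratio follows the closed form `2 − f` (f = focal euploid share): with
  f ≈ 0.05 the observable dosage ratio is ≈ 1.95, the "about twice"
  signature of monosomy.
* **Bulk SNPs.** 5000 SNPs placed by chromosome weight. Off-focal SNPs
  draw one shared population allele frequency per site from Beta(5,5)
  for both bulks; divergence there is pure binomial sampling noise at
  Poisson(50) depth. Focal SNPs carry the alternative allele on the
  chromosome the sterile bulk has lost: fertile-bulk reads are all
  alternative, sterile-bulk reads all reference — an idealization of
  homeolog-mismapped background coverage that produces the maximal
  frequency divergence the bulked design predicts.
* **Markers.** Band intensity = copy/2 + truncated Gaussian noise (sd
  0.05), i.e. a dominant dosage-sensitive marker normalized so the
  euploid control reads 1. Nine focal markers and three off-focal
  controls by default.
* **Tissue atlas.** One euploid sample per tissue (default 5 tissues
  including stamen). Specific genes concentrate expression in their
  target tissue with a 50-fold on/off contrast.

What the generator does **not** emulate: read-level data (FASTQ,
alignment, SNP calling), recombination, segmental aneuploidy, batch and
GC biases, correlated gene-gene variation, homeolog expression bias, or
mismapping between subgenomes beyond the idealized focal-SNP rule.
Passing tests therefore demonstrate the statistical machinery is
correct under the declared model, not that any preprocessing upstream
of counts/VCFs is handled.

## Bulked-segregant ED scan

At each SNP both bulks are reduced to (A,C,G,T) frequency 4-vectors and
compared by Euclidean distance, `ED ∈ [0, √2]`. Raw per-SNP ED against
a flat threshold (default 0.33) — no powering, no window smoothing —
marks significant SNPs; the chromosome with the largest share of them
is the candidate. A data-driven alternative (`median + 3·SD`) is
provided since a fixed 0.33 has no derivation. Records with < 4 reads
in either bulk are dropped (frequencies from fewer reads are dominated
by sampling noise); indel records are dropped on VCF ingestion with a
logged count; multiallelic SNPs are kept as full 4-vectors.

## Dosage scan and karyotype calls

Per-sample chromosome read fractions (invariant to library size) are
compared with a euploid reference — the mean of declared euploid
samples, else the per-chromosome median across samples (robust to one
aberrant chromosome). The test/reference ratio is thresholded at
`null_max = 0.25` and `mono_max = 0.75`, midpoints with wide margins
around the theoretical states 0, ~0.5 (more precisely 0.5/(1 − f/2))
and 1. A zero reference fraction yields an explicit `undefined`, never
infinity. Replicates are averaged after fraction computation so large
libraries get no extra leverage.

## Marker genotyping

Intensities are thresholded at `absent_max = 0.2` / `half_max = 0.75`
into copy numbers 0/1/2; plants are called T/M/D by majority vote over
focal-chromosome markers, ties resolved toward the **lower** copy
number (conservative toward detecting loss) and logged. Plants with no
usable focal marker are `unknown`, never guessed.

## Expression screen

* **FPKM**: `counts · 10⁹ / (library_size · length)`.
* **Differential expression**: library-size-normalized counts; per-gene
  NB dispersion moment-estimated from within-group variances, clipped
  to [0, 10], and shrunk halfway toward a fitted `a₁/mean + a₀` trend;
  the difference of group log-means with delta-method variance
  `(1/m + α)/n` per group is referred to a t distribution with residual
  degrees of freedom. (A normal reference was measurably
  anticonservative at 3 replicates per group — empirical FDR 3× nominal
  on null simulations — and the t reference restores control, verified
  by the type-I simulation in the test suite.) BH correction across
  tested genes; genes all-zero in both groups are excluded and listed.
  Fold change is computed on group FPKM means with a 1-FPKM pseudocount
  (many true zeros arise on a lost chromosome); a gene is up/down only
  if FDR ≤ 0.01 **and** |FC| ≥ the threshold (defaults FC ≥ 2).
* **Homeolog specificity**: a focal gene is chromosome-specific when
  its homeolog group has no member on another chromosome; genes absent
  from the table are treated as specific with a warning.
* **Tissue specificity**: genes whose FPKM peak is ≥ 3× their
  across-tissue median are standardized (mean 0/SD 1) and clustered by
  in-package Euclidean k-means (k = 8 default; greedy farthest-point
  seeding, 10 restarts, argmin tie-break, monotone objective). The
  variation prefilter is this package's resolution of an operational
  gap: standardizing a flat profile only amplifies replicate noise, and
  without the filter constitutive genes dilute every cluster below any
  mass-share cutoff. A cluster is target-specific when its centroid
  peaks in the target tissue and its members' mean expression-mass
  share there exceeds 0.5.
* **Funnel**: exact set intersection (chromosome-specific ∩
  tissue-specific, optionally ∩ DEG) with per-gene provenance flags.
* **Enrichment**: one-sided hypergeometric upper tail per term over a
  user-supplied gene→term map, BH across terms; terms without universe
  members are skipped.

## Segregation genetics and qPCR

Pearson chi-square GOF (no continuity correction) against any
hypothesized ratio; male transmission from F1 T/M counts as the odds
M/T with an exact binomial CI mapped to the odds scale; expected
progeny classes from the gamete model above. Relative qPCR expression
follows 2^−ΔΔCt with the calibrator's mean ΔCt as baseline, a
two-sample t-test on replicate ΔCt values between samples, and
significance stars at P = 0.01. ΔΔCt is invariant to any constant Ct
shift, which the tests assert.

## Numerical and reproducibility choices

All randomness flows through explicitly passed numpy `Generator`
objects; no global state. Ambiguities resolve deterministically (argmin
tie-breaks, stable sorts, sorted set serialization). Degenerate inputs
raise `ParameterError` with the offending values; zero-depth SNP
records and flat expression profiles are dropped with logged counts
rather than silently imputed. Problem sizes in the test suite (2100
genes, 5000 SNPs, 42 progeny, 10⁶-fragment libraries; 100-seed
karyotype sweeps; 100-replicate null DEG simulations; 1000-replicate CI
coverage) were chosen as the smallest at which the Monte-Carlo
tolerances quoted in the tests are meaningful.

## Known limitations

The DEG test is a two-group location test, not a GLM: no covariates,
no paired designs. Homeolog groups must be supplied (or simulated);
sequence-based homeolog inference is out of scope. The dosage caller
assumes whole-chromosome events; segmental losses will produce
intermediate ratios it labels with the nearest whole-chromosome state.
The ED scan assumes exactly two bulks. Marker logic is dominant
(band dose), not codominant allele-pair scoring.
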