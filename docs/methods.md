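# Methods

## Scope and data flow

`ulpcna` estimates tumor fraction (TF) and megabase-scale somatic copy
number from binned read counts of ultra-low-pass WGS (~0.1×) of cfDNA.
The pipeline is: bin counting (1 Mb, reads assigned to the bin containing
their leftmost aligned position; duplicates excluded when flagged) →
gap/centromere masking (gap intervals ±1 Mb flank) → GC and mappability
LOESS correction → sex inference and male chrX rescaling → healthy-donor
reference normalization → log2 copy ratios → Bayesian HMM → solution
selection → segments and summary statistics.

Coordinates are 0-based half-open internally; WIG and SEG output use the
1-based conventions of those formats.  Reads spanning a bin boundary are
assigned by leftmost position; at 1 Mb resolution fractional assignment
is immaterial.

## Normalization

Two LOESS fits are applied sequentially to valid autosomal bins: read
count vs GC fraction (span 0.3), then the GC-corrected count vs
mappability (span 0.99).  The spans follow the convention of the binned
read-depth correction tools this step is modeled on; the bias model is
multiplicative (coverage bias is proportional), so counts are divided by
the fitted curve and then by the valid autosomal median, putting a
copy-neutral genome at corrected coverage 1.  Bins with mappability
< 0.9 are excluded from fitting and flagged invalid (configurable).
Fitting requires ≥100 valid autosomal bins.

A sample is called male when the uncorrected chrY read share exceeds
0.001 **and** the median corrected chrX log2 ratio is below −0.5; male
chrX is rescaled by its median.  The donor reference is the per-bin
median of corrected coverage across the panel; without a panel the
sample's own autosomal median is used (degraded mode, logged).  For
mixed-sex panels the median is taken as supplied; the benchmark
simulations are autosome-only, so sex stratification of the panel never
arises there.

## The HMM

* **States** — clonal copies {1,…,5}; optional subclonal one-copy loss
  and gain sharing a single subclone parameter *s* (one detectable
  subclone is assumed; with ULP data and no allelic information more
  cannot be resolved).  HLAMP is modeled at exactly c = 5.
* **Emission** — Student's-t(μ_g, λ_g, ν = 2.1), ν fixed.  State means are
  in log base 2 so they live on the scale of the data; a bin at the
  tumor's average ploidy sits at 0.
* **Transitions** — stationary, self-transition e = 0.99999, remainder
  uniform.  A is built from e and held fixed during EM: with ~3,000 bins
  the Dirichlet-MAP update moves it by O(10⁻⁴) and has no measurable
  effect (an `update_transitions` switch enables the update).
* **Priors** — flat Beta(1,1) on n and s, flat (improper) on φ, flat
  Dirichlet on π, and Gamma(shape 3, scale (sd(l)/√|K|)⁻¹) on each λ_g,
  i.e. the precision prior tracks the sample's own spread.
* **EM** — E-step by scaled forward–backward; M-step by MAP updates:
  closed-form λ via the Student's-t latent-scale weights
  u = (ν+1)/(ν+λ(l−μ)²); (n, φ, s) by bounded one-dimensional
  maximization (Brent; n, s ∈ [0.01, 0.99], φ ∈ [1.5, 5]) of the
  penalized expected log posterior, one coordinate pass per iteration,
  keeping the current value whenever a candidate does not improve the
  objective (guarantees monotonicity); π by Dirichlet MAP.  λ is
  initialized at 1/var(l), s at 0.1 (a near-clonal start; a symmetric
  s = 0.5 start can trap the fit in a mode that splits clonal events
  between clonal and subclonal explanations).
* **Convergence** — the objective F (observed-data log-likelihood plus
  log prior) must increase by less than max(10⁻³, 10⁻⁴·|F|); at most 50
  iterations.  Restarts: n⁽⁰⁾ ∈ {0.35, 0.45, 0.50, 0.65, 0.75, 0.85,
  0.95} × φ⁽⁰⁾ ∈ {2, 3, 4} (the serial-mixture protocol restricts to
  φ⁽⁰⁾ = 2).
* **chr19** is excluded from parameter estimation (few bins, historically
  biased) but decoded; chrX is excluded from both by default.
* Forward–backward/Viterbi inner loops are numba-JIT-compiled when numba
  is importable, with an identical NumPy code path otherwise; both are
  checked against exhaustive path enumeration in the tests.

## Solution selection

Each restart is decoded (Viterbi, ties toward the lower state index) and
summarized: fraction of valid bins altered, fraction of the genome in
subclonal states, subclonal share of CNA calls (counted over bins; a
segment-count variant exists but bins proved more robust against fits
that hide inflated tumor fractions behind mid-prevalence subclonal
labels), largest event size.  Selection:

1. Candidates with >50 % of the genome subclonal or >70 % of CNA calls
   subclonal are dropped (clonal/subclonal identifiability guard); if
   everything is dropped, the max-F candidate is returned flagged.
2. Among survivors the maximum-F candidate wins.  Candidates whose F is
   within 0.05 of the maximum are treated as **tied** and broken by
   parsimony — fewest altered bins, then largest normal fraction.
   Rationale: without allelic data a whole-genome ploidy rescaling (all
   bins NEUT at φ = 2 vs all bins AMP at φ = 4) yields *identical*
   likelihoods; the F values differ only by optimizer noise and an
   arbitrary argmax regularly picked the everything-altered reading on
   tumor-free samples.
3. Zero-TF rule: a winner with <5 % of bins altered and no event ≥50
   bins is reported as TF 0.
4. Degenerate subclone handling: when ŝ ≤ 0.2 (subclone prevalence
   ≥ 0.8, operationally clonal at this resolution) subclonal Viterbi
   labels are remapped to their clonal counterpart before the summaries;
   when ŝ ≥ 0.8 they are remapped to NEUT.  At endpoint ŝ the subclonal
   states are near-exact twins of other states, the label split is
   arbitrary, and without the remap the subclonality filters misfire on
   correct solutions.

Reported TF is 1 − n̂, uncorrected for s (consistent with treating
low-prevalence events as not contributing to tumor content; against
purity from deep sequencing this can be an underestimate).

## Synthetic data

The generator emulates the study conditions the benchmarks assume:

* hg19 autosomes, 1 Mb bins (2,897 bins), ~1.5 × 10⁶ reads ≈ 0.1×.
* Per-bin intensity ∝ 2n + (1−n)(2s_t + (1−s_t)c_t), times a unimodal
  quadratic GC-bias curve (peak at GC 0.45, ±20 %) and mappability, then
  Poisson-sampled.  GC/mappability annotations are genome properties,
  fixed by their own seed.  An optional gamma overdispersion knob
  (`OVERDISPERSION_ULP` ≈ 0.017) reproduces noisier libraries with
  sd(l) ≈ 0.2 at 0.1×; the default is pure Poisson counting noise.
* The tumor source profile is a metastatic-breast-cancer-like genome:
  arm/chromosome-scale events at copies 1, 3, 4 and 5 covering ~36 % of
  bins, balanced so the mean copy number is exactly 2 (the admixture
  algebra then makes expected TF = proportion × source purity exact).
* Mixtures: binomial thinning (per-read down-sampling), serial
  tumor/normal admixtures (the full published design is 16 proportions ×
  12 coverages = 192 mixtures), exact-TF mixtures
  (CT_reads = 1.5·10⁶·TF/purity), and spike-ins that rescale a
  copy-neutral track's own counts inside event regions (losses thinned
  binomially, gains topped up with a Poisson increment), inheriting its
  noise.
* The default reference panel is 27 tumor-free donors with fixed derived
  seeds.

What the generator does **not** model: correlated (wavy) coverage bias,
fragment-size effects (averaged out at 1 Mb), replication-timing
signal, real inter-donor panel structure, or subclonal truth profiles
(benchmark truth is clonal).  Passing benchmarks therefore demonstrate
correctness of the inference under the stated noise model, not
performance on any particular real library.

## Benchmark problem sizes

The acceptance benchmarks run the full pipeline at these sizes: serial
grid — proportions {0.01, 0.05, 0.11, 0.21, 0.35, 0.45} × coverages
{0.1×, 0.5×, 1×} × 3 seeds (54 mixtures, 7 restarts each; a reduced but
structurally faithful version of the 192-mixture design); sensitivity —
proportions {0.15 … 0.45} × 5 seeds at 0.1× (35 mixtures with expected
TF > 0.10); specificity — 22 tumor-free donors, full 21-restart grid;
detection limit — spiked TF ladder 0.01–0.10 (step 0.01, 5 seeds each,
ascending with early stop at the first majority-detected level).

## Known limitations

* **Detection limit for minimal event sets.**  With one arm-level gain
  plus one arm-level loss, detection requires the decoded path to leave
  the neutral state, which costs 2·log((1−e)/(|K|−1)) ≈ 26.6 nats per
  event against e = 0.99999, while a ~240-bin one-copy event at TF 0.03
  under Poisson noise at ~520 reads/bin carries only ~25 nats of
  evidence (and the precision prior adds a small penalty for populating
  an otherwise-empty state).  The smallest reliably detected spike-in
  level therefore sits at the 0.03–0.04 boundary and is seed-dependent;
  the benchmark script reports the measured value.
* Tumor fractions below ~0.01–0.02 on low-amplitude genomes are zeroed
  by design (no-signal rule) rather than estimated.
* Ploidy is only identified through SCNA amplitude ratios; genomes whose
  events are invisible at a given depth leave φ (and hence TF) weakly
  constrained — the parsimony tie-break then prefers the neutral
  reading.
* Homozygous deletions (c = 0) and copy numbers above 5 are outside the
  state space; real focal high-level amplifications are absorbed by
  HLAMP with a biased amplitude.
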