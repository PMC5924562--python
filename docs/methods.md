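# Methods

`mitodem` analyses temporal samples of a single non-recombining, maternally
inherited haploid locus (a mitogenome) to quantify diversity loss between
dated sample layers and to infer bottleneck/expansion demography by
approximate Bayesian computation (ABC). The package was shaped around a
concrete study system — 39 historical museum specimens (1847–1985) and 79
modern individuals of a severely bottlenecked island parrot, each
represented by a 16,588 bp mitogenome — but every stage is generic over the
sampling design.

## Demographic model

All scenarios are piecewise-constant haploid effective-size histories on a
backwards-time axis in generations before present (time 0 = the modern
layer; years = generations × 25 by default). Six scenarios are built in:
constant size; post-glacial expansion; expansion plus one generic recent
bottleneck; and three refined variants in which the bottleneck is tied to
European settlement (1–10 generations ago), Polynesian settlement (20–30
generations ago), or both in sequence. Sizes are haploid (female) effective
sizes: `k` lineages coalesce at rate `k(k−1)/(2N)` per generation. Epoch
changes are instantaneous steps; there is no growth curve, migration or
structure.

Priors are independent uniforms with order conditions enforced by
draw-and-reject: modern size U(1, 200); pre-European and pre-human sizes
U(5×10³, 6×10⁵); pre-glaciation size U(10³, 3×10⁵); bottleneck times
U(1, 10) and U(20, 30); expansion time U(300, 600) generations; mutation
rate U(10⁻⁸, 10⁻⁷) per site per generation. Conditions: the pre-European
(or pre-human) size must exceed the pre-glaciation size, and the pre-human
size must exceed the pre-European size in the double-bottleneck model.

Choices that were genuinely open:

- the constant model's single size reuses the pre-glaciation prior, and the
  expansion model's post-expansion size reuses the pre-European prior, so
  the simpler models nest inside the bottleneck models;
- the generic recent-bottleneck time in `expansion_bottleneck` is U(1, 30),
  spanning both candidate settlement windows;
- the expansion scenarios carry the "recent size > ancestral size" order
  condition, without which they would not describe expansions;
- mtDNA effective sizes are interpreted as haploid throughout (a config
  switch is unnecessary because every size enters only through `2N`).

## Coalescent simulator

Heterochronous (serial-sample) coalescent: lineages activate backwards in
time at their layer's age; within an epoch of size N the waiting time to
the next coalescence of k active lineages is Exponential(k(k−1)/(2N)),
truncated at epoch boundaries and activation times. The historical layer's
age defaults to 5 generations before present (collection span 1847–1985 at
25-year generations relative to 1990s–2000s sampling).

Mutations are Poisson(μ·L·branch length) per branch. The default model is
infinite sites — every mutation occupies a fresh site, so segregating sites
equal mutation count and the summary statistics are exactly interpretable —
with an explicit error (and a finite-sites Jukes–Cantor alternative) if
mutations ever exceed L. During reference-table construction a
site-exhaustion draw triggers a fresh parameter draw with a logged warning;
such prior corners (θ on the order of L) are astronomically far from any
observable dataset, so the effective truncation is immaterial.

Calibration is tested against closed forms (E[TMRCA] = 2N(1−1/n);
Watterson's E[S] = a₁·2NμL; Poisson branch counts) and distributionally
against msprime (ploidy 1) by two-sample Kolmogorov–Smirnov tests.

A note on Tajima's D under neutrality: the statistic's mean is not exactly
zero; its small negative bias grows with θ (confirmed here with msprime:
≈ −0.06 at θ ≈ 7, ≈ −0.24 at θ ≈ 250, n ≈ 40, no recombination).
Neutrality bands of ±0.15 are therefore checked at data-like moderate
diversity, not at the upper end of the priors.

## Summary statistics

Per layer: sample size n, haplotype count h, segregating sites S, haplotype
diversity Hd = n(1−Σpᵢ²)/(n−1) with Nei's sampling variance, mean pairwise
differences k, nucleotide diversity π = k/L_eff with the no-recombination
coalescent variance b₁π/L + b₂π², Tajima's D, and Fu's Fs.

Missing data (N or gap) follows a complete-deletion policy by default:
columns containing any undetermined base are removed once from the whole
alignment, so every layer sees the same effective sites (L_eff). A pairwise
policy is available. Missing-data handling is the main unresolvable
ambiguity when comparing against published DnaSP values computed on the
real alignment (see Limitations).

Fu's Fs is computed exactly: with θ set to the layer's k, the probability
S′ = P(K ≥ h) of at least the observed number of haplotypes follows from
the Ewens sampling formula, S′ = Σ_{j=h}^n |s(n,j)| θʲ / (θ)ₙ, evaluated
with arbitrary-precision Stirling numbers of the first kind and rational
arithmetic, then Fs = ln(S′/(1−S′)). This keeps the deep tail (e.g. 36
haplotypes among 39 samples, S′ ≈ e⁻²⁷) exact where floating rejection
sums underflow; a log-space floating evaluation is kept as a cross-check
(they agree to 10⁻⁶ up to n = 79). h = 1 yields +∞ by convention; k = 0
leaves Fs undefined.

The ABC feature vector is (h, S, k, D) per layer, layers youngest first
(8 features for the two-layer design). An undefined D (monomorphic layer)
is encoded as 0 with a warning so reference tables have no missing cells;
this distorts only near-monomorphic simulations.

## ABC

- Reference table: for each scenario, prior-predictive simulations reduced
  to feature vectors; per-feature scale = pooled standard deviation
  (MAD optional).
- Distance: normalized Euclidean.
- Rejection: the closest ⌈fraction·rows⌉ rows (1% at full scale), ties at
  the threshold broken by row order.
- Regression adjustment: weighted local-linear regression of each parameter
  on observed-centered features, Epanechnikov weights with bandwidth equal
  to the largest accepted distance; parameters with known prior bounds are
  regressed on a logit scale and back-transformed, so adjusted draws always
  respect the prior. Singular designs fall back to the unadjusted sample.
- Model choice: kernel-weighted multinomial logistic regression of scenario
  label on features over the accepted set, evaluated at the observed
  vector. The regression is effectively unpenalized (sklearn with C = 10⁶):
  ridge shrinkage measurably blunts discrimination between near-separable
  scenarios.
- Posterior summaries: weighted Gaussian-KDE (Silverman bandwidth) on the
  prior-bounded support; the mode is the density argmax and the 5%/95%
  bounds delimit the envelope of the 90% highest-density region, so the
  mode always lies inside the interval.
- Pods: prior-predictive pseudo-observed datasets pushed through the whole
  pipeline against a shared reference table; type I error of a focal
  scenario = fraction of its own pods assigned elsewhere, type II =
  fraction of other scenarios' pods assigned to it.

Scaled-down defaults (10⁴ simulations per model) keep a laptop run in
minutes; the full-scale 10⁶ is a configuration choice, not a code path.

At the scaled setting, discriminating the European-bottleneck scenario from
the Polynesian one from 100 pods per scenario gives an overall
misassignment rate of about 5%: pods whose bottleneck predates the
historical layer's age are genuinely similar under both scenarios, and the
published near-zero error rates were obtained at 100× the table size.
Regression-adjusted 90% HPD intervals for the modern effective size cover
the truth for roughly 85–91% of pods — the familiar slight under-coverage
of regression-adjusted ABC.

## Synthetic data

The generator reproduces the study's shape (two layers, 39+79 sequences,
16,588 bp) and emulates low-coverage consensus calling by replacing each
base of a historical sequence by N independently with probability 0.02
(modern: 0). It does not model post-mortem damage (deamination),
contamination, coverage clustering along fragments, indels or rate
heterogeneity — so a green test establishes correctness of the statistics
and inference machinery on idealized data, not robustness to ancient-DNA
artefacts.

## Haplotype networks

Sequences collapse to haplotypes over the shared effective columns. The
network is a minimum-spanning network — the union of all minimum spanning
trees of the complete Hamming-distance graph, built by admitting every
tie edge that joins distinct components at each Kruskal distance tier.
This deliberately replaces median-joining (which infers unsampled median
haplotypes); published network figures are illustrative rather than
quantitative targets, and raw Hamming step counts are exposed alongside.

## Numerical and degenerate-input conventions

- All randomness flows through one `numpy.random.Generator`; equal seeds
  give byte-identical outputs.
- Tajima's D with S = 0 and Fs with k = 0 are explicit "not computable"
  results (`None`), never silently 0 — except inside ABC feature vectors
  (see above).
- Draw-and-reject raises after 10⁶ consecutive constraint violations.
- A point-mass posterior sample returns mode = HPD bounds = the point.
- Rejection keeps at least one row (`ceil`), and the KDE grid is padded 5%
  beyond the sample range, clipped to the prior.

## Known limitations

- Published DnaSP statistics on the real alignment cannot be reproduced
  bit-for-bit from printed, rounded π values; in particular the published
  historical Fu's Fs (−24.48) corresponds to k ≈ 11.4 while printed π ×
  L gives k = 9.787 (exact Fs −27.44). The discrepancy is consistent with
  a different missing-data normalization inside DnaSP and cannot be
  resolved without the underlying sequences.
- The mutation model behind the original DIYABC analysis is not public;
  infinite sites is a documented substitute, not a reconstruction.
- Full-scale ABC results (posterior modes from 10⁶-row tables on the real
  data) are out of desk-reproducible scope; the pipeline's correctness is
  established on closed forms, conjugate toys and scaled pod studies.
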