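# Methods

## Problem and data model

T-RFLP fingerprinting of 16S rRNA amplicons yields, per sample, an
electropherogram tabulated as peaks: terminal restriction fragment (T-RF)
size in base pairs and peak height in relative fluorescence units (RFU).
A profile mixes a few tall peaks from genuinely abundant fragments with
many small peaks from instrument noise and incomplete digestion.
Taxon-specific qPCR complements the fingerprint with relative abundances
of selected bacteria, and fermentation chemistry (pH, NH₃-N, VFA) is
measured per animal under each diet. The package processes all three
data streams for a crossed design of 3 ruminant species × 4 animals
(nested in species) × 2 diets (high forage, HF; high concentrate, HC),
each animal sampled under both diets.

## True-peak calling

Peaks outside the calibrated 27–520 bp read window are discarded first;
the bounds are inclusive (only fragments strictly shorter than 27 bp or
strictly longer than 520 bp are dropped).

Background peak heights are modelled as fluctuations about a true mean
of zero, so their scale is estimated as the root mean square
`SD = √(Σ h²/n)` (divisor `n`, not `n−1`, because the mean is known, not
estimated). The caller iterates:

1. compute `SD` over all peaks not yet declared true;
2. declare true every remaining peak with height strictly greater than
   `k·SD` (default `k = 3`);
3. stop when an iteration declares nothing (or at `max_iter = 100`, then
   flagged as non-converged; in practice convergence takes a handful of
   rounds).

Because called peaks are removed before re-estimating `SD`, a decreasing
run of dominant peaks is peeled off top-down. The rule is invariant to
peak order and to uniform rescaling of all heights, and raising `k`
can only shrink the true-peak set — both properties are tested.

Two intrinsic limits of the rule, relevant when interpreting results:

- *Self-masking*: a community of `m` equally tall peaks among `n_b`
  background peaks is undetectable once `3·√(m/(m+n_b)) ≥ 1`
  (about `m ≥ n_b/8`), because the true peaks themselves inflate the
  estimate they are compared against.
- *False positives*: after all true peaks are removed the remaining
  background exceeds `3·SD` with probability ≈ `P(|Z|>3) ≈ 0.27 %` per
  peak, so with ~150 background peaks roughly every third sample
  contributes one spurious low peak. These carry a fraction of a percent
  of total height and are tolerated rather than suppressed.

## Binning and standardization

True-peak fragment lengths are pooled across samples, sorted, and
chained in a single pass: a length joins the current bin while its gap
to the previous pooled length is at most the tolerance (default 0.5 bp,
configurable; sizing precision of capillary systems is of this order).
Each bin is represented by the arithmetic mean of its member lengths;
heights of one sample's peaks falling in the same bin are summed, so
binning conserves each sample's total true-peak height. Columns are then
divided by their sums, giving relative abundances (all-zero columns —
samples with no true peaks — are left zero and flagged). Chaining can in
principle grow a bin wider than the tolerance across many samples; with
planted fragment spacing of at least twice the tolerance this does not
merge distinct fragments.

## Diversity

Shannon entropy `H = −Σ pᵢ ln pᵢ` (natural log by default; the base is
an argument) and inverse Simpson `D = 1/Σ pᵢ²` are computed per
standardized sample column. As Hill numbers of orders 1 and 2,
`exp(H) ≥ D` always; both are permutation-invariant and unaffected by
empty bins. No rarefaction or coverage correction is applied — peak
heights are already relative quantities, not counts.

## Ordination

Samples are the observations throughout. Euclidean distances between
standardized profiles feed complete-linkage agglomeration (scipy's
implementation; merge heights are non-decreasing by the monotonicity of
the farthest-neighbour criterion), serialized to Newick with branch
lengths equal to parent-minus-child merge heights. PCA mean-centers the
bin variables without variance scaling — profiles are already on a
common relative scale — and reports eigenvalues of the sample covariance
(divisor `n−1`) plus percent variance explained. Each component's sign
is fixed by making its largest-magnitude loading positive, so output is
deterministic; ties in clustering follow scipy's ordering (real-valued
profile data makes exact ties a measure-zero event).

## qPCR relative quantification

Replicate Ct values (triplicates in the study design) are aggregated by
arithmetic mean; replicate SD above 0.5 cycles flags the record. Under
perfect doubling per cycle (no efficiency correction), abundance
relative to the universal total-bacteria assay is
`100 · 2^−(Ct_target − Ct_total)` percent. Values above 100 % (target
amplifying before the universal assay) are flagged, never clamped, and
a missing total-bacteria assay yields a flagged record rather than an
error. Fold changes between diet groups are computed either as ratio of
group means (the default; group means first, within species, then
optionally averaged across species before taking the ratio) or as mean
of per-animal ratios; the reciprocal symmetry `fold(a,b)·fold(b,a)=1`
holds for ratio-of-means. A presentation value rounds to the nearest
integer, or the nearest hundred above 1,000.

## Split-plot analysis

Fermentation-type responses follow
`y = μ + speciesᵢ + animalⱼ₍ᵢ₎ + dietₖ + (species×diet)ᵢₖ + e` with
animal-within-species random. On the balanced layout the classic
split-plot decomposition gives exact tests: species against the
animal-within-species mean square (whole-plot stratum, df `a(n−1)`),
diet and interaction against the residual (sub-plot stratum). This
coincides with the REML mixed-model F-tests (and Kenward-Roger degrees
of freedom) on balanced data, which is why the simpler closed-form
decomposition is used; unbalanced layouts are rejected with an explicit
error pointing to general mixed-model software instead of being
approximated. Variance components come from the expected mean squares,
truncated at zero. The pooled SEM reported with cell means is
`√(MS_residual/n)`.

Tukey comparisons of the six species×diet cells use the studentized
range distribution (scipy's `studentized_range`, no lookup tables) with
the sub-plot error stratum; for two groups this reduces exactly to the
unadjusted t-test. Each response is analysed separately with no
multiplicity correction across responses, matching the field's reporting
convention (`p < 0.05` significant, `0.05 ≤ p < 0.1` a trend).

## Synthetic data: what it emulates, and what it does not

The generator plants ground truth for every stage:

- **Communities**: fragment lengths uniform in the size window with
  pairwise spacing ≥ 2× the binning tolerance (rejection sampling), so
  bin identity is unambiguous. Abundance models: equal, geometric, or
  broken-stick. The default is geometric with ratio 0.9 — a realistic
  rank-abundance curve whose rarest of 20 taxa still clears the
  detection threshold ~6-fold, whereas an equal-abundance field of that
  size would self-mask (see above).
- **Electropherograms**: true heights `signal_scale × abundance` with
  2 % multiplicative Gaussian noise; `n_background` peaks at uniform
  lengths with heights `|N(0, background_scale)|` — positive RFU values
  whose zero-anchored scale matches what the detection rule estimates.
  Defaults: 20,000 RFU signal, 50 RFU background scale, 150 background
  peaks, so the planted minimum height exceeds the 3-SD threshold in
  ≈ 99 % of realizations.
- **Ct tables**: the 2^−ΔCt transform inverted — a taxon at `a` % of
  total amplifies `−log₂(a/100)` cycles after the total assay — plus
  Gaussian cycle noise (default SD 0.2, 3 replicates). The ΔCt estimator
  is unbiased on the ΔCt scale; noise-free simulation round-trips
  exactly.
- **Fermentation**: additive fixed effects (or a planted species×diet
  cell-mean table), animal intercepts `N(0, σ²_animal)` and residuals
  `N(0, σ²_e)`; defaults σ_animal = 0.3, σ_e = 0.1 on the pH scale.
  The full-study driver plants the reference trial's published cell
  means per response, with noise scaled from the published SEM.

One global seed fans out to per-stream generators through
`SeedSequence` spawn keys, so streams are independent and adding one
does not perturb another; identical seeds give bit-identical output.

Not emulated: dye pull-up, stutter and size-standard artifacts;
amplification-efficiency variation and primer bias; multi-enzyme digest
fusion (each digest's table is processed independently); any mechanistic
rumen fermentation dynamics. Passing recovery tests therefore shows the
*computational chain* is faithful to its rules, not that the rules are
robust to every instrument artifact of real electropherograms.

## Problem sizes and numerical choices

The simulation-based checks run at sizes chosen to keep the whole suite
comfortably interactive: 200 seeds for end-to-end community recovery
(success = every planted length matched within tolerance and every
planted abundance within 2 points absolute; spurious low bins from the
false-positive mechanism above are allowed), 1,000 random tables for the
peak-caller oracle, 1,000 seeds for ΔCt unbiasedness, and 2,000
simulated studies each for the type-I-error and power calibrations of
the diet F-test. Brute-force oracles (pure-loop peak calling, O(n³)
agglomeration, explicit cell-mean ANOVA sums of squares) are kept
independent of the library implementations they check, with agreement
required to 1e−8 where arithmetic is deterministic.

Degenerate inputs have defined behaviour rather than crashes: empty
peak tables, all-zero profiles (diversity undefined, NaN), zero residual
variance (infinite F, p = 0), missing total-bacteria assays, and
non-converged detection are all flagged and tested.

## Known limitations

- The published per-animal raw data of the reference trial are not
  available, so its diversity table, dendrogram and PCA coordinates
  cannot be reproduced; only the derived summaries of its group-mean
  tables are recomputed exactly. Group means entered at printed
  precision bound what is recoverable: the M. elsdenii fold evaluates to
  1636 from the printed three-decimal means, against the trial's
  "approximately 1,700" computed from unrounded data.
- The split-plot engine deliberately handles balanced designs only.
- Binning is a heuristic; profiles whose fragment lengths drift by more
  than the tolerance across runs will fragment or merge bins.
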