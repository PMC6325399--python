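# rumenprof

Community profiling of rumen bacteria from T-RFLP fingerprints and qPCR,
built for cross-species diet-challenge experiments: three ruminant
species (Hanwoo cattle, Holstein cattle, Korean native goats) abruptly
switched from a high-forage ration (HF) to concentrate only (HC), with
rumen fermentation chemistry, 16S T-RFLP fingerprints and taxon-specific
qPCR assayed under both diets.

The package turns three delimited-text inputs — electropherogram peak
tables (fragment size in bp, height in RFU), replicate qPCR Ct tables,
and per-animal fermentation records — into:

- **T-RF profiles**: size filtering to 27–520 bp, *iterative true-peak
  calling* (peaks above `k·SD` of the background, where the background
  SD is the zero-mean RMS `√(Σh²/n)` recomputed after each removal of
  called peaks, k = 3), cross-sample *fragment binning* (sorted
  single-pass chaining, 0.5 bp tolerance, bins represented by their mean
  length), and within-sample standardization to relative abundances;
- **diversity**: Shannon `H = −Σ pᵢ ln pᵢ` and inverse Simpson
  `D = 1/Σ pᵢ²` per sample;
- **ordination**: Euclidean distances between standardized profiles,
  complete-linkage HCA (Newick dendrogram), and centered unscaled PCA
  with per-component variance explained;
- **qPCR quantification**: relative abundance
  `% of total bacteria = 100·2^−ΔCt`, `ΔCt = Ct_target − Ct_total`, from
  mean replicate Ct, with fold-change summaries between diets;
- **statistics**: the balanced split-plot ANOVA
  `y = μ + speciesᵢ + animalⱼ₍ᵢ₎ + dietₖ + (species×diet)ᵢₖ + e`,
  species tested against animal-within-species, diet and interaction
  against the residual, plus Tukey comparisons of the six cells.

A synthetic-data generator plants known communities, Ct values and
factorial effects so every stage is testable with ground truth; no
external data download is needed.

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated
data and write their tables under `results/`:

```
$ python analysis/01_simulate_study.py
simulated 24 samples (3840 raw peaks), 192 Ct records, 10 fermentation responses -> results/simulated

$ python analysis/02_trflp_profiles.py
237 true peaks called across 24 samples; 18 bins; 10/10 planted fragment lengths recovered within 0.5 bp
```

Of 3,840 raw peaks (mostly low half-normal background), the iterative
3-SD rule keeps 237; binning them across the 24 samples yields 18
fragment bins, and all 10 planted fragment lengths come back within the
0.5 bp tolerance.

```
$ python analysis/05_qpcr_abundance.py
median relative recovery error vs planted abundances: 7.0%
         taxon  fold_hc_vs_hf reported
F_succinogenes       0.085304        0
 Lactobacillus      39.759478       40
    M_elsdenii    1715.304862    1,700
    ...
```

Planted qPCR abundances (spanning 0.001 % to 52 % of total bacteria)
are recovered with ~7 % median relative error under 0.2-cycle Ct noise,
and the diet fold changes of the lactate producers/utilizers are
reproduced from the simulated Ct values alone.

```
$ python analysis/06_fermentation_anova.py   # excerpt
response   sem     p_species  p_diet   p_interaction
pH         0.0980  0.1202     0.0000   0.0443
total_VFA  6.8383  0.0369     0.0024   0.0028
```

With cell means planted at the reference trial's published values, the
split-plot tests recover the expected pattern: a strong diet effect on
pH, and species×diet interactions for pH and total VFA.

The CLI wraps the same stages (`rumenprof --seed 5 --out-dir results run-all`,
or individual subcommands `simulate`, `peaks`, `bin`, `diversity`,
`ordinate`, `qpcr`, `anova`).

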