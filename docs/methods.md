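# Methods

This note documents the statistical procedures implemented in `rescuetax`,
the choices made where the design was open, and what the synthetic-data
tests do and do not demonstrate about real data.

## Data model

Abundance tables are samples × taxa matrices at a single taxonomic level,
stored internally as proportions on [0, 1] (rows sum to 1 within 1e-9);
percent formatting happens only in reports. Taxa absent from a sample are
explicit zeros, never missing — the abundance- and presence-based
dissimilarities depend on that convention. "Unclassified" taxa (`uncl. X`
labels) are ordinary columns with no special handling. The design names
exactly three ordered roles — control diet, disease diet, treated disease
diet — with default labels ND / WD / WD-T070 and default sizes 11 / 10 / 8.

## Diversity

* **Shannon index** uses the natural log (nats); the input is renormalized
  first, so counts and proportions give identical values.
* **Chao1** is the bias-corrected form `S_obs + F1(F1−1)/(2(F2+1))`, which
  stays finite when no doubletons are observed. It is defined for integer
  counts only; relative tables are rejected rather than silently rescaled.
* **Rarefied Chao1** averages Chao1 over repeated subsamples drawn without
  replacement (multivariate hypergeometric) at a fixed depth; defaults are
  depth = smallest sample total and 100 replicates, seeded.
* **Bray–Curtis** (`Σ|x−y| / Σ(x+y)`) and **Jaccard** on presence
  (`1 − |shared|/|union|`) are both bounded in [0, 1].
* **PCoA** is Gower's classical scaling: double-center `−D²/2`,
  eigendecompose, scale eigenvectors by √eigenvalue. The full spectrum is
  reported (negative eigenvalues are a useful non-Euclideanity diagnostic)
  but only positive eigenvalues contribute coordinates and variance
  proportions.
* **PERMANOVA** is the one-way dissimilarity-based variance partition:
  `SS_total = Σ_{i<j} d²_ij / N`, within-group sums from within-group
  pairs, `R² = 1 − SS_within/SS_total`,
  `pseudo-F = (SS_between/(a−1)) / (SS_within/(N−a))`. Labels are permuted
  freely (no strata); the Monte-Carlo p-value uses the `(hits+1)/(m+1)`
  convention with a mandatory seed (default 9999 permutations), and small
  designs can request the exhaustive p over all label orderings. Pairwise
  group comparisons are plain subsets with no correction across the three
  pairs. Group-dispersion testing and phylogenetic metrics are out of
  scope.
* **Kruskal–Wallis** uses average ranks with the standard tie-correction
  divisor; an all-tied input returns H = 0, p = 1 rather than 0/0.

## Indicator taxa

The screen runs Kruskal–Wallis per taxon across the three groups and
adjusts with Benjamini–Hochberg over all taxa in the table. Each of the six
coded models maps groups to arbitrary units (25/75/10, 25/75/25, 25/75/50,
25/75/75, 25/75/100, 100/100/10); codes are attached **per sample**, so the
unbalanced design weights the correlation naturally. The fit statistic is
the Pearson correlation between abundances and codes — for a single
regressor this is equivalent to testing the linear-model slope, so one fit
serves as both correlation test and linear model. Choices:

* α = 0.05 for both the adjusted screen and the per-model fits; the
  per-model p-values are not additionally corrected across the six models
  (the FDR correction belongs to the taxon screen).
* A taxon is an indicator iff both conditions hold; the selected model is
  the significant fit with maximal r², ties broken toward the lower model
  index.
* Zero-variance taxa have no defined correlation and are recorded as
  r = 0, p = 1, r² = 0 — never indicators, never NaN.
* Percent change between group means is truncated toward zero to an integer
  (`trunc(100·(new−ref)/ref)`); this is the convention under which the
  packaged fixture means reproduce the printed group-contrast percentages.
* The Firmicutes/Bacteroidetes ratio is computed per sample and summarized
  as the group mean ± SD of per-sample ratios (not the ratio of group
  means).
* Per-pair taxon tests (e.g. ND vs WD columns of a summary table) use the
  two-group Kruskal–Wallis (equivalent to Mann–Whitney) with BH across taxa
  within each pair; this is an interpretation, as the pairwise test behind
  such tables is rarely stated.

**Distinguishability of the codings.** Under the 11/10/8 design the coded
vectors of models 1 and 2 correlate at 0.976 (they differ only in the
treatment-group code, 10 vs 25), and 3 vs 4 at 0.888. Model identification
therefore requires strong effects: in the recovery benchmark, taxa planted
at effect r² ≈ 0.85 are recovered at ≥95% for codings 1, 2, 5 and 6,
whereas near r² ≈ 0.5–0.6 the 1↔2 confusion alone caps recovery around
80%. Classification *as an indicator* is much less demanding than
identification of the exact coding; confusions are confined to adjacent
codings.

## Phenotype correlation

Per-feature Pearson r against a named phenotype, two-sided p from the t
distribution (n−2 df), BH adjustment across the features tested in one
call. Sample matching is pairwise-complete per feature; zero-variance
features are flagged and excluded from the FDR family. Group filtering
(e.g. restricting an SCFA–cholesterol analysis to the disease and treated
groups) is explicit via `subset_groups`, never implicit. Abundances enter
as proportions without transformation.

## Lipase dose–response

Relative activity is residual rate / negative-control rate × 100. The IC50
rule is deliberately discrete: the lowest *tested* concentration at which
activity is ≤50% (inclusive), or none. No sigmoid/4PL fitting is performed,
so the result's resolution is the dilution grid's — printed IC50 values
with more precision than a sparse grid affords cannot be reproduced by this
rule and are not targets.

## Synthetic studies

`generate_study` draws each taxon independently per sample from a gamma
distribution moment-matched to the group's mean/SD target (shape = (m/s)²,
scale = s²/m; SD 0 gives the constant mean, mean 0 gives zeros), appends a
zero-SD filler taxon absorbing `100 − Σ means` per group, and renormalizes
rows to compositions. A joint Dirichlet mode is available when exact
compositionality of the noise matters more than per-taxon SD targets (its
spread is a single concentration parameter). Phenotypes are
`group mean + group SD · (Σ_k r_k z_k + √(1−Σr_k²)·ε)`, where `z_k` is the
standardized abundance of a coupled taxon; the planted `r` is the coupling
strength, and group-level mean structure can reinforce the realized
correlation beyond it. `generate_null_study` draws all three groups from
the control distribution and ignores couplings.

Numerical properties, verified at n = 10,000 per group: group sample means
match targets within 2%. Realized SDs are faithful for minor-share taxa
(within ~15%) but *shrink below target for taxa that dominate the
composition*, because a dominant taxon's noise partly cancels in its own
row total — a known limitation of gamma-then-renormalize generators. The
fixture communities' group sizes (11/10/8), means and SDs, and the signs
of the cholesterol couplings (negative for the *Muribaculum*-like genus,
positive for the *Lactococcus*-like genus at |r| = 0.6) are the packaged
study conditions. Cholesterol group means (100 / 136 / 121 mg/dl, SD 12)
were chosen once as realistic values consistent with the study's reported
relative differences (+36% disease vs control, −11% treatment vs disease);
absolute per-group values are not published.

What passing tests show — and don't. The generator reproduces the *marginal*
group structure (means, SDs, compositionality, coupling signs) but not
taxon–taxon covariance, zero inflation, overdispersion families, or
sequencing-depth artifacts of real 16S data. Calibration results (FDR
behavior of the screen, PERMANOVA p uniformity) transfer to real data only
to the extent that exchangeability under the null holds there too; recovery
rates are specific to the planted gamma model.

## Benchmark problem sizes

The test suite and acceptance script use: 500 null studies at 999
permutations for PERMANOVA uniformity (KS at 1%), a 6-sample design for
exhaustive-vs-Monte-Carlo permutation agreement (99,999 draws, 3 SE), 200
null studies of 50 taxa for indicator-count calibration, 100 replicates per
coding for planted-model recovery, and 100 seeded studies for correlation
sign recovery. These sizes give binomial/KS resolution well below the
gates they check.
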