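# Methods

`lupinest` implements the analysis chain for a multi-experiment early-establishment
study of *Lupinus* accession panels: (1) a long-duration scarification assay
quantifying physical seed dormancy, (2) a multi-soil trial scoring establishment on a
0–5 ordinal scale, and (3) a substrate-pH gradient assay of seedling organ growth,
synthesized into an Integrated Selection Index (ISI) and soil-matched accession
recommendations. This note records the models, the tunable parameters and their
defaults, the numerical choices, and what the bundled synthetic data can and cannot
show.

## Germination and physical dormancy (scarification assay)

Each trial is one accession × treatment Petri dish censused weekly up to a 365-day
horizon; censuses fall on days 7, 14, …, 364 (the last multiple of the census
interval inside the horizon). An event time is the census day on which a germination
is first observed — interval censoring is collapsed to the right endpoint, matching
the weekly scoring resolution, and no midpoint correction is applied.

Indices, all with **viable seeds** as the denominator (non-germinated seeds are
scarified at assay end to verify viability, so the viable count is known):

- **FGP** (final germination percentage) = 100 · germinated / viable.
- **PD** (physical dormancy, non-scarified trials only) = 100 − FGP(NS), the
  percentage of viable intact seeds kept from germinating by the impermeable coat.
  PD + FGP(NS) = 100 holds exactly by construction.
- **MGT** (mean germination time) = mean event day over germinated seeds; undefined
  (not an exception) when nothing germinated.
- **IVG**: the Maguire velocity index Σᵢ nᵢ/tᵢ over censuses (newly germinated count
  divided by census day). The canonical "rate and synchrony" index; chosen because
  the study-level definition of the velocity index leaves the formula open.
- **DDS₅₀**: first crossing of 50% of viable seeds on the cumulative curve, linearly
  interpolated between the bracketing censuses (from (day 0, count 0) when the first
  census already exceeds 50%). A curve that never crosses is **right-censored** at
  365 days and flagged, never assigned an arbitrary large number; censored values are
  excluded from correlation analyses but enter the dormancy classifier at the
  horizon value (the classifier needs a complete matrix, and "still under 50% at one
  year" is at least as dormant as any interpolated value).

Survival analysis uses the Kaplan–Meier product-limit estimator on days-to-
germination ("survival" = probability of remaining ungerminated) and the standard
log-rank chi-square for group comparisons (both via lifelines; each is cross-checked
in the test suite against a hand-computed product-limit table and null-calibration
simulations).

**Dormancy classification.** The study design names the inputs (FGP, MGT, DDS₅₀,
IVG under NS) but not an algorithm, so the rule here is an explicit, documented
choice: orient the four indices so larger = more dormant (MGT, DDS₅₀ as-is; FGP,
IVG negated), z-score with population SD, project onto the first principal axis
(sign fixed to correlate positively with the oriented-index mean), and cut the score
at its tertiles into *low < intermediate < high*. An all-identical panel degenerates
to everyone *low* (no evidence of differences). The classification is deterministic
given the metrics.

## Multi-soil ordinal establishment

The 0–5 score nests three binary outcomes: germination (≥ 1), cotyledon emergence
(≥ 3), establishment (= 5), so establishment rate ≤ cotyledon rate ≤ germination
rate for every grouping — an invariant the tests enforce on every simulated panel.
Score 4 (arrested growth or fungal damage) counts toward germination and cotyledon
emergence but never establishment: it is a failure mode, not a developmental stage,
and the thresholds force this reading.

Proportions carry **Wilson score 95% intervals** — boundary-safe at 0/5 and 5/5,
which matters at the design's n = 5 seeds per dish. The accession × soil
establishment matrix averages the two scarification treatments with equal weight;
missing cells stay missing.

**Model approximation.** A binomial GLMM with accession random intercepts is out of
scope here; species × soil + scarification effects are estimated by fixed-effects
logistic regression (IRLS maximum likelihood via statsmodels GLM), with accession-
level variation handled by direct per-accession aggregation. Coefficient tables
carry this note in their metadata. Complete separation raises a diagnostic error
rather than returning a divergent estimate (detected by non-convergence or
|log-odds| > 15); rank-deficient designs report the aliased terms.

The dormancy-vs-establishment screen computes per-soil Pearson r with Fisher-z 95%
intervals; accessions with censored DDS₅₀ are excluded and counted, not imputed.

## pH × time seedling growth

Per-seedling traits: total length = hypocotyl + epicotyl (mm); stabilized ratio
H/(E+1) (the 1 mm constant keeps seedlings with measured but non-elongated epicotyls
finite); allocation H/total (defined as 0 for a degenerate 0 mm seedling); binary
establishment total ≥ 30 mm, threshold inclusive. Seedlings lacking either organ
measurement are retained with context but flagged invalid and excluded from growth
and allocation analyses; exclusion counts are reported per pH × DAS stratum.

- **Two-way ANOVA** (pH × DAS with interaction) uses type-II sums of squares
  (statsmodels OLS + anova_lm); balanced designs make the SS types coincide. Empty
  cells raise an error naming the cell. The tests verify the table against a
  nested-least-squares oracle to 1e-10 and its type-I error by simulation.
- **Pairwise contrasts** use a seeded **permutation max-|t|** family-wise
  adjustment: pooled-variance t statistics for all pairs, null distribution of the
  maximum |t| over label permutations, add-one p-values. This replaces the
  studentized-range (Tukey HSD) reference distribution while preserving family-wise
  control (verified ≤ 0.07 at nominal 0.05 over 500 null simulations); with two
  groups it reduces to the plain permutation test. A Dunnett-style comparison is not
  provided — the factorial design has no control group.
- **Polynomial pH response** fits least squares on centered pH; with three design
  levels the default quadratic is saturated on the level means and is flagged
  `saturated` (interpolation, not prediction).
- **Allocation regression** clamps allocation to [0.005, 0.995] before the logit
  (boundary handling is otherwise unspecified) and runs OLS on the stated
  predictors.

## Integration and the ISI

Accession-level traits are z-scored (population SD; constant columns dropped with a
warning) before PCA and clustering. PCA is the SVD of the standardized matrix with
each loading column's sign fixed so its largest-magnitude entry is positive;
variance shares always sum to 100% and all components are emitted (any cutoff is a
reporting choice). Clustering is Ward.D2 agglomeration on Euclidean distances
(scipy's `ward` linkage implements exactly this update; verified against an
exhaustive merge-cost oracle at n = 6), with silhouette cohesion at the chosen k.
The cluster count k is an input (default 5), not re-derived. Node robustness is
**ordinary bootstrap co-clustering support**: the fraction of row resamples in which
a node's (unique, resampled) leaf set reappears intact as a node of the resampled
tree. This deliberately replaces multiscale-bootstrap AU p-values and is named
accordingly.

Pairwise trait associations use Spearman's ρ on midranks with percentile-bootstrap
95% intervals and Benjamini–Hochberg q-values over all tested pairs; constant traits
are skipped with an undefined marker.

**ISI.** At 14 days after sowing, using only pH 5.5 and 7.0 (alkaline 8.5 is
excluded from all three components to avoid bias from inhibitory conditions):
establishment component = mean establishment proportion across the two pH levels;
growth component = mean total length (mm); stability = 1/(|est(7.0) − est(5.5)| + 1).
Establishment enters the stability formula as a proportion in [0, 1], so stability
∈ (0.5, 1]; had percentages been intended, the subsequent min-max rescaling absorbs
the difference. Each component is min-max rescaled to [0, 1] across accessions
(jointly over the whole panel, not within species; a constant component maps to a
neutral 0.5), and the ISI is the unweighted mean — hence invariant to any common
affine rescaling of a raw component and monotone in each. Ranks are dense, ties
broken lexicographically by accession id, accessions missing a pH level excluded
with a warning.

**Recommendations.** For each soil: accessions in the top-n of both the soil
establishment ranking and the pH-performance (ISI) ranking come first, ordered by
soil rank and flagged `overlap`; the list is completed from the soil ranking with
`fill` entries until n accessions are listed.

## Synthetic data: what it emulates

No raw data ship with the package; the generators reproduce the statistical
structure of the three designs so every downstream stage is testable. All draws come
from per-experiment numpy Generators seeded `default_rng([seed, stream_id])`
(streams 1/2/3), with the documented nested-loop draw order — identical seeds give
byte-identical outputs across runs.

- **Germination (cure-fraction process).** Panel of 16 accessions × 5 seeds per
  treatment. Under NS each seed is dormant with the accession's π_d; the default
  profile (twelve accessions at 0–0.1, two at 0.4–0.5, two at 0.85–0.95) mirrors a
  panel in which four accessions show measurable dormancy. Permeable seeds draw a
  gamma(4, 3) germination time (mean 12 d); scarification zeroes π_d and multiplies
  the scale by 0.6 (mean ≈ 7 d, i.e. germination within ~20 days). Dormant seeds
  release with a per-census geometric hazard (default 0.002/week, so most stay
  dormant through the year). Events snap to the next census day and truncate at the
  horizon.
- **Soil trial (ordered logit).** 48 accessions (16 per species) × 5 soils × 2
  treatments × 3 blocks × 5 seeds. Latent η = μ(species, soil) + accession intercept
  (SD 0.5) + 1.0·1[scarified] + standard logistic noise, cut at (−2, −1, 0, 1, 2).
  The default μ surface makes MBG3/COPMO permissive, BV restrictive, and MEC
  species-dependent — the qualitative soil ordering of the study — but the exact
  values are fixture choices, not estimates.
- **pH assay (truncated-normal growth).** 48 accessions × 3 pH × 2 DAS × 3
  replicates × 5 seeds. Organ means put the DAS7→DAS14 total-length gain at 26 mm,
  peak hypocotyl growth at pH 7.0, and strong epicotyl inhibition at pH 8.5 by day
  14; residual SD 6 mm per organ, left-truncated at 0. Each organ is independently
  missing with p = 0.1, so ≈ 19% of seedlings lack at least one organ — the same
  order as the study's exclusions (~20%).

What passing tests on these fixtures **do not** show: recovery of the study's
numerical results (its raw data are not deposited, so headline odds ratios,
F-values, PCA percentages and silhouette values are out of numeric scope); real
seed-lot maternal effects, soil microbiota, temperature/moisture dormancy cues, or
correlated organ measurement error (organs and their missingness are simulated
independently). The generators demonstrate that the estimators recover known inputs
— dormant fraction via PD, scarification effect sign, DAS contrasts, constructed
dormancy classes — under the stated designs.

## Problem sizes and runtime choices

Defaults used by the test suite and the acceptance script: type-I calibration of the
log-rank test and the two-way ANOVA at 1000 null replicates (two groups of 30;
3 × 2 × 4 layout), family-wise calibration of the max-|t| adjustment at 500 null
simulations × 199 permutations, dormant-fraction recovery at 1000 seeds, DAS-effect
power at 100 replicates of a 3-accession panel, and pipeline bootstraps at 100
resamples. These sizes give Monte-Carlo error comfortably inside the asserted bands
while keeping a full run in the low minutes on one core.

## Known limitations

- Fixed-effects logistic + aggregation approximates, but does not estimate, the
  accession random-intercept GLMM; predicted probabilities that marginalize over
  random effects are not reproduced.
- Bootstrap co-clustering support is not an AU p-value and is generally more
  conservative for shallow nodes.
- The permutation max-|t| adjustment is exchangeability-based; under strong variance
  heterogeneity between groups its family-wise control is approximate.
- DDS₅₀ at the horizon for classification is a pragmatic completion; with many
  censored accessions the tertile cuts degenerate toward the censoring value.
- The Ca-based soil cation ratios are stored as reported and cannot be recomputed
  (Ca concentration is not part of the profile); one printed Mg/K value (soil MEC)
  disagrees with the charge-equivalent computation by 0.1 at one decimal, consistent
  with source rounding.
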