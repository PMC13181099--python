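# lupinest

Early-establishment analytics for *Lupinus* accession panels: physical seed
dormancy from long-duration germination censuses, ordinal establishment outcomes
across contrasting soils, pH × time seedling growth, and an Integrated Selection
Index (ISI) with soil-matched accession recommendations.

## Who it is for

Breeders and seed physiologists screening legume germplasm (e.g. *L. albus*,
*L. angustifolius*, *L. luteus* cover-crop candidates) for three partially
independent filters of establishment success: seed-coat dormancy, soil
physicochemical tolerance, and substrate-pH response. The package takes tidy CSVs
of the three experiment layouts and produces per-accession metrics, fitted models,
multivariate summaries, and ranked recommendations. A seeded synthetic-data module
emulates all three designs, so the whole chain runs and is testable without any
external data.

## The statistics at the core

- **Physical dormancy**: PD = 100 − FGP_NS (final germination % of viable,
  non-scarified seeds), with MGT, the Maguire velocity index IVG = Σ nᵢ/tᵢ, and
  DDS₅₀ (days to 50% cumulative germination, interpolated, right-censored at 365 d
  when never reached). Germination dynamics are compared with Kaplan–Meier curves
  and log-rank tests; accessions are classified low/intermediate/high dormancy by
  tertiles of a principal-axis score over the four NS indices.
- **Soil establishment**: the 0–5 ordinal score nests germination (≥1), cotyledon
  emergence (≥3), and establishment (=5); rates carry Wilson 95% intervals, and
  species × soil + scarification effects are estimated by fixed-effects logistic
  regression (a documented approximation to the random-intercept GLMM).
- **pH growth**: per-seedling total length, H/(E+1) ratio, allocation H/total and
  establishment (≥ 30 mm); two-way pH × DAS ANOVA (type-II SS), permutation
  max-|t| family-wise contrasts, polynomial pH response, logit-allocation OLS.
- **Integration**: z-scores → PCA and Ward.D2 clustering with silhouette and
  bootstrap co-clustering support; Spearman screen with bootstrap CIs and
  Benjamini–Hochberg FDR; and the ISI at 14 days after sowing,

      ISI = mean of min-max-rescaled { mean establishment (pH 5.5, 7.0),
                                       mean total length (pH 5.5, 7.0),
                                       1 / (|est(7.0) − est(5.5)| + 1) },

  with alkaline pH 8.5 excluded from all components. Soil chemistry helpers
  include the charge-equivalent cation ratio Mg/K = (Mg/12.153)/(K/39.098).

See `docs/methods.md` for models, defaults, numerical choices, and limitations.

## Worked example

Simulate the three experiments at a fixed seed and compute dormancy metrics:

```python
from lupinest import synthetic_data as synth, germination as germ

cfg = synth.SimulationConfig(rng_seed=1)
trials = synth.simulate_germination(cfg)
metrics = germ.metrics_table(trials)
ns = metrics[metrics.treatment == "NS"]
classes = germ.classify_dormancy(ns)
lr = germ.logrank_test(germ.trial_groups_for_logrank(trials))
```

For three representative accessions this prints:

```
accession_id treatment   fgp  mgt   ivg   dds50   pd dormancy_class
      ANG-01        NS 100.0 16.8 0.310  12.833  0.0   intermediate
      ANG-13        NS  40.0 21.0 0.095 365.000 60.0           high
      ANG-13         S 100.0  8.4 0.643   4.375  NaN           high
      ANG-15        NS  20.0  7.0 0.143 365.000 80.0           high
log-rank chi2=46.07 df=1 p=1.14e-11
```

ANG-13 germinates to only 40% intact (PD = 60%, DDS₅₀ censored at 365 d) but
completely and quickly once scarified — the signature of physical dormancy — and
the log-rank test rejects equality of the NS and S time-to-germination curves.
Downstream, the pH experiment yields the ISI ranking:

```python
from lupinest import growth_ph as gph, integration as integ
valid, excluded = gph.filter_valid(synth.simulate_ph_experiment(cfg))
isi = integ.compute_isi(gph.ph_summary(valid, das=14))
```

```
accession_id  est_mean  length_mean stability    isi  rank
      ALB-08     1.000       43.531     1.000  0.935     1
      ALB-06     0.917       45.001     0.968  0.875     2
      ALB-16     0.950       44.606     0.909  0.836     3
```

ALB-08 ranks first: complete establishment at both non-limiting pH levels
(stability 1.0) with near-maximal seedling length. The `excluded` table counts the
787/4320 seedlings dropped for a missing organ measurement.

The same chain runs end to end from a shell:

```bash
lupinest run --seed 1 --outdir run_out     # simulate -> metrics -> models -> ISI
lupinest simulate --seed 1 --outdir data   # just the four CSVs
lupinest germ-metrics data/sim_germination.csv --outdir out
```

`run` writes per-stage CSVs plus `run_manifest.json` (config digest, seeds, paths,
row counts, warnings); identical config and seed give byte-identical outputs.

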