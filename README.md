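# hoppertraits

Trait-based analysis of insect herbivore community assembly and
feeding-niche differentiation, built around grasshopper (Acrididae)
functional traits. The package answers two linked questions that community
ecologists ask of such systems:

1. **Are co-occurring species more or less similar in their traits than
   chance predicts?** Trait clustering (under-dispersion) is the classical
   signature of environmental filtering; over-dispersion points to limiting
   similarity / competition.
2. **Do consumer traits predict the traits of the plants they prefer to
   eat?** Such "trait matching" (e.g. strong mandibles ↔ tough, high-LDMC
   leaves) identifies functional linkages between trophic levels.

## What it computes

* **Trait equations** per specimen: body volume `V = (π/4)·L·D²`, the
  mandible lever index of bite force `F_in·L_in/(L_out·R_i)`, and the C:N
  mass ratio; species means, pairwise Pearson correlations (log scales for
  volume and bite force) and a correlation-matrix PCA.
* **Functional dispersion**: Rao's quadratic entropy
  `Q = Σ_i Σ_j p_i p_j d_ij` per community row on Gower trait distances,
  with a trait-shuffling permutation null (999 replicates) and standardized
  effect sizes `SES = (Q_obs − μ_null)/σ_null`, per trait set ("all
  traits", each single trait, and subfamily as a phylogenetic proxy),
  summarised with one-sample t-tests against zero.
* **Feeding niches** from cafeteria assays: consumption-weighted mean plant
  traits `CWM = Σ p_i·trait_i` per individual, species/subfamily niche
  summaries, and permutation F-tests of diet differentiation.
* **Trait matching**: OLS of individual CWMs on species-mean herbivore
  traits with subfamily fixed intercepts, for the three hypothesised
  linkages (incisor strength↔LDMC, consumer C:N↔plant C:N, body
  volume↔plant C:N).
* **Synthetic data** for all of the above — correlated trait syndromes,
  communities assembled under neutral / filtering / limiting-similarity
  rules, plant pools with the LDMC–SLA trade-off, and consumption matrices
  driven by a known trait-matching kernel — so every stage is testable with
  known ground truth. See `docs/methods.md` for models and defaults.

## Worked example

Run the full pipeline on a simulated filtered landscape (30 sites × 2
periods, 14 species in 4 subfamilies, 16 plants, 12 cafeteria replicates
per species):

```sh
hoppertraits all --outdir demo --seed 42 \
  --config <(echo "assembly_mode: filtering")
```

or in Python:

```python
from hoppertraits.pipeline import PipelineConfig, run_pipeline
run_pipeline(PipelineConfig(outdir="demo", seed=42, assembly_mode="filtering"))
```

`demo/ses_summary.csv` then contains:

```
       trait_set  n  mean_ses  se_ses       t  p_value
             all 60    -1.273   0.090 -14.185    0.000
     body_volume 60    -1.429   0.090 -15.968    0.000
        cn_ratio 60    -0.910   0.098  -9.298    0.000
incisor_strength 60    -1.114   0.128  -8.703    0.000
       subfamily 60     0.054   0.125   0.429    0.669
```

Every numeric trait shows strongly negative SES — the communities are
trait-clustered, as expected under the filtering assembly rule — while
subfamily sits at zero because the simulated subfamilies carry no trait
signal. `demo/trait_matching.csv` shows the recovered trophic linkages:

```
 herbivore_trait plant_trait    slope  p_value     r2
incisor_strength        ldmc  79.9641      0.0 0.9145
        cn_ratio    cn_ratio -10.2649      0.0 0.8608
     body_volume    cn_ratio  10.0180      0.0 0.9179
```

Strong-mandibled species eat tougher (higher-LDMC) diets; low-C:N (nutrient
rich) species eat high-C:N plants. `demo/pca_summary.csv` shows the trait
syndrome: PC1 carries 86.4% of the variance with body volume and incisor
strength loading together against C:N.

Stages can also be run separately (`simulate`, `traits`, `dispersion`,
`niche`, `match`); each writes CSVs into `--outdir` plus a `manifest.json`
of content hashes, and a fixed seed reproduces every file byte-for-byte.

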