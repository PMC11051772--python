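# mixoniche

Trophic-niche analysis of small (pico/nano-sized) marine eukaryotes from 18S
rRNA metabarcoding surveys and grazer–prey culture experiments.

Many small flagellated eukaryotes are constitutive mixotrophs: they carry
their own chloroplasts *and* ingest bacterial prey, competing with strict
autotrophs for nutrients and light and with strict heterotrophs for prey.
`mixoniche` implements the quantitative workflow for asking where, along
ocean environmental gradients, mixotrophy pays off:

1. **Copy-number correction.** 18S rRNA gene counts over-represent taxa with
   many gene copies per cell (dinoflagellates above all). Per group
   g ∈ {dinoflagellate, diatom, other}, a line
   `copies = a_g + b_g · biovolume` is fit to empirical calibration data and
   evaluated at a reference biovolume V_ref = 65 µm³ to give a correction
   factor C.F._g; cell abundances are `genes / C.F._g`. The shipped default
   map is {59.3, 10.5, 4.7}; an independently published alternative
   ({27.1, 4.4, 0.9}, Martin et al. 2022) is available as the
   `martin2022` preset for sensitivity analysis.
2. **Trophic annotation.** Each lineage is looked up in an annotation
   database at species, then genus, then family rank and labelled
   M (mixotroph), A (autotroph), H (heterotroph) or unknown, after excluding
   groups dominated by large or parasitic taxa (Ciliophora, Radiolaria,
   Foraminifera; Fungi, Amoebozoa, Syndiniales, unresolved eukaryotes).
3. **Trophic indices.** Per sample, TI_g = (abundance of group g) / T with
   T the total retained community, i.e. TI_M = M/T, TI_A = A/T, TI_H = H/T.
4. **Niche statistics.** PCA of a 29-variable environmental table
   (mean-imputed, log10-transformed), penalized-spline smoothers of TI over
   PC axes with 95% bands, single-variable and AIC-stepwise regressions,
   and redundancy analysis (RDA) of the Hellinger-transformed community on
   environmental variables screened by permutation tests and variance
   inflation factors, after Escoufier equivalent-vectors species selection.
5. **Culture kinetics.** From batch cultures sampled every 12–24 h:
   maximal exponential growth rate (steepest window slope of ln cells vs
   time), per-interval ingestion I = ΔP / (Δt · Ḡ), clearance C = I / P̄
   (and per grazer body volume, C · 10¹² / V), averaged over pre-stationary
   intervals, with optional grazer-free-control correction; one-way and
   main-effects ANOVA across light/nutrient/species treatments.
6. **Synthetic data.** A generator producing surveys and cultures with
   known ground truth — latitudinal bands of PAR, nitrate+nitrite and
   bacterial abundance; a logistic response of TI_M to standardized
   log-gradients; group-specific gene-copy inflation; multinomial
   sequencing depth; and an integrated grazer–prey ODE — so every stage is
   testable without downloads.

## Worked example

```python
import numpy as np
import mixoniche as mx

# a synthetic survey: 104 surface stations, 61 with a paired
# chlorophyll-maximum-layer (CML) sample
sim = mx.simulate_community(mx.CommunitySimConfig(n_stations=104, cml_stations=61), seed=1)
cells = mx.gene_to_cell(sim.abundance, sim.taxonomy, sim.config.cf_map)
modes = mx.assign_modes(sim.taxonomy, sim.annotation_db)
ti = mx.compute_ti(cells, modes)

layer = mx.compare_layers(ti, sim.env, "TI_M")
print(f"TI_M median SUR {layer.median_sur:.2f} vs CML {layer.median_cml:.2f} "
      f"(t={layer.statistic:.1f}, p={layer.p_value:.2g}, df={layer.df})")

env = sim.env.variable_frame()
r = mx.regress_ti(ti["TI_M"].to_numpy(), env["no3_no2"].to_numpy(),
                  predictor_name="log10_N", log_transform=True)
print(f"TI_M ~ log10(NO3+NO2): slope {r.slope('log10_N'):.3f}, "
      f"p = {r.p_value('log10_N'):.2g}, R^2 = {r.r_squared:.2f}")

culture = mx.simulate_culture(mx.CultureSimConfig(noise_cv=0.1, replicates=3), seed=1)
rates = [mx.grazing_rates(rep) for rep in culture.replicates]
print(f"mu_max = {np.mean([x.mu_max for x in rates]):.3f} h^-1, "
      f"clearance = {np.mean([x.mean_clearance_ml for x in rates]):.2e} mL grazer^-1 h^-1")
```

prints

```
TI_M median SUR 0.44 vs CML 0.10 (t=15.3, p=2.6e-22, df=60)
TI_M ~ log10(NO3+NO2): slope -0.202, p = 1.4e-34, R^2 = 0.60
mu_max = 0.045 h^-1, clearance = 1.81e-06 mL grazer^-1 h^-1
```

Mixotrophs dominate the bright, nutrient-poor surface relative to the CML
(the paired t-test runs on within-station surface-minus-CML differences);
their index falls as nitrate+nitrite rises; and the culture estimator
recovers the generator's true clearance rate (2×10⁻⁶ mL grazer⁻¹ h⁻¹) and
growth rate (0.04 h⁻¹) from noisy 12-hourly counts.

A thin CLI mirrors the batch steps:

```sh
mixoniche simulate community --seed 3 --out demo/
mixoniche correct --abundance demo/abundance_gene.tsv --taxonomy demo/taxonomy.tsv --out demo/cells.tsv
mixoniche ti --abundance demo/abundance_gene.tsv --taxonomy demo/taxonomy.tsv \
    --annotations demo/annotations.tsv --out demo/ti.csv
mixoniche kinetics --input demo/culture.csv --out demo/rates.csv
```

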