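# Methods

`limnoch4` implements the analysis chain that links the temperature
sensitivity of ebullitive CH4 flux from post-glacial lake sediments to the
sediment microbiota and porewater geochemistry underneath: Arrhenius analysis
of bubble-trap flux with homogeneity-of-regression tests between lake zones, a
stable-carbon-isotope mass balance that partitions "fugitive" CH4 by depth,
community-ecology statistics (rarefaction, Bray–Curtis, PCoA, PERMANOVA,
Mantel, functional-guild abundances, qPCR absolute quantification), and
PLSR/MLR models that predict porewater CH4 from abiotic and microbial
variables.  A synthetic-data module generates every input with the statistical
structure the analyses assume, so the whole chain is testable offline.

## Flux thermal sensitivity

Bubble-trap records (flux in mg CH4 m⁻² d⁻¹ against surface-sediment
temperature) are binned in fixed-width temperature intervals per
(lake, zone) group.  Bins are half-open and integer-anchored,
`[k·w, (k+1)·w)` with centers at `(k+0.5)·w` and default width 1 °C; the
convention is ours, since "1 °C intervals" does not pin the anchor.  Each
bin reports the record count, mean flux, and a Student-t 95% CI on the mean
(the CI estimator is likewise our choice); single-record bins are kept for
regression but flagged as degenerate.

Arrhenius fits regress ln(binned mean flux) on 1/T_K with ordinary least
squares, unweighted by default (binned means are the unit of analysis; a
count-weighted variant is available via `weighted=True`).  The apparent
activation energy is −slope·R.  Homogeneity of regression between two groups
is tested by pooling their binned points and fitting
`ln(flux) ~ group + 1/T + group×(1/T)`; the p-value is the F-test of the
interaction term (for a pairwise contrast this equals the squared-t test).
"Temperature interval" enters the interaction model as continuous 1/T_K,
consistent with the Arrhenius framework.  Three robustness subsets are
supported for edge-vs-middle pairs: trimming edge bins hotter than the
hottest middle bin, and dropping the hottest or coldest middle bin.  Both
binned-mean (default) and raw-record regressions are conceivable; the binned
form is implemented because the Arrhenius construction is explicitly defined
on binned data.

Incubation rates are the OLS slope of headspace CH4 against time divided by
sediment dry mass; negative slopes are reported as-is with a flag, and group
contrasts use one-way ANOVA.

## Isotope mass balance ("fugitive" CH4)

Assumptions: fermentation and respiration generate CO2 without fractionating
carbon; methanogenesis generates CH4 and CO2 1:1 with strong fractionation;
DIC stays dissolved while CH4 escapes (dominantly by ebullition); the system
is at steady state; the substrate's isotopic composition equals that of bulk
sedimentary organic carbon (acetate-pool fractionation is ignored for lack of
measurements).  With δ values in ‰ VPDB:

* fractionation factor `α = (δ13C_TOC + 1000) / (δ13C_CH4 + 1000)`;
* methanogenic CO2 endmember `δ13C_CO2meth = 2·δ13C_TOC − δ13C_CH4`
  (1:1 mass balance on the substrate);
* methanogenic fraction of DIC
  `f = (δ13C_DIC − δ13C_TOC) / (δ13C_CO2meth − δ13C_TOC)`,
  a two-endmember mixing coordinate;
* generated CH4 = `f · DIC`; fugitive CH4 = generated − measured.

This is the minimal two-endmember formulation satisfying every stated
assumption.  A Rayleigh-distillation closure would alter the endmember
equations; they are isolated in `fugitive_ch4` so a variant can be
substituted.  `f` is clipped to [0, 1] with a flag (field noise can push it
slightly out) and the raw value retained; negative fugitive CH4 is flagged,
not clipped, because a steady-state violation is diagnostic information.
δ13C_CH4 = δ13C_TOC makes `f` undefined and returns a flagged missing result.

The apparent fractionation `αC = (δ13C_DIC + 1000)/(δ13C_CH4 + 1000)`
classifies the dominant methanogenic pathway: ≥ 1.065 hydrogenotrophic,
≤ 1.055 acetoclastic, otherwise intermediate.  The thresholds follow the
classical genetic-zonation convention and are configurable, as no single
boundary is universal.

## Community statistics

Counts are rarefied to 3000 reads per sample by exact subsampling without
replacement (`Generator.multivariate_hypergeometric`), one recorded-seed draw
per table; samples below depth are dropped with a warning.  Replicate pairs
are averaged per OTU (groups larger than two are rejected — the design ran
duplicates at most).  Bray–Curtis dissimilarity is computed on square-root
transformed counts.  PCoA Gower-centers −D²/2 and eigendecomposes; negative
eigenvalues (non-Euclidean distances) are reported without Lingoes/Cailliez
correction, and coordinates are scaled by √eigenvalue.

PERMANOVA is the one-way pseudo-F from the total-minus-within partition of
squared distances, with `p = (1 + #{F* ≥ F}) / (1 + n_perm)` under label
permutation (999 by default) and an exhaustive-enumeration mode for small
designs.  The Mantel test Spearman-correlates the condensed entries of two
distance matrices and permutes rows/columns of one of them.  Both are
implemented here (the exhaustive mode is not exposed by library equivalents);
scikit-bio's implementations serve as independent cross-checks in the tests.

Functional guilds (methanogens, ANME, aerobic methanotrophs, Syntrophaceae)
are resolved by case-insensitive substring matching of editable patterns
against taxonomy lineage strings, shipped as a YAML-editable default seeded
from well-known clade names; a taxon may belong to at most one guild.
Edge-vs-middle contrasts report both the two-tailed t-test and one-way ANOVA
(equal for two groups, F = t²).

qPCR copies per gram derive from an OLS standard curve of Ct on
log10(copies/µL), where a dilution `d` of the genomic standard carries
`d · 20 ng/µL / (4,686,137 bp · 650 g mol⁻¹ bp⁻¹ / N_A) × 7` gene copies
per µL; samples are interpolated, then scaled by template dilution and
extraction yield (elution volume / wet mass).  Out-of-range samples are
flagged as extrapolated.  Guild relative abundance × total copies gives a
proxy absolute abundance.

## CH4 prediction (PLSR with VIP, MLR)

The explanatory matrix contains an abiotic block (depth, TOC, δ13C_TOC, DIC,
S, TOC:TS — CH4-related measurements are excluded as confounders), every OTU
strictly above 1% relative abundance in any sample, lineage sums (phylum
level, with a class-level override list defaulting to Proteobacteria),
configured MAG-lineage proxies (a directly mapped OTU or a lineage-pattern
sum), and guild sums.  Identical columns are collapsed with a warning;
missing chemistry cells are imputed by within-core linear interpolation over
depth.

PLSR is the NIPALS PLS1 algorithm on autoscaled columns (centering always;
unit-variance scaling by default, switchable), written as a scikit-learn
estimator.  The number of latent components defaults to the leave-one-out
minimum-PRESS choice, overridable with an integer.  The headline r² is the
squared Pearson correlation of fitted vs measured response (calibration), and

    VIP_j = sqrt( p · Σ_a SSY_a (w_ja / ‖w_a‖)² / Σ_a SSY_a )

with SSY_a the response sum of squares captured by component a; mean squared
VIP is 1 by construction, and variables with VIP strictly above 1 form the
significant set (the strict inequality is used for counting; the boundary
case VIP = 1 is thereby excluded).  MLR is OLS with r², adjusted r², and the
overall F-test; rank-deficient designs are rejected naming the collinear
columns.  Suites of variables (abiotic, abiotic+guilds, …) are compared by
PLSR r² and, where n > p + 1, MLR adjusted r².

## Synthetic study conditions

The generator emulates two lakes × two zones.  Defaults, chosen once as
field-realistic conditions:

* **Flux** — 5 traps per lake-zone × 150 observations; temperature uniform on
  4–22 °C (edge) / 4–14 °C (middle, colder at depth); ln flux =
  lnA + slope/T_K with slope −6000 K (edge) and −20000 K (middle, ≈3.3-fold
  steeper, inside the 3–5-fold range the field contrast motivates), lnA 23
  and 71 so fluxes land around 1–50 mg m⁻² d⁻¹; multiplicative lognormal
  noise, sdlog 0.8 (ebullition is strongly right-skewed).
* **Chemistry** — 4 cores on a 4–40 cm grid (10 depths); δ13C_TOC −28 ‰
  (±0.3 ‰ between samples), true α 1.060; the methanogenic DIC fraction rises
  linearly with depth from 0.25 and is 1.5× higher in middles; DIC rises
  800→3000 µM with 5% lognormal noise (the noise also prevents DIC from being
  an exact linear function of depth, which would make regression designs
  singular); 30% of generated CH4 is retained in porewater.  Isotope
  measurement noise defaults to zero so the forward model is exactly
  invertible; it is configurable.
* **Community** — 160 OTUs, library size 5000, samples at 21 core-depths
  (6+5+5+5, matching the field design's n = 21).  Guild mean relative
  abundances: methanogens 0.7% (edge) / 2.0% (middle), Syntrophaceae
  1.0%/2.0%, ANME 0.3%/0.03% (an order of magnitude higher in edges), aerobic
  methanotrophs 0.5% confined above 6 cm.  Background OTUs carry lognormal
  zone effects (sdlog 0.4) and log-linear depth gradients, making depth the
  dominant compositional axis.  Counts are Dirichlet-multinomial; the
  `overdispersion` parameter is the inverse of the total Dirichlet
  concentration, default 0.002 (weak): substantially stronger values make the
  community noise swamp the configured guild contrasts.
* **Coupling** — a latent lognormal "methanogenic activity" factor per
  (core, depth) (sdlog 0.35, its own stream) multiplies both the
  methanogen/syntroph guild means and the methanogenic DIC fraction, so
  microbial abundances carry information about porewater CH4 beyond the
  abiotic depth profiles.  Zone is deliberately absent from the abiotic
  variable set, so the zone-linked part of this signal is only accessible to
  biotic variables.
* **qPCR** — 10⁹ copies/g at the surface declining 0.025 log10 units per cm;
  100% amplification efficiency (Ct slope −3.32 per decade); Ct noise 0 by
  default, configurable.

Every artifact draws from its own random stream derived from the master seed,
so artifacts are independently reproducible; the trap-to-trap variance within
a zone is exposed as configuration rather than asserted, since no field value
is available for it.

### What the generator does *not* emulate

Raw sequencing reads and their processing; bubble physics and pressure
transients; phylogenetic correlation among OTUs; compositional covariance
beyond the Dirichlet; seasonal and interannual structure in flux; diffusive
isotope transport corrections.  Passing tests therefore show that the
*analysis chain* is correct and well calibrated under its own assumptions,
not that those assumptions hold in any particular lake.

## Numerical choices and degenerate inputs

Bins with non-positive mean flux are dropped (ln undefined) and fewer than
three usable bins aborts a fit; subsetting a group below three bins skips the
comparison with a warning.  Zero-variance columns are dropped before PLSR
scaling; a zero-variance condensed distance vector yields a flagged null
Mantel result rather than an error.  Permutation p-values use the
add-one convention except in exhaustive mode, where the identity relabeling
is included in both numerator and denominator.  PCoA eigenvalues below
`max(λ)·1e-12` are treated as null axes.  Ties in the LOO-PRESS component
search resolve toward fewer components.

## Problem sizes in tests

Null calibrations use 500 simulations (homogeneity type-I at two groups ×
1000 records; PERMANOVA type-I at n = 12 with 199 permutations per table);
power and effect-direction checks use 50–60 seeds at the default study
conditions; exhaustive enumerations run at n = 5–8 where the permutation
space is complete (20–40320 relabelings).  These sizes give binomial
standard errors comfortably inside the asserted bands.

## Known limitations

The isotope model's two endmembers are fixed by the stated assumptions; real
systems with substantial anaerobic CH4 oxidation or acetate-pool
fractionation violate them and bias f upward or downward.  Calibration r² on
n = 21 with PRESS-selected components remains optimistic relative to
cross-validated r² (which `press_` exposes).  Guild pattern matching is
lexical, not phylogenetic.  The 2014-isotopes/2012-concentrations depth
matching of the field campaign is handled by generating consistent depths;
for file-driven runs the chemistry table must already be depth-matched.
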