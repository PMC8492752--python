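# limnoch4

Northern post-glacial lakes vent microbially produced methane to the
atmosphere mostly by ebullition — bubbles that rise from the sediment and
bypass water-column oxidation.  Ebullitive CH4 flux tracks surface-sediment
temperature, but the *slope* of that relationship can differ between the
shallow littoral edge of a lake and its deeper pelagic middle, with direct
consequences for emission forecasts in a warming Arctic.  `limnoch4` is a
pipeline for asking why: it quantifies the spatial contrast in temperature
sensitivity and links it to the sediment microbiota and porewater
geochemistry underneath.  It is aimed at biogeochemists and microbial
ecologists working with bubble-trap flux records, sediment-core porewater
chemistry, 16S rRNA amplicon OTU tables, and qPCR plates.

## What it computes

**Temperature sensitivity.**  Flux records are binned in 1 °C intervals of
surface-sediment temperature per (lake, zone) group, and each group's binned
means feed an Arrhenius regression,

    ln F = ln A + s · (1/T_K),      E_a = −s · R,

with homogeneity of regression between groups tested by the F-test of the
`group × 1/T` interaction on pooled binned points (plus robustness subsets
that trim hot edge bins or drop extreme middle bins).

**Fugitive CH4 from stable isotopes.**  Methanogenesis makes CH4 and CO2 1:1
and fractionates carbon; fermentation/respiration make CO2 without
fractionating; DIC stays in porewater while CH4 escapes.  From δ13C of
organic carbon, CH4, and DIC, the model computes the fractionation factor
α = (δ_TOC+1000)/(δ_CH4+1000), the methanogenic CO2 endmember
δ_CO2meth = 2·δ_TOC − δ_CH4, the fraction of DIC from methanogenesis
f = (δ_DIC − δ_TOC)/(δ_CO2meth − δ_TOC), and fugitive CH4 = f·DIC − measured
CH4 per depth.  The apparent fractionation αC between DIC and CH4 classifies
the dominant methanogenic pathway (hydrogenotrophic vs acetoclastic).

**Community structure.**  Rarefaction to 3000 reads, replicate averaging,
square-root Bray–Curtis, PCoA, one-way PERMANOVA (with an exact
enumeration mode), Spearman Mantel tests, functional-guild relative
abundances (methanogens, ANME, aerobic methanotrophs, Syntrophaceae) from an
editable taxonomy-pattern map, and absolute abundances from qPCR standard
curves.

**CH4 prediction.**  A NIPALS partial least squares regression with
variance-in-projection (VIP) scores — built as a scikit-learn estimator —
and multiple linear regression predict porewater CH4 from variable suites
(abiotic only; abiotic plus CH4-cycler guilds; everything), where
VIP_j = sqrt(p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a) and VIP > 1 marks a
significant predictor.

A synthetic-data module generates all inputs (flux records, core chemistry
via the forward isotope model, a Dirichlet-multinomial OTU table with
zone-enriched guilds, qPCR plates) so the entire chain runs and is tested
without any download.

## Worked example

```python
from limnoch4 import (SyntheticConfig, generate_flux_records,
                      generate_core_chemistry, generate_otu_table,
                      bin_flux, fit_arrhenius, fugitive_ch4, rarefy,
                      guild_abundance, braycurtis, permanova,
                      assemble_variables, compare_models)

cfg = SyntheticConfig(seed=42)
bins = bin_flux(generate_flux_records(cfg))
for (lake, zone), grp in bins.groupby(["lake", "zone"]):
    fit = fit_arrhenius(grp, group=(lake, zone))
    print(f"{lake} {zone:6s} slope = {fit.slope:9.0f} K   "
          f"Ea = {fit.apparent_Ea_kJ_mol:5.1f} kJ/mol   r2 = {fit.r2:.3f}")
```

    IH edge   slope =     -5358 K   Ea =  44.5 kJ/mol   r2 = 0.877
    IH middle slope =    -18287 K   Ea = 152.0 kJ/mol   r2 = 0.962
    MH edge   slope =     -5893 K   Ea =  49.0 kJ/mol   r2 = 0.917
    MH middle slope =    -19750 K   Ea = 164.2 kJ/mol   r2 = 0.985

Lake middles are ~3.3-fold more temperature-sensitive than edges (steeper
Arrhenius slope, higher apparent activation energy).  One depth's isotope
mass balance:

```python
res = fugitive_ch4(dict(depth_cm=10, d13C_TOC=-28, d13C_CH4=-80,
                        d13C_DIC=-2, DIC_uM=2000, CH4_uM=300))
print(f"f_meth = {res.f_meth:.2f}  generated = {res.generated_CH4_uM:.0f} uM  "
      f"fugitive = {res.fugitive_CH4_uM:.0f} uM  pathway = {res.pathway}")
```

    f_meth = 0.50  generated = 1000 uM  fugitive = 700 uM  pathway = hydrogenotrophic

Half the DIC at this depth came from methanogenesis, so 1000 µM of CH4 was
generated; only 300 µM remains in porewater, leaving 700 µM fugitive.  The
community and prediction stages:

```python
table = rarefy(generate_otu_table(cfg), depth=3000, seed=42)
perma = permanova(braycurtis(table), table.sample_meta["zone"], seed=42)
abund, tests = guild_abundance(table)
vm = assemble_variables(table, generate_core_chemistry(cfg))
out = compare_models(vm, suites={"abiotic": ("abiotic",),
                                 "abiotic+CH4 cyclers": ("abiotic", "guild_sum")})
print(out[["n_variables", "plsr_r2", "mlr_adj_r2"]].round(3))
```

    PERMANOVA edge vs middle: pseudo-F = 2.35, p = 0.014
    methanogen %: edge = 0.78, middle = 2.54 (ANOVA p = 0.0098)
                         n_variables  plsr_r2  mlr_adj_r2
    suite
    abiotic                        6    0.818       0.750
    abiotic+CH4 cyclers            9    0.866       0.767

Edge and middle communities differ significantly, methanogens are enriched in
the middles, and adding CH4-cycler abundances to the abiotic variables
improves the CH4 prediction — the same effect directions the pipeline is
designed to resolve in field data.

A full run (synthetic or file-driven) is also available from the shell:

```bash
limnoch4 demo --seed 42 --out demo_run        # all four stages + report.json
limnoch4 flux --records flux.csv --subset edge_trimmed --out flux.json
limnoch4 isotopes --chem chem.csv --out fugitive.csv
limnoch4 validate --flux flux.csv --chem chem.csv
```

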