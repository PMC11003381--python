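# aquatrial

Quantitative analysis of fishmeal-replacement feeding trials in
aquaculture, built around a gibel carp (*Carassius gibelio*) trial in
which dietary fishmeal was replaced by blends of *Tenebrio molitor* meal,
*Chlorella* meal, *Clostridium autoethanogenum* protein and cottonseed
protein concentrate.  The package is aimed at fish-nutrition researchers
who need to go from raw trial tables — diet formulations, diet/feces
marker assays, cage growth records — to the quantities such studies
report, with every formula explicit and testable.

## What it computes

**Diet formulation.** Blended diets substituting fishmeal at a fraction
*f* on an isonitrogenous basis: blend mass = FM base × *f* × *k*, where
the protein-equivalence factor *k* = CP_FM / (ratio-weighted blend CP)
keeps dietary crude protein constant; the formulation is closed to 100%
dry matter with an inert filler.

**Marker-based digestibility.** Apparent digestibility coefficients from
yttrium-oxide marker ratios,

ADC (%) = 100 × [1 − (fecal conc / dietary conc) × (Y₂O₃ in diet / Y₂O₃ in feces)],

with pooled coefficients (total EAA, total NEAA) computed on summed
concentrations, and digestible contents as content × ADC/100.

**Protein-quality indices.** The essential amino acid index and its
digestible counterpart, geometric means over the nine essential amino
acids (lysine, methionine, threonine, arginine, leucine, isoleucine,
valine, phenylalanine, histidine) against the species' requirements
*r*ᵢ:

EAAI (%) = 100 × (∏ᵢ aᵢ/rᵢ)^(1/9),  DEAAI (%) = 100 × (∏ᵢ (aᵢ·ADCᵢ/100)/rᵢ)^(1/9).

**Performance indices.** SR, SGR, FR, FE, PER, PRE from cage records and
CF, VSI, HSI from fish morphometrics, exactly as conventionally defined
(see `aquatrial.performance`).

**Dose-response.** A statsmodels-style `LinearPlateau` model (broken-line
regression), y = plateau − slope·max(0, b − x), fitted by profiled least
squares over the breakpoint with a deterministic grid-plus-refinement
search; `QuadraticPlateau` and plain OLS are provided alongside.  The
breakpoint estimates the dietary quality level needed for maximum
response.

**Group statistics.** One-way ANOVA, Duncan's multiple range test with
compact-letter displays (harmonic-mean group size for unbalanced data,
studentized-range quantiles computed numerically), Levene's
homogeneity test, and reference-gene-normalised qPCR relative expression.

**Synthetic trials.** `aquatrial.simulate` generates complete trials
(formulated diets, fecal marker assays obeying mass balance, cage growth
driven by a linear-plateau response to DEAAI, morphometrics, qPCR Ct
tables) with recorded ground truth, seed-deterministic per table.

## Worked example

```python
import aquatrial as aq

trial = aq.load_gibel_trial()          # packaged trial tables
req = trial.requirements               # gibel carp EAA requirements

for diet in ("Control", "B100"):
    e = aq.eaai(trial.diet_aa[diet], req)
    d = aq.deaai(trial.diet_aa[diet], trial.adc_per_aa(diet), req)
    print(f"{diet:8s} EAAI = {e.value:6.2f}   DEAAI = {d.value:6.2f}")

model = aq.LinearPlateau(trial.growth["sgr"], trial.quality_indices.loc["DEAAI"])
print()
print(model.fit().summary())
```

```
Control  EAAI =  95.83   DEAAI =  79.07
B100     EAAI =  96.84   DEAAI =  83.18

linear-plateau fit (profiled least squares)
  n observations : 10
  breakpoint     : 79.4604
  slope          : 0.26274
  plateau        : 2.4643
  RSS            : 0.0131533
  R-squared      : 0.7535
```

The control diet's chemical quality index (95.83%) is close to that of
every replacement diet, but its *digestible* index is much lower (79.07%)
because digestibility discounts each amino acid individually.  Fitting
specific growth rate against DEAAI across the ten diets places the
breakpoint near 79.5% DEAAI: growth rises with digestible protein quality
up to that threshold and plateaus at about 2.46 %/day beyond it.  (The
recomputed B100 indices differ slightly from the published ones, which
were evidently calculated from unrounded laboratory values.)

A command-line interface mirrors the library:

```sh
aquatrial simulate --seed 7 --out trial/          # synthetic trial + truth
aquatrial full --aa-table trial/diet_amino_acids.csv \
               --adc-table trial/adc_assays.csv \
               --cage-table trial/cage_records.csv --out reports/
aquatrial fit --data pairs.csv --x deaai --y sgr --model linear-plateau
```

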