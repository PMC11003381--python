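"""Synthetic feeding-trial generator with known ground truth.

Emulates the structure of the gibel carp fishmeal-replacement trial — a
control diet plus three blends at three replacement levels (10 diets),
three cages per diet, 70 fish per cage, 56 days — so that every analysis
stage (formulation, digestibility, quality indices, performance indices,
group statistics, dose-response fitting) can be exercised end to end
against a recorded truth.

The generative model:

* Diets are formulated with :mod:`aquatrial.formulation` from synthetic
  ingredient profiles; protein-equivalence factors are derived from the
  ingredient crude-protein contents, and the true dietary amino-acid
  composition follows by linear mixing.
* Each diet has true per-substance ADCs (a per-amino-acid baseline plus a
  blend-and-level-dependent shift), from which the true DEAAI is computed.
* Cage mean specific growth rate is drawn as
  linear_plateau(DEAAI; breakpoint, slope, plateau) + Normal(0, sgr_sd) —
  growth responds to digestible protein quality up to a requirement
  threshold and is flat beyond it.
* Fecal compositions obey marker mass balance: with the marker fully
  recovered, feces concentrate by the factor 1/(1 - ADC_DM/100), so
  ``feces_conc = diet_conc * (1 - ADC/100) / (1 - ADC_DM/100)`` and
  ``marker_feces = marker_diet / (1 - ADC_DM/100)``; assay noise is
  multiplicative lognormal (concentrations stay positive).
* qPCR Ct values are normal on the cycle scale around a reference-gene
  baseline, with a per-diet shift in true log2 expression.

Randomness comes from a single seed expanded into one substream per table
(growth, fecal assays, morphometrics, qPCR), so adding a new table type
never perturbs existing draws and the same seed reproduces the dataset
bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .amino import ESSENTIAL_AA, AminoAcidVector, IngredientProfile, write_aa_table
from .digestibility import AdcAssay
from .errors import ValidationError
from .formulation import (
    BlendSpec,
    DietSpec,
    GIBEL_TRIAL_BLENDS,
    equivalence_factor,
    formulate_replacement_series,
)
from .performance import CageRecord
from .quality import deaai

__all__ = ["TrialConfig", "GroundTruth", "TrialDataset", "generate", "write_dataset"]


def _aa(**kwargs: float) -> AminoAcidVector:
    return AminoAcidVector(kwargs)


def default_ingredients() -> dict[str, IngredientProfile]:
    """Synthetic ingredient profiles with realistic CP and amino-acid levels.

    Crude-protein contents are typical commercial values (fishmeal 65%,
    insect meal 52%, Chlorella 55%, C. autoethanogenum protein 72%,
    cottonseed protein concentrate 60%, rapeseed meal 38%, soybean meal
    46% DM); amino-acid contents are % DM of the ingredient.
    """
    return {
        "fish meal": IngredientProfile(
            "fish meal", 65.0, 8.0,
            _aa(lysine=4.80, methionine=1.80, threonine=2.70, arginine=3.90, leucine=4.70,
                isoleucine=2.80, valine=3.20, phenylalanine=2.50, histidine=1.50,
                asparagine=5.90, **{"glutamic acid": 8.30}),
        ),
        "T. molitor meal": IngredientProfile(
            "T. molitor meal", 52.0, 24.0,
            _aa(lysine=2.90, methionine=0.80, threonine=2.10, arginine=2.70, leucine=3.70,
                isoleucine=2.30, valine=3.00, phenylalanine=2.00, histidine=1.60,
                asparagine=4.20, **{"glutamic acid": 6.00}),
        ),
        "Chlorella meal": IngredientProfile(
            "Chlorella meal", 55.0, 9.0,
            _aa(lysine=2.90, methionine=1.10, threonine=2.50, arginine=3.20, leucine=4.60,
                isoleucine=2.10, valine=3.00, phenylalanine=2.60, histidine=1.10,
                asparagine=4.80, **{"glutamic acid": 6.30}),
        ),
        "Clostridium autoethanogenum protein": IngredientProfile(
            "Clostridium autoethanogenum protein", 72.0, 2.0,
            _aa(lysine=6.00, methionine=1.90, threonine=3.30, arginine=4.70, leucine=5.90,
                isoleucine=3.60, valine=4.30, phenylalanine=3.30, histidine=1.50,
                asparagine=6.90, **{"glutamic acid": 9.10}),
        ),
        "cottonseed protein concentrate": IngredientProfile(
            "cottonseed protein concentrate", 60.0, 1.5,
            _aa(lysine=2.50, methionine=0.80, threonine=1.90, arginine=6.70, leucine=3.50,
                isoleucine=1.90, valine=2.70, phenylalanine=3.20, histidine=1.70,
                asparagine=5.40, **{"glutamic acid": 11.80}),
        ),
        "rapeseed meal": IngredientProfile(
            "rapeseed meal", 38.0, 2.5,
            _aa(lysine=2.00, methionine=0.70, threonine=1.60, arginine=2.20, leucine=2.60,
                isoleucine=1.50, valine=1.90, phenylalanine=1.50, histidine=1.00,
                asparagine=2.60, **{"glutamic acid": 6.50}),
        ),
        "soybean meal": IngredientProfile(
            "soybean meal", 46.0, 1.9,
            _aa(lysine=2.80, methionine=0.60, threonine=1.80, arginine=3.30, leucine=3.50,
                isoleucine=2.10, valine=2.20, phenylalanine=2.30, histidine=1.20,
                asparagine=5.20, **{"glutamic acid": 8.20}),
        ),
    }


#: Baseline true per-amino-acid ADCs (%) shared by all diets before the
#: blend shifts; levels typical of practical omnivorous-fish diets, set so
#: the control diet's true DEAAI sits near 79% and the ten diets straddle
#: the growth breakpoint.
DEFAULT_BASE_ADC: dict[str, float] = {
    "lysine": 86.0, "methionine": 97.5, "threonine": 77.5, "arginine": 79.0,
    "leucine": 85.5, "isoleucine": 85.0, "valine": 82.0, "phenylalanine": 84.5,
    "histidine": 86.5, "asparagine": 84.0, "glutamic acid": 90.0,
}


@dataclass(frozen=True)
class TrialConfig:
    """Configuration (= ground-truth parameters) for a synthetic trial.

    Defaults mirror the study conditions: 3 cages of 70 fish per diet for
    56 days, fishmeal base inclusion 15% DM, blends A/B/C at replacement
    levels 1/3, 2/3 and 1, a growth plateau of 2.46 %/d reached at a DEAAI
    breakpoint of 79.5% with rising slope 0.26 per DEAAI unit, cage-level
    SGR noise 0.03 %/d, 1% CV multiplicative fecal assay noise and 0.15
    cycle qPCR noise.
    """

    n_cages: int = 3
    n_fish: int = 70
    days: float = 56.0
    ibw_mean: float = 15.18
    ibw_cv: float = 0.005
    fm_base: float = 15.0
    fractions: Sequence[float] = (1.0 / 3.0, 2.0 / 3.0, 1.0)
    blends: Mapping[str, BlendSpec] = field(default_factory=lambda: dict(GIBEL_TRIAL_BLENDS))
    ingredients: Mapping[str, IngredientProfile] = field(default_factory=default_ingredients)
    base_adc: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE_ADC))
    #: per-blend ADC shift (percentage points at full replacement), applied
    #: proportionally to the replacement fraction
    blend_adc_shift: Mapping[str, float] = field(
        default_factory=lambda: {"A": -4.5, "B": 4.5, "C": 1.5}
    )
    adc_dm_base: float = 56.0
    adc_cp_base: float = 78.0
    breakpoint: float = 79.5
    slope: float = 0.26
    plateau_sgr: float = 2.46
    sgr_sd: float = 0.03
    survival_p: float = 0.965
    feeding_rate: float = 3.0  # %BW/d
    diet_cp: float = 34.2  # % DM, isonitrogenous target
    body_protein_frac: float = 0.169  # whole-body crude protein, wet basis
    weight_cv: float = 0.10  # fish-level body-weight CV within a cage
    assay_cv: float = 0.01  # multiplicative fecal assay noise
    ct_sd: float = 0.15  # qPCR cycle noise
    n_qpcr: int = 6
    marker_diet: float = 0.10  # Y2O3 inclusion, % DM
    seed: int = 0

    def __post_init__(self) -> None:
        for fld in ("n_cages", "n_fish", "days", "ibw_mean", "fm_base", "slope",
                    "plateau_sgr", "feeding_rate", "diet_cp", "marker_diet"):
            if getattr(self, fld) <= 0:
                raise ValidationError(f"{fld} must be > 0")
        for fld in ("ibw_cv", "sgr_sd", "weight_cv", "assay_cv", "ct_sd"):
            if getattr(self, fld) < 0:
                raise ValidationError(f"{fld} must be >= 0")
        if not (0 < self.survival_p <= 1):
            raise ValidationError("survival_p must be in (0, 1]")

    def noiseless(self) -> "TrialConfig":
        """A copy with every noise scale set to zero (and survival 100%)."""
        return dataclasses.replace(
            self, ibw_cv=0.0, sgr_sd=0.0, weight_cv=0.0, assay_cv=0.0, ct_sd=0.0,
            survival_p=1.0,
        )


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows that an analyst must estimate."""

    factors: dict[str, float]
    diet_aa: dict[str, AminoAcidVector]
    adc: dict[str, dict[str, float]]  # diet -> substance -> true ADC %
    adc_dm: dict[str, float]
    deaai: dict[str, float]
    sgr_mean: dict[str, float]
    log2_expression: dict[str, float]
    breakpoint: float
    slope: float
    plateau_sgr: float


@dataclass(frozen=True)
class TrialDataset:
    """One generated trial: analysis-ready tables plus the ground truth."""

    diets: dict[str, DietSpec]
    diet_aa: dict[str, AminoAcidVector]
    cage_records: list[CageRecord]
    adc_assays: pd.DataFrame  # diet, replicate, substance, concentrations
    morphometrics: pd.DataFrame
    ct_table: pd.DataFrame
    truth: GroundTruth

    def assays_for(self, diet: str, replicate: int) -> list[AdcAssay]:
        """The :class:`AdcAssay` objects of one diet/replicate pair."""
        sub = self.adc_assays[
            (self.adc_assays["diet"] == diet) & (self.adc_assays["replicate"] == replicate)
        ]
        return [
            AdcAssay(r.substance, r.diet_conc, r.feces_conc, r.marker_diet, r.marker_feces)
            for r in sub.itertuples()
        ]


def _plateau_response(x: float, breakpoint: float, slope: float, plateau: float) -> float:
    return plateau - slope * max(0.0, breakpoint - x)


def generate(config: TrialConfig) -> TrialDataset:
    """Generate a complete synthetic feeding trial.

    Deterministic in ``config.seed``; see the module docstring for the
    generative model.  Raises :class:`ValidationError` if the configured
    growth breakpoint falls outside the range of the diets' true DEAAIs
    (the dose-response would then be unidentifiable by design).
    """
    ss = np.random.SeedSequence(config.seed)
    rng_growth, rng_feces, rng_morpho, rng_ct = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    ingredients = dict(config.ingredients)
    fm = ingredients["fish meal"]
    factors = {
        name: equivalence_factor(fm, blend, ingredients)
        for name, blend in config.blends.items()
    }
    base_inclusions = {"rapeseed meal": 25.0, "soybean meal": 26.0}
    diets = formulate_replacement_series(
        config.fm_base, config.fractions, config.blends, factors,
        base_inclusions=base_inclusions,
    )

    from .formulation import diet_aa as mix_aa

    # the cellulose filler is inert: drop it before amino-acid mixing
    def strip_filler(spec: DietSpec) -> DietSpec:
        incl = {k: v for k, v in spec.inclusions.items()
                if k != "microcrystalline cellulose"}
        return dataclasses.replace(spec, inclusions=incl)

    aa_true = {name: mix_aa(strip_filler(spec), ingredients) for name, spec in diets.items()}

    # --- true digestibility and quality ------------------------------
    def diet_shift(name: str) -> float:
        if name == "Control":
            return 0.0
        blend, level = name[0], float(name[1:]) / 100.0
        return config.blend_adc_shift.get(blend, 0.0) * level

    adc_true: dict[str, dict[str, float]] = {}
    adc_dm_true: dict[str, float] = {}
    deaai_true: dict[str, float] = {}
    req = _requirements()
    for name in diets:
        shift = diet_shift(name)
        # a true ADC cannot reach 100%: cap near-complete absorption at 99.5
        per_sub = {sub: min(base + shift, 99.5) for sub, base in config.base_adc.items()}
        per_sub["crude protein"] = min(config.adc_cp_base + shift, 99.5)
        adc_true[name] = per_sub
        adc_dm_true[name] = config.adc_dm_base + shift
        eaa_adc = {a: per_sub[a] for a in ESSENTIAL_AA}
        deaai_true[name] = deaai(aa_true[name], eaa_adc, req).value

    dvals = list(deaai_true.values())
    if not (min(dvals) <= config.breakpoint <= max(dvals)):
        raise ValidationError(
            f"configured breakpoint {config.breakpoint} lies outside the generated "
            f"DEAAI range [{min(dvals):.2f}, {max(dvals):.2f}]"
        )

    # --- cage growth records ------------------------------------------
    sgr_mean = {
        name: _plateau_response(deaai_true[name], config.breakpoint, config.slope,
                                config.plateau_sgr)
        for name in diets
    }
    records: list[CageRecord] = []
    for name in diets:
        for cage in range(config.n_cages):
            ibw = config.ibw_mean * (1.0 + config.ibw_cv * rng_growth.standard_normal())
            sgr = sgr_mean[name] + config.sgr_sd * rng_growth.standard_normal()
            fbw = ibw * np.exp(sgr * config.days / 100.0)
            n_final = (
                config.n_fish
                if config.survival_p >= 1.0
                else int(rng_growth.binomial(config.n_fish, config.survival_p))
            )
            n_dead = config.n_fish - n_final
            # mortalities assumed to die mid-trial at the geometric mean weight
            dead_total = n_dead * float(np.sqrt(ibw * fbw))
            feed = config.feeding_rate / 100.0 * config.days * (ibw + fbw) / 2.0
            records.append(
                CageRecord(
                    diet=name, n_initial=config.n_fish, n_final=max(n_final, 1),
                    ibw=ibw, fbw=fbw, feed_dm=feed, days=config.days,
                    dead_weight=dead_total / max(n_final, 1),
                    protein_intake=feed * config.diet_cp / 100.0,
                    body_protein_gain=config.body_protein_frac * (fbw - ibw),
                    basis="fish",
                )
            )

    # --- fecal assay tables -------------------------------------------
    assay_rows = []
    for name in diets:
        indig_dm = 1.0 - adc_dm_true[name] / 100.0
        for rep in range(config.n_cages):
            marker_feces = config.marker_diet / indig_dm
            marker_feces *= np.exp(config.assay_cv * rng_feces.standard_normal())
            for sub, adc_s in adc_true[name].items():
                diet_conc = (
                    config.diet_cp if sub == "crude protein" else aa_true[name][sub]
                )
                feces = diet_conc * (1.0 - adc_s / 100.0) / indig_dm
                feces *= np.exp(config.assay_cv * rng_feces.standard_normal())
                assay_rows.append(
                    {
                        "diet": name, "replicate": rep, "substance": sub,
                        "diet_conc": diet_conc, "feces_conc": feces,
                        "marker_diet": config.marker_diet, "marker_feces": marker_feces,
                    }
                )
    adc_assays = pd.DataFrame(assay_rows)

    # --- morphometrics -------------------------------------------------
    morpho_rows = []
    for name in diets:
        fbw_mean = config.ibw_mean * np.exp(sgr_mean[name] * config.days / 100.0)
        for fish in range(3 * config.n_cages):
            bw = fbw_mean * np.exp(config.weight_cv * rng_morpho.standard_normal())
            cf = 3.2 * (1.0 + 0.03 * rng_morpho.standard_normal())
            length = (100.0 * bw / cf) ** (1.0 / 3.0)
            visceral = bw * 0.12 * (1.0 + 0.05 * rng_morpho.standard_normal())
            liver = visceral * 0.26 * (1.0 + 0.05 * rng_morpho.standard_normal())
            morpho_rows.append(
                {
                    "diet": name, "fish": fish, "body_weight": bw,
                    "total_length": length, "visceral_weight": visceral,
                    "liver_weight": liver,
                }
            )
    morphometrics = pd.DataFrame(morpho_rows)

    # --- qPCR Ct table --------------------------------------------------
    log2_expr = {name: 0.15 * diet_shift(name) for name in diets}
    ct_rows = []
    for name in diets:
        for sample in range(config.n_qpcr):
            ct_ref = 18.0 + config.ct_sd * rng_ct.standard_normal()
            ct_target = 24.0 - log2_expr[name] + config.ct_sd * rng_ct.standard_normal()
            ct_rows.append(
                {"diet": name, "sample": sample, "gene": "pept1",
                 "ct_target": ct_target, "ct_ref": ct_ref}
            )
    ct_table = pd.DataFrame(ct_rows)

    truth = GroundTruth(
        factors=factors, diet_aa=aa_true, adc=adc_true, adc_dm=adc_dm_true,
        deaai=deaai_true, sgr_mean=sgr_mean, log2_expression=log2_expr,
        breakpoint=config.breakpoint, slope=config.slope, plateau_sgr=config.plateau_sgr,
    )
    return TrialDataset(
        diets=diets, diet_aa=aa_true, cage_records=records, adc_assays=adc_assays,
        morphometrics=morphometrics, ct_table=ct_table, truth=truth,
    )


def _requirements():
    from .datasets import load_gibel_trial

    return load_gibel_trial().requirements


def write_dataset(ds: TrialDataset, outdir: str | Path) -> None:
    """Write a generated dataset as delimited tables plus a truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({n: s.inclusions for n, s in ds.diets.items()}).rename_axis(
        "ingredient"
    ).to_csv(out / "diet_ingredients.csv")
    write_aa_table(ds.diet_aa, out / "diet_amino_acids.csv")
    pd.DataFrame([dataclasses.asdict(r) for r in ds.cage_records]).to_csv(
        out / "cage_records.csv", index=False
    )
    ds.adc_assays.to_csv(out / "adc_assays.csv", index=False)
    ds.morphometrics.to_csv(out / "morphometrics.csv", index=False)
    ds.ct_table.to_csv(out / "ct_values.csv", index=False)
    truth = dataclasses.asdict(ds.truth)
    truth["diet_aa"] = {k: dict(v.values) for k, v in ds.truth.diet_aa.items()}
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
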