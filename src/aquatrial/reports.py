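"""End-to-end analysis pipeline and report rendering.

``run_full_analysis`` sequences the stages of a fishmeal-replacement
trial analysis from delimited input tables: dietary quality indices
(EAAI/DEAAI), per-diet ADC summaries, cage performance indices with
ANOVA/Duncan letters, and dose-response fits of growth against quality.
Reports are delimited tables plus a JSON machine summary; values are kept
at full precision internally and rounded to 2 decimals only at render
time.  Re-running on identical inputs yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .amino import ESSENTIAL_AA, RequirementSet, read_aa_table, read_requirements
from .digestibility import AdcAssay, adc, pooled_adc
from .doseresponse import fit_linear, fit_linear_plateau, fit_quadratic_plateau
from .errors import AquatrialError, ValidationError
from .groupstats import GroupData, duncan_mrt, one_way_anova
from .performance import CageRecord, performance_table, summarize_by_diet
from .quality import deaai, eaai

logger = logging.getLogger("aquatrial")

_FIT_FUNCS = {
    "linear": fit_linear,
    "linear-plateau": fit_linear_plateau,
    "quadratic-plateau": fit_quadratic_plateau,
}


@dataclass
class AnalysisConfig:
    """File locations and choices for a full trial analysis.

    Any table path may be None; the stages that need it are then skipped
    with a warning.  ``requirements`` falls back to the packaged gibel
    carp requirement set.
    """

    aa_table: str | Path | None = None
    requirements_table: str | Path | None = None
    adc_table: str | Path | None = None  # long format: diet, substance, concentrations
    cage_table: str | Path | None = None
    model: str = "linear-plateau"
    alpha: float = 0.05
    outdir: str | Path | None = None
    response: str = "sgr"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 0.5):
            raise ValidationError(f"alpha must be in (0, 0.5), got {self.alpha}")
        if self.model not in _FIT_FUNCS:
            raise ValidationError(
                f"model must be one of {sorted(_FIT_FUNCS)}, got {self.model!r}"
            )


@dataclass
class ReportBundle:
    """All tables a full analysis produces (None where a stage was skipped)."""

    quality: pd.DataFrame | None = None
    adc_summary: pd.DataFrame | None = None
    performance: pd.DataFrame | None = None
    performance_summary: pd.DataFrame | None = None
    letters: dict[str, dict[str, str]] = field(default_factory=dict)
    fits: dict[str, dict] = field(default_factory=dict)

    def to_machine_summary(self) -> dict:
        out: dict = {"fits": self.fits, "letters": self.letters}
        if self.quality is not None:
            out["quality"] = self.quality.round(2).to_dict(orient="index")
        return out


def _load_requirements(cfg: AnalysisConfig) -> RequirementSet:
    if cfg.requirements_table is not None:
        return read_requirements(cfg.requirements_table)
    from .datasets import load_gibel_trial

    return load_gibel_trial().requirements


def quality_stage(
    aa_vectors, req: RequirementSet, adc_per_diet: dict[str, dict[str, float]] | None
) -> pd.DataFrame:
    """EAAI (and DEAAI where per-AA ADCs are available) per diet."""
    rows = {}
    for diet, vec in aa_vectors.items():
        row = {"EAAI": eaai(vec, req).value}
        if adc_per_diet and diet in adc_per_diet:
            aa_adcs = {
                a: v for a, v in adc_per_diet[diet].items() if a in ESSENTIAL_AA
            }
            if len(aa_adcs) == len(ESSENTIAL_AA):
                row["DEAAI"] = deaai(vec, aa_adcs, req).value
        rows[diet] = row
    return pd.DataFrame(rows).T.rename_axis("diet")


def adc_stage(adc_long: pd.DataFrame) -> pd.DataFrame:
    """Mean ADC per diet and substance from a long assay table.

    Expects columns diet, substance, diet_conc, feces_conc, marker_diet,
    marker_feces (one row per replicate); adds pooled total-EAA rows per
    diet/replicate where all 9 EAAs are present.
    """
    needed = {"diet", "substance", "diet_conc", "feces_conc", "marker_diet", "marker_feces"}
    missing = needed - set(adc_long.columns)
    if missing:
        raise ValidationError(f"ADC table is missing column(s): {sorted(missing)}")
    rep_col = "replicate" if "replicate" in adc_long.columns else None
    rows = []
    group_cols = ["diet"] + ([rep_col] if rep_col else [])
    for key, sub in adc_long.groupby(group_cols, sort=False):
        diet = key[0] if isinstance(key, tuple) else key
        assays = [
            AdcAssay(r.substance, r.diet_conc, r.feces_conc, r.marker_diet, r.marker_feces)
            for r in sub.itertuples()
        ]
        for a in assays:
            rows.append({"diet": diet, "substance": a.substance, "adc": adc(a)})
        eaa_assays = [a for a in assays if a.substance in ESSENTIAL_AA]
        if len(eaa_assays) == len(ESSENTIAL_AA):
            rows.append(
                {
                    "diet": diet,
                    "substance": "total essential amino acid",
                    "adc": pooled_adc(eaa_assays),
                }
            )
    long = pd.DataFrame(rows)
    return long.pivot_table(index="substance", columns="diet", values="adc", sort=False)


def performance_stage(
    records: list[CageRecord], alpha: float
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, dict[str, str]]]:
    """Per-cage indices, per-diet mean +/- SE, and Duncan letters per index."""
    table = performance_table(records)
    summary = summarize_by_diet(table)
    letters: dict[str, dict[str, str]] = {}
    for index_name in ("sr", "fr", "sgr", "fe", "per", "pre"):
        col = table[["diet", index_name]].dropna()
        if col.empty or col.groupby("diet").size().min() < 2:
            continue
        g = GroupData.from_long(col, "diet", index_name)
        res = one_way_anova(g)
        if res.degenerate:
            continue
        letters[index_name] = dict(duncan_mrt(g, alpha=alpha).letters)
    return table, summary, letters


def run_full_analysis(cfg: AnalysisConfig) -> ReportBundle:
    """Run every stage the configured inputs allow; see module docstring.

    Any stage failure is re-raised with the stage name prepended so a CLI
    user can locate the offending table.
    """
    bundle = ReportBundle()
    req = _load_requirements(cfg)

    adc_per_diet: dict[str, dict[str, float]] | None = None
    if cfg.adc_table is not None:
        logger.info("stage: digestibility")
        try:
            adc_long = pd.read_csv(cfg.adc_table)
            bundle.adc_summary = adc_stage(adc_long)
            adc_per_diet = {
                diet: bundle.adc_summary[diet].dropna().to_dict()
                for diet in bundle.adc_summary.columns
            }
        except AquatrialError as exc:
            raise type(exc)(f"[digestibility stage] {exc}") from exc
    else:
        logger.warning("no ADC table; digestibility stage skipped")

    if cfg.aa_table is not None:
        logger.info("stage: protein quality")
        try:
            vectors = read_aa_table(cfg.aa_table)
            bundle.quality = quality_stage(vectors, req, adc_per_diet)
        except AquatrialError as exc:
            raise type(exc)(f"[quality stage] {exc}") from exc
    else:
        logger.warning("no amino-acid table; quality stage skipped")

    if cfg.cage_table is not None:
        logger.info("stage: performance")
        try:
            df = pd.read_csv(cfg.cage_table)
            if df.empty:
                logger.warning("cage table is empty; performance stage skipped")
            else:
                records = [
                    CageRecord(
                        diet=str(r["diet"]),
                        n_initial=int(r["n_initial"]),
                        n_final=int(r["n_final"]),
                        ibw=float(r["ibw"]),
                        fbw=float(r["fbw"]),
                        feed_dm=float(r["feed_dm"]),
                        days=float(r["days"]),
                        dead_weight=float(r.get("dead_weight", 0.0)),
                        protein_intake=(
                            float(r["protein_intake"]) if "protein_intake" in r else None
                        ),
                        body_protein_gain=(
                            float(r["body_protein_gain"]) if "body_protein_gain" in r else None
                        ),
                        basis=str(r.get("basis", "cage")),
                    )
                    for _, r in df.iterrows()
                ]
                (
                    bundle.performance,
                    bundle.performance_summary,
                    bundle.letters,
                ) = performance_stage(records, cfg.alpha)
        except AquatrialError as exc:
            raise type(exc)(f"[performance stage] {exc}") from exc
    else:
        logger.warning("no cage table; performance stage skipped")

    # Dose-response: growth response against DEAAI, per-diet means
    if (
        bundle.quality is not None
        and "DEAAI" in getattr(bundle.quality, "columns", [])
        and bundle.performance is not None
    ):
        logger.info("stage: dose-response")
        per_diet = bundle.performance.groupby("diet", sort=False)[cfg.response].mean()
        shared = [d for d in bundle.quality.index if d in per_diet.index]
        x = bundle.quality.loc[shared, "DEAAI"].to_numpy()
        y = per_diet.loc[shared].to_numpy()
        if len(shared) >= 4 and np.ptp(x) > 0:
            fit = _FIT_FUNCS[cfg.model](x, y)
            bundle.fits[f"{cfg.response}~DEAAI"] = {
                "model": cfg.model,
                **{
                    k: float(v)
                    for k, v in (
                        fit.params.items()
                        if hasattr(fit, "params")
                        else dataclasses.asdict(fit).items()
                        if dataclasses.is_dataclass(fit)
                        else []
                    )
                    if np.isscalar(v)
                },
                "r2": float(fit.r2),
                "n": int(len(shared)),
            }

    if cfg.outdir is not None:
        write_reports(bundle, cfg.outdir)
    return bundle


def write_reports(bundle: ReportBundle, outdir: str | Path) -> None:
    """Render the bundle: 2-dp delimited tables plus a JSON summary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if bundle.quality is not None:
        bundle.quality.round(2).to_csv(out / "quality_indices.csv")
    if bundle.adc_summary is not None:
        bundle.adc_summary.round(2).to_csv(out / "adc_summary.csv")
    if bundle.performance is not None:
        bundle.performance.round(4).to_csv(out / "performance_by_cage.csv", index=False)
    if bundle.performance_summary is not None:
        flat = bundle.performance_summary.copy()
        flat.columns = ["_".join(c) for c in flat.columns]
        lettered = flat.round(2).astype(object)
        for index_name, per_diet in bundle.letters.items():
            col = f"{index_name}_mean"
            if col in lettered.columns:
                lettered[col] = [
                    f"{v}{per_diet.get(d, '')}" for d, v in flat[col].round(2).items()
                ]
        lettered.to_csv(out / "performance_summary.csv")
    (out / "summary.json").write_text(
        json.dumps(bundle.to_machine_summary(), indent=1, sort_keys=True)
    )
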