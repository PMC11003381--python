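"""Growth, feed-utilisation and body indices of a feeding trial.

The unit of analysis is the cage: a :class:`CageRecord` holds one cage's
bookkeeping over the trial (counts, mean body weights, total dry feed
intake, mortality mass, protein intake and deposition), and the index
functions implement the standard definitions:

    SR  (%)      = 100 * n_final / n_initial
    SGR (%/d)    = 100 * (ln FBW - ln IBW) / days
    FR  (%BW/d)  = 100 * feed DM / (days * (FBW + IBW)/2)
    FE  (%)      = 100 * (weight gain + dead fish weight) / feed DM
    PER          = weight gain / protein intake
    PRE (%)      = 100 * body protein deposition / protein intake

FR and FE require feed intake and weights on the same basis (both per fish
or both per cage); the ``basis`` flag on the record documents which and is
purely declarative.  Body indices are per fish:

    CF  (g/cm3)  = 100 * body weight / total length**3
    VSI (%)      = 100 * visceral weight / body weight
    HSI (%)      = 100 * liver weight / body weight
"""

from __future__ import annotations

import math
from collections.abc import Iterable
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError


@dataclass(frozen=True)
class CageRecord:
    """Growth and feed bookkeeping for one cage over a trial.

    ``ibw``/``fbw`` are mean body weights (g); ``feed_dm`` total dry feed
    intake (g) on the basis given by ``basis`` ("fish" = per-fish averages,
    "cage" = cage totals); ``dead_weight`` the summed weight of mortalities
    (g, same basis); ``protein_intake`` and ``body_protein_gain`` in g.
    """

    diet: str
    n_initial: int
    n_final: int
    ibw: float
    fbw: float
    feed_dm: float
    days: float
    dead_weight: float = 0.0
    protein_intake: float | None = None
    body_protein_gain: float | None = None
    basis: str = "cage"

    def __post_init__(self) -> None:
        if self.n_initial <= 0:
            raise ValidationError(f"n_initial must be > 0, got {self.n_initial}")
        if self.n_final < 0 or self.n_final > self.n_initial:
            raise ValidationError(
                f"n_final must be in [0, n_initial], got {self.n_final} of {self.n_initial}"
            )
        if self.ibw <= 0 or self.fbw <= 0:
            raise DomainError("body weights must be > 0")
        if self.days <= 0:
            raise DomainError("trial duration must be > 0 days")
        if self.feed_dm < 0 or self.dead_weight < 0:
            raise ValidationError("feed intake and dead-fish weight must be >= 0")
        if self.basis not in ("cage", "fish"):
            raise ValidationError(f"basis must be 'cage' or 'fish', got {self.basis!r}")


@dataclass(frozen=True)
class FishMorphometrics:
    """One fish's weight (g), total length (cm) and organ weights (g)."""

    body_weight: float
    total_length: float
    visceral_weight: float
    liver_weight: float

    def __post_init__(self) -> None:
        for fld in ("body_weight", "total_length", "visceral_weight", "liver_weight"):
            if getattr(self, fld) <= 0:
                raise DomainError(f"{fld} must be > 0")
        if self.visceral_weight >= self.body_weight:
            raise ValidationError("visceral weight must be below body weight")
        if self.liver_weight >= self.visceral_weight:
            raise ValidationError("liver weight must be below visceral weight")


def survival_rate(rec: CageRecord) -> float:
    """Survival rate (%), in [0, 100]."""
    return 100.0 * rec.n_final / rec.n_initial


def specific_growth_rate(rec: CageRecord) -> float:
    """Specific growth rate (%/day); invariant to rescaling both weights."""
    return 100.0 * (math.log(rec.fbw) - math.log(rec.ibw)) / rec.days


def feeding_rate(rec: CageRecord) -> float:
    """Feeding rate (% of mean body weight per day)."""
    mean_bw = (rec.fbw + rec.ibw) / 2.0
    return 100.0 * rec.feed_dm / (rec.days * mean_bw)


def feed_efficiency(rec: CageRecord) -> float:
    """Feed efficiency (%): gain plus mortality mass over dry feed intake."""
    if rec.feed_dm <= 0:
        raise DomainError("feed efficiency needs feed_dm > 0")
    return 100.0 * ((rec.fbw - rec.ibw) + rec.dead_weight) / rec.feed_dm


def _require_protein_intake(rec: CageRecord) -> float:
    if rec.protein_intake is None:
        raise ValidationError(f"cage {rec.diet!r}: protein_intake is not recorded")
    if rec.protein_intake <= 0:
        raise DomainError("protein intake must be > 0")
    return rec.protein_intake


def protein_efficiency_ratio(rec: CageRecord) -> float:
    """Protein efficiency ratio: weight gain per unit protein intake."""
    return (rec.fbw - rec.ibw) / _require_protein_intake(rec)


def protein_retention(rec: CageRecord) -> float:
    """Protein retention efficiency (%): protein deposited over protein eaten."""
    intake = _require_protein_intake(rec)
    if rec.body_protein_gain is None:
        raise ValidationError(f"cage {rec.diet!r}: body_protein_gain is not recorded")
    return 100.0 * rec.body_protein_gain / intake


def condition_factor(m: FishMorphometrics) -> float:
    """Condition factor (g/cm3): 100 x body weight / length cubed."""
    return 100.0 * m.body_weight / m.total_length**3


def viscerosomatic_index(m: FishMorphometrics) -> float:
    """Viscerosomatic index (%): visceral weight as a share of body weight."""
    return 100.0 * m.visceral_weight / m.body_weight


def hepatosomatic_index(m: FishMorphometrics) -> float:
    """Hepatosomatic index (%): liver weight as a share of body weight."""
    return 100.0 * m.liver_weight / m.body_weight


# ---------------------------------------------------------------------------
# Tabulation helpers
# ---------------------------------------------------------------------------

_INDEX_FUNCS = {
    "sr": survival_rate,
    "fr": feeding_rate,
    "sgr": specific_growth_rate,
    "fe": feed_efficiency,
    "per": protein_efficiency_ratio,
    "pre": protein_retention,
}


def performance_table(records: Iterable[CageRecord]) -> pd.DataFrame:
    """Per-cage table of all computable indices.

    One row per cage with columns diet, ibw, fbw and the indices; PER/PRE
    are NaN where protein bookkeeping is missing.
    """
    rows = []
    for rec in records:
        row: dict[str, object] = {"diet": rec.diet, "ibw": rec.ibw, "fbw": rec.fbw}
        for name, fn in _INDEX_FUNCS.items():
            try:
                row[name] = fn(rec)
            except ValidationError:
                row[name] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_by_diet(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error of each index by diet (cage = replicate)."""
    num = table.select_dtypes("number")
    g = table.assign(**{c: num[c] for c in num}).groupby("diet", sort=False)[list(num.columns)]
    mean = g.mean()
    se = g.sem(ddof=1)
    out = pd.concat({"mean": mean, "se": se}, axis=1)
    return out.swaplevel(axis=1).sort_index(axis=1, level=0, sort_remaining=False)
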