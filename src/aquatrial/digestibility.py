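"""Marker-ratio apparent digestibility coefficients (ADC).

Digestibility is estimated without total fecal collection by spiking the
diet with an indigestible indicator (yttrium trioxide, Y2O3).  Because the
marker passes through unabsorbed, the ratio of marker concentrations in
diet and feces measures how much the feces were concentrated by nutrient
absorption, and the apparent digestibility of any substance follows from
the diet/feces concentration pair referenced to that ratio:

    ADC (%) = 100 * [1 - (fecal conc / dietary conc) * (marker in diet / marker in feces)]

For dry matter both "concentrations" are 100, so
``ADC_DM = 100 * (1 - marker_diet / marker_feces)``.

ADCs above 100 are impossible (a substance cannot be more than fully
absorbed); values below 0 are mathematically possible under assay noise
and are reported as-is with a :class:`~aquatrial.errors.NegativeAdcWarning`
rather than clamped.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Sequence
from dataclasses import dataclass

from .errors import DomainError, NegativeAdcWarning, ValidationError

_MARKER_TOL = 1e-9


@dataclass(frozen=True)
class AdcAssay:
    """Paired diet/feces concentrations for one digestibility estimate.

    ``diet_conc`` and ``feces_conc`` must share units (% DM for proximate
    and amino-acid assays, MJ/kg for gross energy); ``marker_diet`` and
    ``marker_feces`` are the Y2O3 concentrations (% DM) in diet and feces.
    """

    substance: str
    diet_conc: float
    feces_conc: float
    marker_diet: float
    marker_feces: float

    def __post_init__(self) -> None:
        for fld in ("diet_conc", "feces_conc"):
            v = getattr(self, fld)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{fld} must be finite and >= 0, got {v!r}")
        for fld in ("marker_diet", "marker_feces"):
            v = getattr(self, fld)
            if not math.isfinite(v) or v <= 0:
                raise DomainError(f"{fld} must be finite and > 0, got {v!r}")


def dry_matter_assay(marker_diet: float, marker_feces: float) -> AdcAssay:
    """An :class:`AdcAssay` for dry matter (both concentrations are 100% DM)."""
    return AdcAssay("dry matter", 100.0, 100.0, marker_diet, marker_feces)


def adc(assay: AdcAssay) -> float:
    """Apparent digestibility coefficient (%) of one substance.

    Strictly decreasing in ``feces_conc`` and in the marker ratio
    ``marker_diet / marker_feces``; at most 100 (attained when the
    substance is absent from feces); negative values are flagged with
    :class:`~aquatrial.errors.NegativeAdcWarning` but returned unmodified.
    """
    if assay.diet_conc <= 0:
        raise DomainError(
            f"dietary concentration of {assay.substance!r} must be > 0 to estimate an ADC"
        )
    value = 100.0 * (
        1.0 - (assay.feces_conc / assay.diet_conc) * (assay.marker_diet / assay.marker_feces)
    )
    if value < 0:
        warnings.warn(
            f"negative ADC ({value:.2f}%) for {assay.substance!r}; reported as-is",
            NegativeAdcWarning,
            stacklevel=2,
        )
    return value


def digestible_content(content: float, adc_percent: float) -> float:
    """Digestible content (% DM) = analysed content x ADC/100."""
    if content < 0:
        raise ValidationError(f"content must be >= 0, got {content}")
    return content * adc_percent / 100.0


def pooled_adc(assays: Sequence[AdcAssay]) -> float:
    """ADC of a substance pool (e.g. total essential amino acids).

    The pooled coefficient applies the marker-ratio formula to the *summed*
    diet and feces concentrations — not the mean of the individual ADCs —
    which is the coefficient one would measure by assaying the pool as a
    single substance.  All assays must share the same marker pair.
    """
    if not assays:
        raise ValidationError("pooled_adc needs at least one assay")
    first = assays[0]
    for a in assays[1:]:
        if (
            abs(a.marker_diet - first.marker_diet) > _MARKER_TOL
            or abs(a.marker_feces - first.marker_feces) > _MARKER_TOL
        ):
            raise ValidationError(
                "assays in a pool must share marker concentrations; "
                f"{a.substance!r} differs from {first.substance!r}"
            )
    pooled = AdcAssay(
        substance="+".join(a.substance for a in assays),
        diet_conc=sum(a.diet_conc for a in assays),
        feces_conc=sum(a.feces_conc for a in assays),
        marker_diet=first.marker_diet,
        marker_feces=first.marker_feces,
    )
    return adc(pooled)
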