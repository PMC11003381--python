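"""Geometric-mean protein-quality indices: EAAI and DEAAI.

The essential amino acid index (EAAI) scores a diet's protein quality as
100 times the geometric mean, over the nine essential amino acids, of the
ratio of dietary content to the species' requirement:

    EAAI (%) = 100 * (prod_i content_i / requirement_i) ** (1/9)

The digestible essential amino acid index (DEAAI) applies the same formula
to digestible contents (content x ADC/100), so it discounts each amino
acid by its apparent digestibility.  Ratios are deliberately NOT capped at
1 (the classic Oser index caps them); leaving them uncapped lets amino
acids supplied above requirement raise the index, which is the convention
the packaged gibel carp trial values follow.

Both indices are evaluated in log space (the arithmetic mean of log
ratios), which is numerically identical to the product form but immune to
overflow/underflow for extreme ratios.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass

from .amino import ESSENTIAL_AA, AminoAcidVector, RequirementSet, canonical_aa_name
from .digestibility import digestible_content
from .errors import DomainError, ValidationError


@dataclass(frozen=True)
class QualityIndexResult:
    """A protein-quality index value with its per-amino-acid ratios.

    ``value`` is 100 x the geometric mean of ``per_aa_ratios`` over the 9
    EAAs; ``basis`` records whether ratios were formed from chemical or
    digestible contents.
    """

    value: float
    per_aa_ratios: Mapping[str, float]
    basis: str  # "chemical" | "digestible"

    def __post_init__(self) -> None:
        if self.basis not in ("chemical", "digestible"):
            raise ValidationError(f"basis must be 'chemical' or 'digestible', got {self.basis!r}")
        object.__setattr__(self, "per_aa_ratios", dict(self.per_aa_ratios))


def _eaa_contents(diet_aa: AminoAcidVector) -> dict[str, float]:
    contents = {}
    for a in ESSENTIAL_AA:
        if a not in diet_aa:
            raise ValidationError(f"diet amino-acid vector is missing essential amino acid {a!r}")
        c = diet_aa[a]
        if c <= 0:
            raise DomainError(f"content of {a!r} must be > 0 for a geometric-mean index")
        contents[a] = c
    return contents


def _geometric_index(ratios: Mapping[str, float], basis: str) -> QualityIndexResult:
    mean_log = sum(math.log(r) for r in ratios.values()) / len(ratios)
    return QualityIndexResult(value=100.0 * math.exp(mean_log), per_aa_ratios=ratios, basis=basis)


def eaai(diet_aa: AminoAcidVector, req: RequirementSet) -> QualityIndexResult:
    """Essential amino acid index of a diet against a requirement set.

    Scale-invariant: multiplying every content and every requirement by the
    same positive constant leaves the index unchanged.  A diet exactly
    matching the requirements scores 100.
    """
    contents = _eaa_contents(diet_aa)
    ratios = {a: contents[a] / req[a] for a in ESSENTIAL_AA}
    return _geometric_index(ratios, "chemical")


def deaai(
    diet_aa: AminoAcidVector,
    adc_per_aa: Mapping[str, float],
    req: RequirementSet,
) -> QualityIndexResult:
    """Digestible essential amino acid index.

    Like :func:`eaai` but each content is first multiplied by its apparent
    digestibility coefficient over 100.  With every ADC at 100 the two
    indices coincide; with ADCs at or below 100, DEAAI <= EAAI.  The index
    is strictly increasing in each individual ADC.
    """
    contents = _eaa_contents(diet_aa)
    adcs = {canonical_aa_name(k): float(v) for k, v in adc_per_aa.items()}
    missing = [a for a in ESSENTIAL_AA if a not in adcs]
    if missing:
        raise ValidationError(f"missing ADC for essential amino acid(s): {', '.join(missing)}")
    for a in ESSENTIAL_AA:
        if adcs[a] <= 0:
            raise DomainError(f"ADC of {a!r} must be > 0 for a geometric-mean index")
    ratios = {a: digestible_content(contents[a], adcs[a]) / req[a] for a in ESSENTIAL_AA}
    return _geometric_index(ratios, "digestible")


def deaa_ratio_profile(
    diet_aa: AminoAcidVector,
    adc_per_aa: Mapping[str, float],
    reference: AminoAcidVector,
) -> dict[str, float]:
    """Per-EAA ratios of dietary digestible contents to a reference pattern.

    The reference is typically the muscle EAA composition of the target
    species or its requirement pattern; with the requirement pattern as
    reference, 100 x the geometric mean of these ratios equals the DEAAI.
    """
    contents = _eaa_contents(diet_aa)
    adcs = {canonical_aa_name(k): float(v) for k, v in adc_per_aa.items()}
    missing = [a for a in ESSENTIAL_AA if a not in adcs]
    if missing:
        raise ValidationError(f"missing ADC for essential amino acid(s): {', '.join(missing)}")
    out = {}
    for a in ESSENTIAL_AA:
        if a not in reference:
            raise ValidationError(f"reference pattern is missing essential amino acid {a!r}")
        ref = reference[a]
        if ref <= 0:
            raise DomainError(f"reference content of {a!r} must be > 0")
        out[a] = digestible_content(contents[a], adcs[a]) / ref
    return out
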