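"""Diet formulation with blended protein sources replacing fishmeal.

A replacement diet substitutes a fraction of the fishmeal inclusion with a
blend of alternative protein ingredients, mixed at fixed ratio parts, on an
isonitrogenous (protein-equivalent) basis: the blend mass replacing unit
mass of fishmeal is scaled by a protein-equivalence factor so total dietary
crude protein is unchanged.  The formulation is closed to 100% of dry
matter with an inert filler (microcrystalline cellulose in practice).

:func:`equivalence_factor` derives the factor from ingredient crude-protein
contents (factor = fishmeal CP / ratio-weighted blend CP).  The gibel carp
trial reproduced by the packaged fixtures used factors 0.912, 0.960 and
1.008 for its three blends (:data:`GIBEL_TRIAL_FACTORS`); those factors are
back-derived from the published formulation table and are carried as data
because the exact equivalence rule behind them is not recoverable from
ingredient compositions alone.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace

from .amino import AminoAcidVector, IngredientProfile
from .errors import (
    DomainError,
    InfeasibleFormulationError,
    MissingIngredientError,
    ValidationError,
)

#: Blend ratio parts (TMM : CM : CAP : CPC) used in the gibel carp trial.
GIBEL_TRIAL_BLENDS: dict[str, "BlendSpec"] = {}

#: Protein-equivalence factors of the gibel carp trial, back-derived from
#: the published inclusion table (blend mass = 15% x fraction x factor).
GIBEL_TRIAL_FACTORS: dict[str, float] = {"A": 0.912, "B": 0.96, "C": 1.008}

#: Fishmeal inclusion (% DM) of the trial's control diet.
GIBEL_TRIAL_FM_BASE: float = 15.0


@dataclass(frozen=True)
class BlendSpec:
    """An ordered blend of ingredients with positive ratio parts."""

    components: Sequence[tuple[str, float]]

    def __post_init__(self) -> None:
        comps = [(str(n), float(p)) for n, p in self.components]
        if not comps:
            raise ValidationError("a blend needs at least one component")
        for n, p in comps:
            if p <= 0:
                raise ValidationError(f"ratio part for {n!r} must be > 0, got {p}")
        object.__setattr__(self, "components", tuple(comps))

    @property
    def total_parts(self) -> float:
        return float(sum(p for _, p in self.components))

    def weights(self) -> dict[str, float]:
        """Ratio parts normalised to sum to 1."""
        t = self.total_parts
        return {n: p / t for n, p in self.components}


GIBEL_TRIAL_BLENDS.update(
    {
        "A": BlendSpec(
            [
                ("T. molitor meal", 1),
                ("Chlorella meal", 1),
                ("Clostridium autoethanogenum protein", 8),
                ("cottonseed protein concentrate", 2),
            ]
        ),
        "B": BlendSpec(
            [
                ("T. molitor meal", 1),
                ("Chlorella meal", 1),
                ("Clostridium autoethanogenum protein", 6),
                ("cottonseed protein concentrate", 4),
            ]
        ),
        "C": BlendSpec(
            [
                ("T. molitor meal", 1),
                ("Chlorella meal", 1),
                ("Clostridium autoethanogenum protein", 4),
                ("cottonseed protein concentrate", 6),
            ]
        ),
    }
)


@dataclass(frozen=True)
class DietSpec:
    """A complete diet: named ingredient inclusions in % of dry matter.

    ``marker`` is the inert-indicator inclusion (yttrium trioxide, % DM);
    ``proximate`` holds analysed crude protein / crude lipid / ash / gross
    energy values when available.
    """

    name: str
    inclusions: Mapping[str, float]
    marker: float = 0.0
    proximate: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {str(k): float(v) for k, v in self.inclusions.items()}
        for k, v in clean.items():
            if v < 0:
                raise ValidationError(f"inclusion of {k!r} in {self.name!r} must be >= 0, got {v}")
        if self.marker < 0:
            raise ValidationError(f"marker inclusion of {self.name!r} must be >= 0")
        object.__setattr__(self, "inclusions", clean)
        object.__setattr__(self, "proximate", dict(self.proximate))

    def total_inclusion(self) -> float:
        return float(sum(self.inclusions.values()))

    def is_closed(self, tol: float = 1e-6) -> bool:
        return abs(self.total_inclusion() - 100.0) <= tol


def equivalence_factor(
    fm: IngredientProfile,
    blend: BlendSpec,
    ingredients: Mapping[str, IngredientProfile],
) -> float:
    """Protein-equivalence factor of a blend against fishmeal.

    The mass of blend that carries the same crude protein as unit mass of
    fishmeal: ``fm.crude_protein / (ratio-weighted mean blend CP)``.
    """
    weighted = 0.0
    for name, w in blend.weights().items():
        if name not in ingredients:
            raise MissingIngredientError(f"no ingredient profile for blend component {name!r}")
        cp = ingredients[name].crude_protein
        if cp <= 0:
            raise ValidationError(f"crude protein of {name!r} must be > 0")
        weighted += w * cp
    if fm.crude_protein <= 0:
        raise ValidationError("fishmeal crude protein must be > 0")
    return fm.crude_protein / weighted


def blend_inclusions(
    fm_base: float,
    replacement_fraction: float,
    blend: BlendSpec,
    factor: float,
    fm_name: str = "fish meal",
) -> dict[str, float]:
    """Inclusions (% DM) after replacing part of the fishmeal with a blend.

    Total blend mass is ``fm_base * replacement_fraction * factor``, split
    across components in proportion to their ratio parts; the residual
    fishmeal inclusion ``fm_base * (1 - replacement_fraction)`` is returned
    under *fm_name*.
    """
    if fm_base <= 0:
        raise ValidationError(f"fm_base must be > 0, got {fm_base}")
    if not (0 <= replacement_fraction <= 1):
        raise ValidationError(f"replacement_fraction must be in [0, 1], got {replacement_fraction}")
    if factor <= 0:
        raise ValidationError(f"equivalence factor must be > 0, got {factor}")
    total = fm_base * replacement_fraction * factor
    out = {fm_name: fm_base * (1.0 - replacement_fraction)}
    for name, w in blend.weights().items():
        out[name] = total * w
    return out


def diet_aa(spec: DietSpec, ingredients: Mapping[str, IngredientProfile]) -> AminoAcidVector:
    """Dietary amino-acid composition by linear mixing of ingredient profiles.

    Each amino-acid content is the inclusion-weighted sum over ingredients:
    ``sum_i inclusion_i/100 * aa_i``.  Ingredients with zero inclusion may
    lack a profile; a nonzero inclusion without one raises
    :class:`MissingIngredientError`.  Profiled ingredients without an AA
    vector (oils, starch, premixes) contribute nothing.
    """
    totals: dict[str, float] = {}
    for name, incl in spec.inclusions.items():
        if incl == 0:
            continue
        if name not in ingredients:
            raise MissingIngredientError(
                f"diet {spec.name!r}: no profile for ingredient {name!r} (inclusion {incl}%)"
            )
        vec = ingredients[name].aa
        if vec is None:
            continue
        for a, c in vec.items():
            totals[a] = totals.get(a, 0.0) + incl / 100.0 * c
    return AminoAcidVector(totals)


def close_formulation(spec: DietSpec, filler: str) -> DietSpec:
    """Set the filler inclusion so that the formulation sums to exactly 100% DM."""
    non_filler = sum(v for k, v in spec.inclusions.items() if k != filler)
    if non_filler > 100.0 + 1e-9:
        raise InfeasibleFormulationError(
            f"diet {spec.name!r}: non-filler inclusions sum to {non_filler:.4f}% > 100%"
        )
    new = dict(spec.inclusions)
    new[filler] = 100.0 - non_filler
    return replace(spec, inclusions=new)


def formulate_replacement_series(
    fm_base: float,
    fractions: Sequence[float],
    blends: Mapping[str, BlendSpec],
    factors: Mapping[str, float],
    base_inclusions: Mapping[str, float] | None = None,
    fm_name: str = "fish meal",
    filler: str = "microcrystalline cellulose",
) -> dict[str, DietSpec]:
    """Formulate a control plus a grid of blend x replacement-level diets.

    Diet names follow the ``<blend><level%>`` convention (e.g. ``B67``)
    with a ``Control`` diet at zero replacement.  *base_inclusions* are the
    non-protein fixed ingredients shared by all diets; the filler absorbs
    the formulation-mass difference left by the protein substitution.
    """
    base = dict(base_inclusions or {})
    diets: dict[str, DietSpec] = {}

    def build(name: str, blend: BlendSpec | None, factor: float, fraction: float) -> DietSpec:
        incl = dict(base)
        if blend is None:
            incl[fm_name] = fm_base
        else:
            incl.update(blend_inclusions(fm_base, fraction, blend, factor, fm_name=fm_name))
        spec = DietSpec(name=name, inclusions=incl)
        return close_formulation(spec, filler)

    diets["Control"] = build("Control", None, 1.0, 0.0)
    for bname, blend in blends.items():
        if bname not in factors:
            raise MissingIngredientError(f"no equivalence factor for blend {bname!r}")
        for frac in fractions:
            if frac <= 0:
                raise DomainError(f"replacement fraction must be > 0, got {frac}")
            label = f"{bname}{round(frac * 100):d}"
            diets[label] = build(label, blend, factors[bname], frac)
    return diets
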