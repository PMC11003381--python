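"""Blended-diet formulation: equivalence factors, inclusions, mixing, closure."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aquatrial import (
    GIBEL_TRIAL_BLENDS,
    GIBEL_TRIAL_FACTORS,
    GIBEL_TRIAL_FM_BASE,
    AminoAcidVector,
    BlendSpec,
    DietSpec,
    InfeasibleFormulationError,
    IngredientProfile,
    MissingIngredientError,
    ValidationError,
    blend_inclusions,
    close_formulation,
    diet_aa,
    equivalence_factor,
)

BLEND_COMPONENTS = (
    "T. molitor meal",
    "Chlorella meal",
    "Clostridium autoethanogenum protein",
    "cottonseed protein concentrate",
)


def _profiles(cps):
    return {n: IngredientProfile(n, cp) for n, cp in cps.items()}


class TestEquivalenceFactor:
    def test_identity_when_blend_matches_fm(self):
        fm = IngredientProfile("fm", 65.0)
        blend = BlendSpec([("a", 1), ("b", 1)])
        ing = _profiles({"a": 65.0, "b": 65.0})
        assert equivalence_factor(fm, blend, ing) == pytest.approx(1.0)

    def test_equal_weighted_mean(self):
        fm = IngredientProfile("fm", 65.0)
        blend = BlendSpec([("a", 1), ("b", 1)])
        ing = _profiles({"a": 50.0, "b": 80.0})
        assert equivalence_factor(fm, blend, ing) == pytest.approx(1.0)

    def test_blend_a_factor_back_derivation(self):
        # blend-weighted CP 71.27 against fishmeal CP 65 gives the 0.912
        # factor recoverable from the published inclusion sums (13.68/15)
        fm = IngredientProfile("fm", 65.0)
        blend = BlendSpec([("a", 1)])
        ing = _profiles({"a": 65.0 / 0.912})
        assert equivalence_factor(fm, blend, ing) == pytest.approx(0.912, abs=1e-9)

    def test_missing_ingredient_raises(self):
        fm = IngredientProfile("fm", 65.0)
        with pytest.raises(MissingIngredientError):
            equivalence_factor(fm, BlendSpec([("ghost", 1)]), {})


class TestBlendInclusions:
    def test_full_replacement_blend_a(self):
        out = blend_inclusions(15.0, 1.0, GIBEL_TRIAL_BLENDS["A"], 0.912)
        assert out["Clostridium autoethanogenum protein"] == pytest.approx(9.12)
        assert out["T. molitor meal"] == pytest.approx(1.14)
        assert out["fish meal"] == pytest.approx(0.0)

    def test_zero_fraction_keeps_fishmeal(self):
        out = blend_inclusions(15.0, 0.0, GIBEL_TRIAL_BLENDS["A"], 0.912)
        assert out["fish meal"] == pytest.approx(15.0)
        assert all(out[c] == 0.0 for c in BLEND_COMPONENTS)

    def test_two_thirds_replacement_blend_b(self):
        out = blend_inclusions(15.0, 2.0 / 3.0, GIBEL_TRIAL_BLENDS["B"], 0.96)
        assert out["Clostridium autoethanogenum protein"] == pytest.approx(4.80)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            blend_inclusions(-1.0, 0.5, GIBEL_TRIAL_BLENDS["A"], 0.912)
        with pytest.raises(ValidationError):
            blend_inclusions(15.0, 1.5, GIBEL_TRIAL_BLENDS["A"], 0.912)

    @given(
        fraction=st.floats(0, 1),
        factor=st.floats(0.5, 2.0),
        fm_base=st.floats(1.0, 40.0),
    )
    def test_conservation_of_blend_mass(self, fraction, factor, fm_base):
        out = blend_inclusions(fm_base, fraction, GIBEL_TRIAL_BLENDS["B"], factor)
        blend_total = sum(out[c] for c in BLEND_COMPONENTS)
        assert blend_total == pytest.approx(fm_base * fraction * factor, rel=1e-12)

    def test_monotone_in_replacement_fraction(self):
        fracs = np.linspace(0, 1, 11)
        for comp in BLEND_COMPONENTS:
            vals = [
                blend_inclusions(15.0, f, GIBEL_TRIAL_BLENDS["C"], 1.008)[comp]
                for f in fracs
            ]
            assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


@pytest.mark.parametrize("diet", ["A33", "A67", "A100", "B33", "B67", "B100", "C33", "C67", "C100"])
def test_reconstructs_published_inclusions_to_2dp(trial, diet):
    """Blend ratios + back-derived factors reproduce every published cell."""
    blend_name = diet[0]
    fraction = {"33": 1 / 3, "67": 2 / 3, "100": 1.0}[diet[1:]]
    out = blend_inclusions(
        GIBEL_TRIAL_FM_BASE,
        fraction,
        GIBEL_TRIAL_BLENDS[blend_name],
        GIBEL_TRIAL_FACTORS[blend_name],
    )
    for comp in BLEND_COMPONENTS + ("fish meal",):
        assert round(out[comp], 2) == pytest.approx(trial.ingredients.loc[comp, diet])


class TestDietAa:
    def test_single_ingredient_identity(self):
        vec = AminoAcidVector({"lysine": 4.8, "leucine": 4.7})
        ing = {"fm": IngredientProfile("fm", 65.0, aa=vec)}
        spec = DietSpec("d", {"fm": 100.0})
        assert dict(diet_aa(spec, ing).values) == pytest.approx(dict(vec.values))

    def test_fifty_fifty_average(self):
        ing = {
            "a": IngredientProfile("a", 50.0, aa=AminoAcidVector({"lysine": 2.0})),
            "b": IngredientProfile("b", 50.0, aa=AminoAcidVector({"lysine": 4.0})),
        }
        spec = DietSpec("d", {"a": 50.0, "b": 50.0})
        assert diet_aa(spec, ing)["lysine"] == pytest.approx(3.0)

    def test_three_ingredient_mix_matches_brute_force(self):
        rng = np.random.default_rng(42)
        names = ["i1", "i2", "i3"]
        aas = ["lysine", "methionine", "serine"]
        profiles = {}
        contents = {}
        for n in names:
            contents[n] = {a: float(rng.uniform(0.1, 6.0)) for a in aas}
            profiles[n] = IngredientProfile(n, 50.0, aa=AminoAcidVector(contents[n]))
        incl = {"i1": 20.0, "i2": 30.0, "i3": 10.0}
        spec = DietSpec("d", incl)
        mixed = diet_aa(spec, profiles)
        for a in aas:
            expected = sum(incl[n] / 100.0 * contents[n][a] for n in names)
            assert mixed[a] == pytest.approx(expected, abs=1e-12)

    def test_missing_profile_for_nonzero_inclusion(self):
        spec = DietSpec("d", {"ghost": 10.0})
        with pytest.raises(MissingIngredientError, match="ghost"):
            diet_aa(spec, {})


class TestCloseFormulation:
    def test_fills_filler_to_100(self):
        spec = DietSpec("d", {"a": 95.62})
        closed = close_formulation(spec, "cellulose")
        assert closed.inclusions["cellulose"] == pytest.approx(4.38)
        assert closed.is_closed()

    def test_exact_100_gives_zero_filler(self):
        closed = close_formulation(DietSpec("d", {"a": 100.0}), "cellulose")
        assert closed.inclusions["cellulose"] == pytest.approx(0.0)

    def test_over_100_is_infeasible(self):
        with pytest.raises(InfeasibleFormulationError):
            close_formulation(DietSpec("d", {"a": 101.0}), "cellulose")


class TestSpecValidation:
    def test_negative_inclusion_rejected(self):
        with pytest.raises(ValidationError):
            DietSpec("d", {"a": -1.0})

    def test_blend_needs_positive_parts(self):
        with pytest.raises(ValidationError):
            BlendSpec([("a", 0.0)])
        with pytest.raises(ValidationError):
            BlendSpec([])
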