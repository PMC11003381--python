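"""EAAI / DEAAI geometric-mean indices and ratio profiles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aquatrial import (
    ESSENTIAL_AA,
    AminoAcidVector,
    DomainError,
    RequirementSet,
    ValidationError,
    deaa_ratio_profile,
    deaai,
    eaai,
)

# Diets whose published EAAI/DEAAI recompute exactly from the published
# 2-dp inputs.  B100 is the known exception: its printed indices were
# evidently computed from unrounded laboratory values and do not
# recompute from the rounded table (EAAI 97.50 vs ~96.84, DEAAI 83.75 vs
# ~83.18), so it is excluded here and documented rather than "fixed".
EXACT_DIETS = ["Control", "A33", "A67", "A100", "B33", "B67", "C33", "C67", "C100"]


def _uniform_req(value=1.0):
    return RequirementSet({a: value for a in ESSENTIAL_AA})


def _vec(value=1.0):
    return AminoAcidVector({a: value for a in ESSENTIAL_AA})


class TestEaai:
    @pytest.mark.parametrize("diet", EXACT_DIETS)
    def test_reproduces_published_values_to_2dp(self, trial, diet):
        result = eaai(trial.diet_aa[diet], trial.requirements)
        assert round(result.value, 2) == pytest.approx(
            trial.quality_indices.loc["EAAI", diet]
        )

    def test_diet_matching_requirements_scores_100(self):
        req = _uniform_req(1.3)
        assert eaai(_vec(1.3), req).value == pytest.approx(100.0)

    def test_missing_eaa_names_the_culprit(self, trial):
        vec = AminoAcidVector({a: 1.0 for a in ESSENTIAL_AA if a != "valine"})
        with pytest.raises(ValidationError, match="valine"):
            eaai(vec, trial.requirements)

    def test_zero_content_is_domain_error(self, trial):
        contents = {a: 1.0 for a in ESSENTIAL_AA}
        contents["lysine"] = 0.0
        with pytest.raises(DomainError):
            eaai(AminoAcidVector(contents), trial.requirements)

    def test_ratios_not_capped_at_one(self, trial):
        result = eaai(trial.diet_aa["Control"], trial.requirements)
        assert any(r > 1 for r in result.per_aa_ratios.values())
        assert any(r < 1 for r in result.per_aa_ratios.values())

    @given(c=st.floats(0.01, 100.0))
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(5)
        contents = {a: float(rng.uniform(0.3, 3)) for a in ESSENTIAL_AA}
        reqs = {a: float(rng.uniform(0.5, 3.5)) for a in ESSENTIAL_AA}
        base = eaai(AminoAcidVector(contents), RequirementSet(reqs)).value
        scaled = eaai(
            AminoAcidVector({a: v * c for a, v in contents.items()}),
            RequirementSet({a: v * c for a, v in reqs.items()}),
        ).value
        assert scaled == pytest.approx(base, rel=1e-12)

    @given(seed=st.integers(0, 2**16))
    def test_log_form_agrees_with_direct_product(self, seed):
        rng = np.random.default_rng(seed)
        contents = {a: float(rng.uniform(0.1, 5)) for a in ESSENTIAL_AA}
        reqs = {a: float(rng.uniform(0.5, 4)) for a in ESSENTIAL_AA}
        got = eaai(AminoAcidVector(contents), RequirementSet(reqs)).value
        product = math.prod(contents[a] / reqs[a] for a in ESSENTIAL_AA)
        assert got == pytest.approx(100 * product ** (1 / 9), rel=1e-12)


class TestDeaai:
    @pytest.mark.parametrize("diet", EXACT_DIETS)
    def test_reproduces_published_values_to_2dp(self, trial, diet):
        result = deaai(
            trial.diet_aa[diet],
            {a: trial.adc_per_aa(diet)[a] for a in ESSENTIAL_AA},
            trial.requirements,
        )
        assert round(result.value, 2) == pytest.approx(
            trial.quality_indices.loc["DEAAI", diet]
        )

    def test_reduces_to_eaai_at_full_digestibility(self, trial):
        vec = trial.diet_aa["Control"]
        full = {a: 100.0 for a in ESSENTIAL_AA}
        assert deaai(vec, full, trial.requirements).value == pytest.approx(
            eaai(vec, trial.requirements).value, rel=1e-12
        )

    def test_never_exceeds_eaai_for_adcs_below_100(self, trial):
        for diet in trial.diets:
            adcs = {a: trial.adc_per_aa(diet)[a] for a in ESSENTIAL_AA}
            assert (
                deaai(trial.diet_aa[diet], adcs, trial.requirements).value
                <= eaai(trial.diet_aa[diet], trial.requirements).value
            )

    def test_strictly_increasing_in_each_single_adc(self, trial):
        vec = trial.diet_aa["Control"]
        base_adcs = {a: 80.0 for a in ESSENTIAL_AA}
        base = deaai(vec, base_adcs, trial.requirements).value
        for a in ESSENTIAL_AA:
            bumped = dict(base_adcs)
            bumped[a] += 1.0
            assert deaai(vec, bumped, trial.requirements).value > base

    def test_missing_adc_rejected(self, trial):
        adcs = {a: 80.0 for a in ESSENTIAL_AA if a != "methionine"}
        with pytest.raises(ValidationError, match="methionine"):
            deaai(trial.diet_aa["Control"], adcs, trial.requirements)

    def test_basis_labels(self, trial):
        adcs = {a: 80.0 for a in ESSENTIAL_AA}
        assert eaai(trial.diet_aa["Control"], trial.requirements).basis == "chemical"
        assert deaai(trial.diet_aa["Control"], adcs, trial.requirements).basis == "digestible"


class TestDeaaRatioProfile:
    def test_self_reference_gives_unit_ratios(self, trial):
        vec = trial.diet_aa["Control"]
        adcs = {a: trial.adc_per_aa("Control")[a] for a in ESSENTIAL_AA}
        digestible = AminoAcidVector(
            {a: vec[a] * adcs[a] / 100 for a in ESSENTIAL_AA}
        )
        ratios = deaa_ratio_profile(vec, adcs, digestible)
        assert all(r == pytest.approx(1.0) for r in ratios.values())

    def test_requirement_reference_geomean_equals_deaai(self, trial):
        vec = trial.diet_aa["Control"]
        adcs = {a: trial.adc_per_aa("Control")[a] for a in ESSENTIAL_AA}
        req_vec = AminoAcidVector(dict(trial.requirements.requirements))
        ratios = deaa_ratio_profile(vec, adcs, req_vec)
        geomean = math.exp(sum(math.log(r) for r in ratios.values()) / 9)
        expected = deaai(vec, adcs, trial.requirements).value
        assert 100 * geomean == pytest.approx(expected, rel=1e-12)

    def test_doubling_reference_halves_ratios(self, trial):
        vec = trial.diet_aa["Control"]
        adcs = {a: 80.0 for a in ESSENTIAL_AA}
        ref1 = _vec(1.0)
        ref2 = _vec(2.0)
        r1 = deaa_ratio_profile(vec, adcs, ref1)
        r2 = deaa_ratio_profile(vec, adcs, ref2)
        for a in ESSENTIAL_AA:
            assert r2[a] == pytest.approx(r1[a] / 2, rel=1e-12)

    def test_zero_reference_entry_rejected(self, trial):
        ref = {a: 1.0 for a in ESSENTIAL_AA}
        ref["histidine"] = 0.0
        with pytest.raises(DomainError):
            deaa_ratio_profile(
                trial.diet_aa["Control"],
                {a: 80.0 for a in ESSENTIAL_AA},
                AminoAcidVector(ref),
            )
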