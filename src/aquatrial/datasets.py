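"""Packaged tables from the gibel carp fishmeal-replacement trial.

The bundled dataset covers a 10-diet, 3-cages-per-diet, 56-day trial in
which dietary fishmeal (15% of dry matter) was replaced at 1/3, 2/3 and
full level by three blends (A, B, C) of Tenebrio molitor meal, Chlorella
meal, Clostridium autoethanogenum protein and cottonseed protein
concentrate at ratio parts 1:1:8:2, 1:1:6:4 and 1:1:4:6.  The tables are
the published group-level summaries:

* diet ingredient inclusions and proximate composition (% DM),
* dietary amino-acid composition (17 amino acids, % DM) and the gibel
  carp EAA requirement levels,
* the published EAAI/DEAAI values per diet,
* growth/feed-utilisation summaries (mean and SE over 3 cages),
* body indices, and
* apparent digestibility coefficients per substance and diet.

Every file is verified against a recorded SHA-256 checksum on load;
corruption raises :class:`~aquatrial.errors.FixtureIntegrityError`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .amino import AminoAcidVector, RequirementSet, read_aa_table, read_requirements
from .errors import FixtureIntegrityError

_DATA_PKG = "aquatrial.data"

#: Diet names in published order.
DIET_NAMES: tuple[str, ...] = (
    "Control",
    "A33",
    "A67",
    "A100",
    "B33",
    "B67",
    "B100",
    "C33",
    "C67",
    "C100",
)


def _data_path(name: str):
    return resources.files(_DATA_PKG).joinpath(name)


def _verified_path(name: str):
    path = _data_path(name)
    with resources.as_file(_data_path("checksums.json")) as p:
        expected = json.loads(p.read_text())
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if name not in expected:
        raise FixtureIntegrityError(f"no recorded checksum for fixture {name!r}")
    if digest != expected[name]:
        raise FixtureIntegrityError(
            f"fixture {name!r} is corrupted: sha256 {digest} != recorded {expected[name]}"
        )
    return path


def _read_matrix(name: str) -> pd.DataFrame:
    with resources.as_file(_verified_path(name)) as p:
        return pd.read_csv(p, index_col=0)


@dataclass(frozen=True)
class TrialTables:
    """The bundled trial dataset as aligned pandas tables."""

    ingredients: pd.DataFrame  # ingredient x diet inclusions, % DM
    proximate: pd.DataFrame  # component x diet, % DM (energy MJ/kg)
    diet_aa: dict[str, AminoAcidVector]  # diet -> 17-AA vector, % DM
    requirements: RequirementSet  # gibel carp EAA requirements, % DM
    quality_indices: pd.DataFrame  # published EAAI/DEAAI rows x diet
    growth: pd.DataFrame  # diet x growth indices (mean, se)
    body: pd.DataFrame  # diet x body indices
    adc: pd.DataFrame  # substance x diet ADCs, %

    @property
    def diets(self) -> tuple[str, ...]:
        return DIET_NAMES

    def adc_per_aa(self, diet: str) -> dict[str, float]:
        """Per-amino-acid ADCs (%) for one diet, keyed by canonical name."""
        from .amino import CANONICAL_AA

        col = self.adc[diet]
        return {a: float(col[a]) for a in CANONICAL_AA if a in col.index}


def load_gibel_trial() -> TrialTables:
    """Load (and integrity-check) the bundled gibel carp trial dataset."""
    with resources.as_file(_verified_path("diet_amino_acids.csv")) as p:
        diet_aa = read_aa_table(p)
    with resources.as_file(_verified_path("eaa_requirements.csv")) as p:
        requirements = read_requirements(p)
    return TrialTables(
        ingredients=_read_matrix("diet_ingredients.csv"),
        proximate=_read_matrix("diet_proximate.csv"),
        diet_aa=diet_aa,
        requirements=requirements,
        quality_indices=_read_matrix("diet_quality_indices.csv"),
        growth=_read_matrix("growth_performance.csv"),
        body=_read_matrix("body_indices.csv"),
        adc=_read_matrix("adc.csv"),
    )
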