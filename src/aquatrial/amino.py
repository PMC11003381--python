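"""Amino-acid composition containers and delimited-table I/O.

All compositions are expressed in percent of dry matter (% DM) and kept at
full floating precision; rounding to the 2 decimals conventional in feed
tables happens only at report time.

The canonical amino-acid list has 17 names.  Nine are treated as essential
for the target species (gibel carp): lysine, methionine, threonine,
arginine, leucine, isoleucine, valine, phenylalanine and histidine.
Tryptophan is deliberately absent — it is destroyed by the acid hydrolysis
used in routine feed amino-acid analysis and is not part of the nine-term
quality indices this package computes, so the essential set has exactly
nine members everywhere.  The asparagine entry is pooled Asx
(asparagine + aspartate), as acid hydrolysis cannot distinguish them;
likewise glutamic acid is pooled Glx.
"""

from __future__ import annotations

import math
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field

import pandas as pd

from .errors import DomainError, ValidationError

#: The nine essential amino acids (EAA), in conventional reporting order.
ESSENTIAL_AA: tuple[str, ...] = (
    "lysine",
    "methionine",
    "threonine",
    "arginine",
    "leucine",
    "isoleucine",
    "valine",
    "phenylalanine",
    "histidine",
)

#: The eight nonessential amino acids (NEAA) reported in feed tables.
NONESSENTIAL_AA: tuple[str, ...] = (
    "asparagine",
    "serine",
    "glutamic acid",
    "glycine",
    "alanine",
    "tyrosine",
    "proline",
    "cysteine",
)

CANONICAL_AA: tuple[str, ...] = ESSENTIAL_AA + NONESSENTIAL_AA

#: Common 3-letter (and pooled) abbreviations accepted by the readers.
AA_ALIASES: dict[str, str] = {
    "lys": "lysine",
    "met": "methionine",
    "thr": "threonine",
    "arg": "arginine",
    "leu": "leucine",
    "ile": "isoleucine",
    "val": "valine",
    "phe": "phenylalanine",
    "his": "histidine",
    "asn": "asparagine",
    "asp": "asparagine",
    "asx": "asparagine",
    "ser": "serine",
    "glu": "glutamic acid",
    "glx": "glutamic acid",
    "glutamate": "glutamic acid",
    "gly": "glycine",
    "ala": "alanine",
    "tyr": "tyrosine",
    "pro": "proline",
    "cys": "cysteine",
    "cystine": "cysteine",
}


def canonical_aa_name(name: str) -> str:
    """Map a user-supplied amino-acid label to its canonical full name.

    Accepts canonical full names (any case) and the common abbreviations in
    :data:`AA_ALIASES`.  Raises :class:`ValidationError` for anything else.
    """
    key = str(name).strip().lower().replace("_", " ")
    if key in CANONICAL_AA:
        return key
    if key in AA_ALIASES:
        return AA_ALIASES[key]
    raise ValidationError(
        f"unknown amino acid name {name!r}; expected one of the 17 canonical "
        f"names or a recognised abbreviation"
    )


def is_essential(name: str) -> bool:
    """True if *name* (canonical or alias) denotes one of the 9 EAAs."""
    return canonical_aa_name(name) in ESSENTIAL_AA


@dataclass(frozen=True)
class AminoAcidVector(Mapping):
    """Named amino-acid contents in % of dry matter.

    Behaves as an immutable mapping from canonical amino-acid name to
    content.  Keys are canonicalised on construction; all contents must be
    finite and nonnegative.
    """

    values: Mapping[str, float]

    def __post_init__(self) -> None:
        clean: dict[str, float] = {}
        for name, raw in self.values.items():
            cname = canonical_aa_name(name)
            try:
                v = float(raw)
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"non-numeric content for {cname!r}: {raw!r}") from exc
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"content for {cname!r} must be finite and >= 0, got {v!r}")
            if cname in clean:
                raise ValidationError(f"duplicate amino acid {cname!r}")
            clean[cname] = v
        object.__setattr__(self, "values", clean)

    # Mapping protocol -------------------------------------------------
    def __getitem__(self, name: str) -> float:
        return self.values[canonical_aa_name(name)]

    def __iter__(self) -> Iterator[str]:
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)

    def __contains__(self, name: object) -> bool:
        try:
            return canonical_aa_name(str(name)) in self.values
        except ValidationError:
            return False

    # Subsets ----------------------------------------------------------
    def eaa_subset(self) -> "AminoAcidVector":
        """The entries for the 9 essential amino acids present in this vector."""
        return AminoAcidVector({k: v for k, v in self.values.items() if k in ESSENTIAL_AA})

    def neaa_subset(self) -> "AminoAcidVector":
        """The nonessential entries present in this vector."""
        return AminoAcidVector({k: v for k, v in self.values.items() if k in NONESSENTIAL_AA})

    def total(self) -> float:
        return float(sum(self.values.values()))

    def as_series(self) -> pd.Series:
        """Contents as a pandas Series in canonical order."""
        order = [a for a in CANONICAL_AA if a in self.values]
        return pd.Series({a: self.values[a] for a in order}, name="content")


@dataclass(frozen=True)
class RequirementSet(Mapping):
    """Essential amino-acid requirement levels (% DM) for the target species.

    Exactly the 9 EAAs, each strictly positive.  These are the denominators
    of the EAAI/DEAAI quality indices.  ``source_labels`` carries free-text
    citation tags for each requirement (requirements for a species are
    typically assembled from several dose-response studies).
    """

    requirements: Mapping[str, float]
    source_labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, float] = {}
        for name, raw in self.requirements.items():
            cname = canonical_aa_name(name)
            if cname not in ESSENTIAL_AA:
                raise ValidationError(f"{cname!r} is not an essential amino acid")
            v = float(raw)
            if not math.isfinite(v) or v <= 0:
                raise DomainError(f"requirement for {cname!r} must be > 0, got {v!r}")
            clean[cname] = v
        missing = [a for a in ESSENTIAL_AA if a not in clean]
        if missing:
            raise ValidationError(f"requirement set is missing EAA(s): {', '.join(missing)}")
        object.__setattr__(self, "requirements", clean)
        object.__setattr__(
            self,
            "source_labels",
            {canonical_aa_name(k): str(v) for k, v in self.source_labels.items()},
        )

    def __getitem__(self, name: str) -> float:
        return self.requirements[canonical_aa_name(name)]

    def __iter__(self) -> Iterator[str]:
        return iter(self.requirements)

    def __len__(self) -> int:
        return len(self.requirements)

    def as_series(self) -> pd.Series:
        return pd.Series({a: self.requirements[a] for a in ESSENTIAL_AA}, name="requirement")


@dataclass(frozen=True)
class IngredientProfile:
    """Proximate and amino-acid profile of one feed ingredient.

    ``crude_protein`` and ``crude_lipid`` in % DM; ``aa`` the ingredient's
    amino-acid contents (% DM of the ingredient); ``marker`` an optional
    inert-marker content (% DM), e.g. yttrium trioxide.
    """

    name: str
    crude_protein: float
    crude_lipid: float = 0.0
    aa: AminoAcidVector | None = None
    marker: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.crude_protein <= 100):
            raise ValidationError(
                f"crude protein of {self.name!r} must be in (0, 100], got {self.crude_protein}"
            )
        if self.crude_lipid < 0:
            raise ValidationError(f"crude lipid of {self.name!r} must be >= 0")
        if self.aa is not None and self.aa.total() > 100 + 1e-9:
            raise ValidationError(
                f"amino-acid contents of {self.name!r} sum to {self.aa.total():.2f} > 100% DM"
            )
        if self.marker is not None and self.marker < 0:
            raise ValidationError(f"marker content of {self.name!r} must be >= 0")


# ---------------------------------------------------------------------------
# Delimited-table I/O
# ---------------------------------------------------------------------------

def _read_table(path, sep) -> pd.DataFrame:
    # cells are read as text and converted with float(): pandas' fast float
    # parser is not correctly rounded, which would break exact round trips
    try:
        if sep is None:
            return pd.read_csv(path, sep=None, engine="python", index_col=0, dtype=str)
        return pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except FileNotFoundError:
        raise
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty table") from exc


def read_aa_table(path, sep: str | None = None) -> dict[str, AminoAcidVector]:
    """Read a diet-by-amino-acid table into per-diet vectors.

    The table must have a header row of diet names and one row per amino
    acid (canonical names or recognised abbreviations in the first column).
    Comma or tab separation is auto-detected when *sep* is None.  Unknown
    amino-acid names, negative values and non-numeric cells raise
    :class:`ValidationError` naming the offending row/column.
    """
    df = _read_table(path, sep)
    if df.shape[0] == 0:  # header only: nothing to parse
        return {}
    rows = [canonical_aa_name(r) for r in df.index]  # rejects unknown AAs
    out: dict[str, AminoAcidVector] = {}
    for col in df.columns:
        contents: dict[str, float] = {}
        for cname, raw in zip(rows, df[col]):
            try:
                v = float(raw)
            except (TypeError, ValueError) as exc:
                raise ValidationError(
                    f"{path}: non-numeric cell at row {cname!r}, column {col!r}: {raw!r}"
                ) from exc
            if not math.isfinite(v) or v < 0:
                raise ValidationError(
                    f"{path}: content at row {cname!r}, column {col!r} must be finite "
                    f"and >= 0, got {v!r}"
                )
            contents[cname] = v
        out[str(col)] = AminoAcidVector(contents)
    return out


def write_aa_table(vectors: Mapping[str, AminoAcidVector], path, sep: str = ",") -> None:
    """Write per-diet amino-acid vectors as a delimited table (full precision).

    Inverse of :func:`read_aa_table`: a write-then-read round trip
    reproduces every content exactly (values are serialised with ``repr``
    precision).
    """
    names: list[str] = []
    for v in vectors.values():
        for a in v:
            if a not in names:
                names.append(a)
    names.sort(key=lambda a: CANONICAL_AA.index(a))
    df = pd.DataFrame(
        {diet: [vec.values.get(a, float("nan")) for a in names] for diet, vec in vectors.items()},
        index=pd.Index(names, name="amino_acid"),
    )
    df.to_csv(path, sep=sep, float_format=None)


def read_requirements(path, sep: str | None = None) -> RequirementSet:
    """Read a requirement table with columns ``amino_acid, requirement[, source]``."""
    try:
        df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty table") from exc
    if "amino_acid" not in df.columns or "requirement" not in df.columns:
        raise ValidationError(f"{path}: expected columns 'amino_acid' and 'requirement'")
    reqs = dict(zip(df["amino_acid"], df["requirement"]))
    sources = dict(zip(df["amino_acid"], df["source"])) if "source" in df.columns else {}
    return RequirementSet(reqs, sources)
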