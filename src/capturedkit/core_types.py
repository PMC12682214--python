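"""Domain enumerations, record types and the bundled Medan market fixture.

The CAPTURED target-suitability framework scores each species on a set of
supply-side (opportunity) and demand-side (consumer) variables derived from
its ecology, legal status and observed trade attributes.  Every enumeration
here carries the ordinal score the framework assigns to that category; the
composite scoring formulas live in :mod:`capturedkit.scoring`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Optional

import pandas as pd

__all__ = [
    "BodySizeClass",
    "ThreatStatus",
    "PopulationTrend",
    "HabitatClass",
    "Locomotion",
    "DielActivity",
    "TrophicGuild",
    "AgeGroupTraded",
    "SpeciesTraits",
    "ScoreProfile",
    "MarketDataset",
    "MedanFixture",
    "classify_body_size",
    "load_medan_fixture",
    "ValidationError",
    "FixtureIntegrityError",
]


class ValidationError(ValueError):
    """Raised when an input value violates a domain precondition."""


class FixtureIntegrityError(RuntimeError):
    """Raised when the bundled fixture fails its internal consistency checks."""


class BodySizeClass(str, Enum):
    """Body-size category; smaller primates are more concealable (score 3)."""

    SMALL = "small"
    MEDIUM = "medium"
    LARGE = "large"

    @property
    def score(self) -> int:
        return {"small": 3, "medium": 2, "large": 1}[self.value]


class ThreatStatus(str, Enum):
    """IUCN Red List category, ordered Least Concern -> Critically Endangered.

    ``abundance_rank`` (LC=5 ... CR=1) feeds the abundance score;
    ``rarity_rank`` (LC=1 ... CR=5) feeds conservation value.  The two ranks
    are complements: abundance_rank + rarity_rank == 6 for every status.
    """

    LC = "LC"
    NT = "NT"
    VU = "VU"
    EN = "EN"
    CR = "CR"

    @property
    def rarity_rank(self) -> int:
        return {"LC": 1, "NT": 2, "VU": 3, "EN": 4, "CR": 5}[self.value]

    @property
    def abundance_rank(self) -> int:
        return 6 - self.rarity_rank


class PopulationTrend(str, Enum):
    DECREASING = "decreasing"
    STABLE = "stable"
    INCREASING = "increasing"

    @property
    def score(self) -> int:
        return {"decreasing": 1, "stable": 2, "increasing": 3}[self.value]


class HabitatClass(str, Enum):
    """Habitat category scaled by difficulty of trapper access (wetland hardest)."""

    WETLAND = "wetland"
    FOREST = "forest"
    SHRUBLAND_GRASSLAND = "shrubland_grassland"
    ANTHROPOGENIC = "anthropogenic"

    @property
    def access_score(self) -> int:
        return {
            "wetland": 1,
            "forest": 2,
            "shrubland_grassland": 3,
            "anthropogenic": 4,
        }[self.value]


class Locomotion(str, Enum):
    ARBOREAL = "arboreal"
    BOTH = "both"
    TERRESTRIAL = "terrestrial"

    @property
    def score(self) -> int:
        return {"arboreal": 1, "both": 2, "terrestrial": 3}[self.value]


class DielActivity(str, Enum):
    """Daily activity pattern. Binary here: cathemeral activity is not
    documented among Indonesian primates, so adapters targeting other regions
    must extend this enum themselves."""

    NOCTURNAL = "nocturnal"
    DIURNAL = "diurnal"

    @property
    def score(self) -> int:
        return {"nocturnal": 1, "diurnal": 2}[self.value]


class TrophicGuild(str, Enum):
    """Dietary guild, used as a proxy for dietary flexibility in captivity."""

    GUMMIVORE = "gummivore"
    FRUGIVORE = "frugivore"
    FOLIVORE = "folivore"
    INSECTIVORE = "insectivore"
    OMNIVORE = "omnivore"
    FOLIVORE_FRUGIVORE = "folivore_frugivore"

    @property
    def flexibility_score(self) -> int:
        return {
            "gummivore": 1,
            "frugivore": 2,
            "folivore": 2,
            "insectivore": 2,
            "omnivore": 3,
            "folivore_frugivore": 3,
        }[self.value]


class AgeGroupTraded(str, Enum):
    MOSTLY_ADULTS = "mostly_adults"
    EQUAL_MIX = "equal_mix"
    MOSTLY_NONADULTS = "mostly_nonadults"

    @property
    def score(self) -> int:
        return {"mostly_adults": 1, "equal_mix": 2, "mostly_nonadults": 3}[self.value]


def classify_body_size(mass_kg: float) -> BodySizeClass:
    """Map mean adult body mass (kg) to a size class.

    Intervals are half-open and closed at the upper edge: small = [0.03, 5.0],
    medium = (5.0, 10.0], large = (10.0, inf), so every mass >= 0.03 kg is
    classifiable.

    Raises
    ------
    ValidationError
        If ``mass_kg`` is non-finite or below 0.03 kg (lighter than any primate).
    """
    if not isinstance(mass_kg, (int, float)) or isinstance(mass_kg, bool):
        raise ValidationError(f"mass_kg must be a real number, got {mass_kg!r}")
    if not math.isfinite(mass_kg) or mass_kg < 0.03:
        raise ValidationError(f"mass_kg must be finite and >= 0.03 kg, got {mass_kg!r}")
    if mass_kg <= 5.0:
        return BodySizeClass.SMALL
    if mass_kg <= 10.0:
        return BodySizeClass.MEDIUM
    return BodySizeClass.LARGE


@dataclass
class SpeciesTraits:
    """Raw biological, legal and trade attributes for one species.

    These are the inputs to every framework score.  Species are keyed by
    ``scientific_name`` (case-sensitive exact match); common names are
    display-only.  Optional fields left as ``None`` propagate into missing
    score markers rather than errors.
    """

    scientific_name: str
    common_name: str = ""
    mean_body_mass_kg: Optional[float] = None
    body_size_class: Optional[BodySizeClass] = None
    legally_trappable: bool = False
    threat_status: ThreatStatus = ThreatStatus.LC
    population_trend: Optional[PopulationTrend] = None
    habitats_major_importance: frozenset[HabitatClass] = frozenset()
    on_focal_island: bool = True
    endemic_to_focal_country: bool = False
    locomotion: Locomotion = Locomotion.ARBOREAL
    diel: DielActivity = DielActivity.DIURNAL
    group_living: bool = True
    trophic_guild: TrophicGuild = TrophicGuild.FRUGIVORE
    teeth_removed_in_trade: bool = False
    n_markets_found: Optional[int] = None
    uses_after_purchase: frozenset[str] = frozenset()
    age_group_traded: Optional[AgeGroupTraded] = None
    average_price: Optional[float] = None
    ecological_value: bool = False
    symbolic_value: bool = False

    def __post_init__(self) -> None:
        if not self.scientific_name:
            raise ValidationError("scientific_name must be non-empty")
        if self.mean_body_mass_kg is None and self.body_size_class is None:
            raise ValidationError(
                f"{self.scientific_name}: need mean_body_mass_kg or body_size_class"
            )
        if self.mean_body_mass_kg is not None:
            derived = classify_body_size(self.mean_body_mass_kg)
            if self.body_size_class is None:
                self.body_size_class = derived
            elif self.body_size_class is not derived:
                raise ValidationError(
                    f"{self.scientific_name}: body_size_class {self.body_size_class.value} "
                    f"inconsistent with mass {self.mean_body_mass_kg} kg ({derived.value})"
                )
        self.habitats_major_importance = frozenset(self.habitats_major_importance)
        self.uses_after_purchase = frozenset(self.uses_after_purchase)
        if self.n_markets_found is not None and self.n_markets_found < 0:
            raise ValidationError(f"{self.scientific_name}: n_markets_found < 0")
        if self.average_price is not None and self.average_price < 0:
            raise ValidationError(f"{self.scientific_name}: average_price < 0")

    @property
    def size_class(self) -> BodySizeClass:
        assert self.body_size_class is not None  # guaranteed by __post_init__
        return self.body_size_class


#: Declared inclusive range of each framework variable (default abundance mode).
SCORE_RANGES: dict[str, tuple[float, float]] = {
    "concealability": (1, 4),
    "abundance": (1, 8),  # 2..8 in composite mode, 1..5 in medan_compat
    "habitat_access": (1, 10),
    "focal_island": (0, 1),
    "removability": (2, 6),
    "teeth_removal": (0, 1),
    "replaceability": (0, math.inf),
    "success_in_captivity": (1, 4),
    "multiple_uses": (0, 1),
    "enjoyability": (2, 6),
    "economic_value": (0, math.inf),
    "ecological_value": (0, 1),
    "conservation_value": (1, 6),
    "symbolic_value": (0, 1),
}


@dataclass
class ScoreProfile:
    """Per-species vector of framework variable scores.

    ``None`` marks a variable that could not be computed; ``missing_reasons``
    records why.  Downstream matrix assembly drops any variable that is
    missing for any species (never imputes).
    """

    scientific_name: str
    concealability: Optional[int] = None
    abundance: Optional[int] = None
    habitat_access: Optional[int] = None
    focal_island: Optional[int] = None
    removability: Optional[int] = None
    teeth_removal: Optional[int] = None
    replaceability: Optional[int] = None
    success_in_captivity: Optional[int] = None
    multiple_uses: Optional[int] = None
    enjoyability: Optional[int] = None
    economic_value: Optional[float] = None
    ecological_value: Optional[int] = None
    conservation_value: Optional[int] = None
    symbolic_value: Optional[int] = None
    missing_reasons: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (lo, hi) in SCORE_RANGES.items():
            v = getattr(self, name)
            if v is not None and not (lo <= v <= hi):
                raise ValidationError(
                    f"{self.scientific_name}: {name}={v} outside [{lo}, {hi}]"
                )

    def as_dict(self) -> dict[str, Optional[float]]:
        return {name: getattr(self, name) for name in SCORE_RANGES}


@dataclass
class MarketDataset:
    """Observed individual counts per species from market surveys."""

    records: list[tuple[str, int]]
    n_surveys: Optional[int] = None
    n_markets: Optional[int] = None
    period: Optional[str] = None

    def __post_init__(self) -> None:
        names = [name for name, _ in self.records]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate species names in market records")
        if any(count < 0 for _, count in self.records):
            raise ValidationError("market counts must be non-negative")

    @property
    def species(self) -> list[str]:
        return [name for name, _ in self.records]

    @property
    def counts(self) -> dict[str, int]:
        return dict(self.records)

    @property
    def total(self) -> int:
        return sum(count for _, count in self.records)


@dataclass
class MedanFixture:
    """Bundled worked example: 10 primate species observed in the urban
    wildlife markets of Medan, North Sumatra, over 66 surveys of 3 markets
    (1997-2008), with their framework scores and market counts.

    ``iucn_status_at_study`` is the Red List status reported at the time of
    the surveys and is the one used in all score reproduction;
    ``iucn_status_2022`` is informational only.
    """

    traits: list[SpeciesTraits]
    scores: list[ScoreProfile]
    counts: MarketDataset
    iucn_status_at_study: dict[str, ThreatStatus]
    iucn_status_2022: dict[str, ThreatStatus]

    def __post_init__(self) -> None:
        if len(self.traits) != 10 or len(self.scores) != 10:
            raise FixtureIntegrityError("fixture must contain exactly 10 species")
        if self.counts.total != 1953:
            raise FixtureIntegrityError(
                f"fixture total count is {self.counts.total}, expected 1953"
            )
        t_names = [t.scientific_name for t in self.traits]
        s_names = [s.scientific_name for s in self.scores]
        if t_names != s_names or t_names != self.counts.species:
            raise FixtureIntegrityError("species lists disagree across fixture parts")


_DATA_PKG = "capturedkit.data"

_BOOL = {"true": True, "false": False, "1": True, "0": False}


def _parse_bool(token: str, context: str) -> bool:
    try:
        return _BOOL[str(token).strip().lower()]
    except KeyError:
        raise ValidationError(f"{context}: cannot parse boolean from {token!r}") from None


def _parse_set(cell: object) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
        return frozenset()
    return frozenset(tok.strip() for tok in str(cell).split(";") if tok.strip())


def traits_from_row(row: dict, context: str = "") -> SpeciesTraits:
    """Build a :class:`SpeciesTraits` from one CSV row (dict of header->cell)."""

    def opt(key: str):
        v = row.get(key)
        if v is None or v == "" or (isinstance(v, float) and math.isnan(v)):
            return None
        return v

    ctx = context or str(row.get("scientific_name", "?"))
    try:
        mass = opt("mean_body_mass_kg")
        trend = opt("population_trend")
        age = opt("age_group_traded")
        n_markets = opt("n_markets_found")
        price = opt("average_price")
        return SpeciesTraits(
            scientific_name=str(row["scientific_name"]),
            common_name=str(row.get("common_name", "") or ""),
            mean_body_mass_kg=float(mass) if mass is not None else None,
            legally_trappable=_parse_bool(row["legally_trappable"], ctx),
            threat_status=ThreatStatus(str(row["threat_status"]).strip()),
            population_trend=PopulationTrend(str(trend).strip()) if trend else None,
            habitats_major_importance=frozenset(
                HabitatClass(tok) for tok in _parse_set(row.get("habitats_major_importance"))
            ),
            on_focal_island=_parse_bool(row["on_focal_island"], ctx),
            endemic_to_focal_country=_parse_bool(row["endemic_to_focal_country"], ctx),
            locomotion=Locomotion(str(row["locomotion"]).strip()),
            diel=DielActivity(str(row["diel"]).strip()),
            group_living=_parse_bool(row["group_living"], ctx),
            trophic_guild=TrophicGuild(str(row["trophic_guild"]).strip()),
            teeth_removed_in_trade=_parse_bool(row["teeth_removed_in_trade"], ctx),
            n_markets_found=int(n_markets) if n_markets is not None else None,
            uses_after_purchase=_parse_set(row.get("uses_after_purchase")),
            age_group_traded=AgeGroupTraded(str(age).strip()) if age else None,
            average_price=float(price) if price is not None else None,
            ecological_value=_parse_bool(row["ecological_value"], ctx),
            symbolic_value=_parse_bool(row["symbolic_value"], ctx),
        )
    except (KeyError, ValueError) as exc:
        if isinstance(exc, ValidationError):
            raise
        raise ValidationError(f"{ctx}: {exc}") from exc


def load_medan_fixture() -> MedanFixture:
    """Load and validate the bundled Medan (1997-2008) worked example.

    Raises
    ------
    FixtureIntegrityError
        If the bundled CSVs fail any invariant (species counts, total of
        1953 individuals, score ranges).
    """
    try:
        with resources.files(_DATA_PKG).joinpath("medan_traits.csv").open("r") as fh:
            traits_df = pd.read_csv(fh, dtype=str)
        with resources.files(_DATA_PKG).joinpath("medan_scores.csv").open("r") as fh:
            scores_df = pd.read_csv(fh)
    except (OSError, pd.errors.ParserError) as exc:
        raise FixtureIntegrityError(f"cannot read bundled fixture: {exc}") from exc

    try:
        traits = [traits_from_row(row) for row in traits_df.to_dict("records")]
        status_study = {
            t.scientific_name: t.threat_status for t in traits
        }
        status_2022 = {
            str(r["scientific_name"]): ThreatStatus(str(r["iucn_status_2022"]).strip())
            for r in traits_df.to_dict("records")
        }
        score_cols = [c for c in scores_df.columns if c not in ("scientific_name", "count")]
        scores = [
            ScoreProfile(
                scientific_name=str(r["scientific_name"]),
                **{c: int(r[c]) for c in score_cols},
            )
            for r in scores_df.to_dict("records")
        ]
        counts = MarketDataset(
            records=[(str(r["scientific_name"]), int(r["count"])) for r in scores_df.to_dict("records")],
            n_surveys=66,
            n_markets=3,
            period="1997-2008",
        )
    except (ValidationError, ValueError, KeyError) as exc:
        raise FixtureIntegrityError(f"bundled fixture is corrupt: {exc}") from exc

    return MedanFixture(
        traits=traits,
        scores=scores,
        counts=counts,
        iucn_status_at_study=status_study,
        iucn_status_2022=status_2022,
    )
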