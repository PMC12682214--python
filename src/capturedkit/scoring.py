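"""Pure scoring operations for every framework variable, plus matrix assembly.

Each ``score_*`` function implements one measurement of the quantitative
framework as a deterministic function of raw traits.  ``score_species``
composes them into a :class:`~capturedkit.core_types.ScoreProfile`;
``build_score_matrix`` stacks profiles into a complete species x variable
matrix, dropping (never imputing) any variable missing for any species.

Abundance has two modes.  The framework's declared composite is population
trend + threat rank on a 2-8 scale (``composite`` mode, the default).  The Medan
worked example's printed abundance column, however, equals the threat-status
abundance rank alone (LC=5 ... CR=1); ``medan_compat`` mode reproduces that
and is what fixture validation uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .core_types import (
    SCORE_RANGES,
    AgeGroupTraded,
    BodySizeClass,
    DielActivity,
    HabitatClass,
    Locomotion,
    PopulationTrend,
    ScoreProfile,
    SpeciesTraits,
    ThreatStatus,
    TrophicGuild,
    ValidationError,
)

__all__ = [
    "AbundanceMode",
    "MissingDataError",
    "AnalysisInfeasibleError",
    "ScoreMatrix",
    "CANONICAL_VARIABLE_ORDER",
    "score_concealability",
    "score_abundance",
    "score_habitat_access",
    "score_focal_island",
    "score_removability",
    "score_processability",
    "score_replaceability",
    "score_success_in_captivity",
    "score_multiple_uses",
    "score_enjoyability",
    "score_conservation_value",
    "score_binary_value",
    "score_economic_value",
    "score_species",
    "build_score_matrix",
]

AbundanceMode = Literal["composite", "medan_compat"]


class MissingDataError(ValueError):
    """An input required by a scoring formula is absent."""


class AnalysisInfeasibleError(ValueError):
    """The requested computation is impossible on the given data shape."""


#: Column order used by :func:`build_score_matrix`: the worked example's
#: twelve variables left-to-right, then any extras alphabetically.
CANONICAL_VARIABLE_ORDER: tuple[str, ...] = (
    "concealability",
    "abundance",
    "habitat_access",
    "focal_island",
    "removability",
    "teeth_removal",
    "success_in_captivity",
    "multiple_uses",
    "enjoyability",
    "ecological_value",
    "conservation_value",
    "symbolic_value",
)


def score_concealability(legally_trappable: bool, size: BodySizeClass) -> int:
    """Concealability, 1-4 (4 most concealable): legal-trapping indicator
    plus body-size score.  Species trappable under quota (not fully
    protected) and small-bodied species are easier to hide in a market."""
    return int(legally_trappable) + size.score


def score_abundance(
    trend: Optional[PopulationTrend],
    status: ThreatStatus,
    mode: AbundanceMode = "composite",
) -> int:
    """Abundance: in ``composite`` mode trend score + threat abundance rank
    (2-8, 8 most abundant); in ``medan_compat`` mode the threat abundance
    rank alone (1-5)."""
    if mode == "composite":
        if trend is None:
            raise MissingDataError("population_trend required for composite abundance")
        return trend.score + status.abundance_rank
    if mode == "medan_compat":
        return status.abundance_rank
    raise ValidationError(f"unknown abundance mode {mode!r}")


def score_habitat_access(habitats: Iterable[HabitatClass]) -> int:
    """Habitat access, 1-10: sum of access scores over the distinct habitat
    classes of major importance to the species (max 10 when all four are
    occupied).  More, and more accessible, habitats mean easier trapping."""
    classes = frozenset(habitats)
    if not classes:
        raise MissingDataError("habitat set is empty")
    return sum(h.access_score for h in classes)


def score_focal_island(on_focal_island: bool) -> int:
    """Focal-island indicator: 1 if the species naturally occurs on the
    island hosting the market (a proxy for distance to market)."""
    return int(on_focal_island)


def score_removability(loco: Locomotion, diel: DielActivity, group_living: bool) -> int:
    """Removability, 2-6 (6 most removable): locomotion + diel activity +
    group-living indicator.  Terrestrial, diurnal, group-living primates are
    easiest to capture."""
    return loco.score + diel.score + int(group_living)


def score_processability(teeth_removed_in_trade: bool) -> int:
    """Teeth-removal indicator: 1 if most traded individuals have their
    teeth removed (a form of processing for sale)."""
    return int(teeth_removed_in_trade)


def score_replaceability(n_markets: int) -> int:
    """Replaceability: the number of markets where the species is found
    (validated passthrough)."""
    if n_markets < 0:
        raise ValidationError(f"n_markets must be >= 0, got {n_markets}")
    return int(n_markets)


def score_success_in_captivity(guild: TrophicGuild, teeth_removed: bool) -> int:
    """Success in captivity, 1-4 (4 lowest mortality risk): dietary
    flexibility plus 1 if teeth are NOT removed.  Teeth removal predisposes
    to infection and premature death, lowering usability."""
    return guild.flexibility_score + (0 if teeth_removed else 1)


def score_multiple_uses(uses: Iterable[str]) -> int:
    """Multiple-uses indicator: 1 if more than one distinct potential use
    after live purchase (pet, food, medicine, ...)."""
    return int(len(frozenset(uses)) > 1)


def score_enjoyability(size: BodySizeClass, age: AgeGroupTraded) -> int:
    """Enjoyability, 2-6 (6 most enjoyable): body-size score + traded age
    group score.  Smaller, younger animals are perceived as more enjoyable."""
    return size.score + age.score


def score_conservation_value(status: ThreatStatus, endemic: bool) -> int:
    """Conservation value / rarity, 1-6 (6 rarest): threat rarity rank plus
    endemism indicator."""
    return status.rarity_rank + int(endemic)


def score_binary_value(flag: bool) -> int:
    """Shared 0/1 indicator used for ecological value and symbolic value."""
    return int(flag)


def score_economic_value(prices: Sequence[float]) -> float:
    """Economic value: average observed price."""
    if len(prices) == 0:
        raise MissingDataError("no prices available")
    if any(p < 0 for p in prices):
        raise ValidationError("prices must be non-negative")
    return fmean(prices)


def score_species(
    traits: SpeciesTraits, abundance_mode: AbundanceMode = "composite"
) -> ScoreProfile:
    """Score every framework variable for one species.

    Variables whose inputs are absent are left ``None`` with the reason in
    ``missing_reasons``; the profile is always returned, never aborted.
    """
    missing: dict[str, str] = {}

    if abundance_mode == "composite" and traits.population_trend is None:
        abundance = None
        missing["abundance"] = "population_trend unavailable (composite mode)"
    else:
        abundance = score_abundance(
            traits.population_trend, traits.threat_status, abundance_mode
        )

    try:
        habitat_access = score_habitat_access(traits.habitats_major_importance)
    except MissingDataError as exc:
        habitat_access = None
        missing["habitat_access"] = str(exc)

    if traits.n_markets_found is None:
        replaceability = None
        missing["replaceability"] = "max no. of markets unavailable"
    else:
        replaceability = score_replaceability(traits.n_markets_found)

    if traits.age_group_traded is None:
        enjoyability = None
        missing["enjoyability"] = "age group traded unavailable"
    else:
        enjoyability = score_enjoyability(traits.size_class, traits.age_group_traded)

    if traits.average_price is None:
        economic_value = None
        missing["economic_value"] = "average price unavailable"
    else:
        economic_value = score_economic_value([traits.average_price])

    return ScoreProfile(
        scientific_name=traits.scientific_name,
        concealability=score_concealability(traits.legally_trappable, traits.size_class),
        abundance=abundance,
        habitat_access=habitat_access,
        focal_island=score_focal_island(traits.on_focal_island),
        removability=score_removability(traits.locomotion, traits.diel, traits.group_living),
        teeth_removal=score_processability(traits.teeth_removed_in_trade),
        replaceability=replaceability,
        success_in_captivity=score_success_in_captivity(
            traits.trophic_guild, traits.teeth_removed_in_trade
        ),
        multiple_uses=score_multiple_uses(traits.uses_after_purchase),
        enjoyability=enjoyability,
        economic_value=economic_value,
        ecological_value=score_binary_value(traits.ecological_value),
        conservation_value=score_conservation_value(
            traits.threat_status, traits.endemic_to_focal_country
        ),
        symbolic_value=score_binary_value(traits.symbolic_value),
        missing_reasons=missing,
    )


@dataclass
class ScoreMatrix:
    """Complete species x variable score matrix.

    Columns with any missing datum are excluded and recorded in
    ``dropped_variables`` as (name, reason) pairs.
    """

    species: list[str]
    variables: list[str]
    values: np.ndarray
    dropped_variables: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.species), len(self.variables)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.species)} species x {len(self.variables)} variables"
            )
        if np.isnan(self.values).any():
            raise ValidationError("score matrix contains missing cells")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species, columns=self.variables)


def build_score_matrix(profiles: Sequence[ScoreProfile]) -> ScoreMatrix:
    """Assemble profiles into a complete matrix.

    Any variable that is missing for at least one species is dropped for all
    species and logged with the first missing species' reason.  Requires at
    least two species.
    """
    if len(profiles) < 2:
        raise AnalysisInfeasibleError(
            f"need at least 2 species to build a score matrix, got {len(profiles)}"
        )
    species = [p.scientific_name for p in profiles]
    if len(set(species)) != len(species):
        raise ValidationError("duplicate species in profiles")

    all_vars = list(CANONICAL_VARIABLE_ORDER) + sorted(
        set(SCORE_RANGES) - set(CANONICAL_VARIABLE_ORDER)
    )
    kept: list[str] = []
    dropped: list[tuple[str, str]] = []
    for var in all_vars:
        missing_in = [p for p in profiles if getattr(p, var) is None]
        if missing_in:
            p0 = missing_in[0]
            reason = p0.missing_reasons.get(var, "value missing")
            dropped.append((var, f"{p0.scientific_name}: {reason}"))
        else:
            kept.append(var)

    values = np.array([[float(getattr(p, var)) for var in kept] for p in profiles])
    return ScoreMatrix(species=species, variables=kept, values=values, dropped_variables=dropped)
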