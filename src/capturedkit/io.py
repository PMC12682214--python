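"""CSV readers/writers for trait tables, market counts and score matrices.

Dialect is fixed for bit-exact interchange: UTF-8, comma delimiter, header
row required, "." decimal separator; set-valued cells (habitats, uses) use
";" as the inner separator.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_types import (
    MarketDataset,
    SpeciesTraits,
    ValidationError,
    traits_from_row,
)
from .scoring import ScoreMatrix

__all__ = [
    "SchemaError",
    "read_traits_csv",
    "write_traits_csv",
    "read_counts_csv",
    "write_counts_csv",
    "read_score_matrix_csv",
    "write_score_matrix_csv",
]

TRAIT_COLUMNS = [
    "scientific_name",
    "common_name",
    "mean_body_mass_kg",
    "legally_trappable",
    "threat_status",
    "population_trend",
    "habitats_major_importance",
    "on_focal_island",
    "endemic_to_focal_country",
    "locomotion",
    "diel",
    "group_living",
    "trophic_guild",
    "teeth_removed_in_trade",
    "n_markets_found",
    "uses_after_purchase",
    "age_group_traded",
    "average_price",
    "ecological_value",
    "symbolic_value",
]


class SchemaError(ValueError):
    """A CSV file violates the documented schema; message lists each bad
    row with its line number and field."""


def read_traits_csv(path: str | Path) -> list[SpeciesTraits]:
    """Read a species trait table; collects all row errors before raising."""
    try:
        df = pd.read_csv(path, dtype=str)
    except (OSError, pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise SchemaError(f"{path}: {exc}") from exc
    required = set(TRAIT_COLUMNS) - {
        "common_name", "mean_body_mass_kg", "population_trend",
        "n_markets_found", "uses_after_purchase", "age_group_traded",
        "average_price",
    }
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise SchemaError(f"{path}: missing columns {sorted(missing_cols)}")

    traits, errors = [], []
    for i, row in enumerate(df.to_dict("records")):
        line = i + 2  # header is line 1
        try:
            traits.append(traits_from_row(row, context=f"line {line}"))
        except (ValidationError, ValueError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise SchemaError(f"{path}: {len(errors)} invalid row(s)\n" + "\n".join(errors))
    names = [t.scientific_name for t in traits]
    if len(set(names)) != len(names):
        raise SchemaError(f"{path}: duplicate scientific names")
    return traits


def write_traits_csv(traits: Sequence[SpeciesTraits], path: str | Path) -> None:
    rows = []
    for t in traits:
        rows.append({
            "scientific_name": t.scientific_name,
            "common_name": t.common_name,
            "mean_body_mass_kg": t.mean_body_mass_kg,
            "legally_trappable": str(t.legally_trappable).lower(),
            "threat_status": t.threat_status.value,
            "population_trend": t.population_trend.value if t.population_trend else "",
            "habitats_major_importance": ";".join(
                sorted(h.value for h in t.habitats_major_importance)
            ),
            "on_focal_island": str(t.on_focal_island).lower(),
            "endemic_to_focal_country": str(t.endemic_to_focal_country).lower(),
            "locomotion": t.locomotion.value,
            "diel": t.diel.value,
            "group_living": str(t.group_living).lower(),
            "trophic_guild": t.trophic_guild.value,
            "teeth_removed_in_trade": str(t.teeth_removed_in_trade).lower(),
            "n_markets_found": t.n_markets_found if t.n_markets_found is not None else "",
            "uses_after_purchase": ";".join(sorted(t.uses_after_purchase)),
            "age_group_traded": t.age_group_traded.value if t.age_group_traded else "",
            "average_price": t.average_price if t.average_price is not None else "",
            "ecological_value": str(t.ecological_value).lower(),
            "symbolic_value": str(t.symbolic_value).lower(),
        })
    pd.DataFrame(rows, columns=TRAIT_COLUMNS).to_csv(path, index=False)


def read_counts_csv(path: str | Path) -> MarketDataset:
    """Read a market-count table: columns ``scientific_name, count``."""
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise SchemaError(f"{path}: {exc}") from exc
    if not {"scientific_name", "count"} <= set(df.columns):
        raise SchemaError(f"{path}: need columns scientific_name, count")
    records = []
    for i, row in df.iterrows():
        count = row["count"]
        if pd.isna(count) or float(count) != int(count) or int(count) < 0:
            raise SchemaError(
                f"{path}: line {i + 2}: count must be a non-negative integer, got {count!r}"
            )
        records.append((str(row["scientific_name"]), int(count)))
    try:
        return MarketDataset(records=records)
    except ValidationError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_counts_csv(counts: MarketDataset, path: str | Path) -> None:
    pd.DataFrame(counts.records, columns=["scientific_name", "count"]).to_csv(
        path, index=False
    )


def write_score_matrix_csv(matrix: ScoreMatrix, path: str | Path) -> None:
    """Write the score matrix with species as the first column; integral
    values are written without a decimal point."""
    df = matrix.to_dataframe()
    out = df.reset_index(names="scientific_name")
    for col in matrix.variables:
        if np.all(np.mod(df[col].to_numpy(), 1) == 0):
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False)


def read_score_matrix_csv(path: str | Path) -> ScoreMatrix:
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise SchemaError(f"{path}: {exc}") from exc
    if "scientific_name" not in df.columns:
        raise SchemaError(f"{path}: first column must be scientific_name")
    species = df["scientific_name"].astype(str).tolist()
    variables = [c for c in df.columns if c != "scientific_name"]
    values = df[variables].to_numpy(dtype=float)
    if math.prod(values.shape) and pd.isna(values).any():
        raise SchemaError(f"{path}: score matrix contains missing cells")
    return ScoreMatrix(species=species, variables=variables, values=values)
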