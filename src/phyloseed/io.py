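"""CSV dialects shared by the pipeline stages.

All tables are plain UTF-8 CSV with a header row and '.' decimals:

* measurements: ``taxon,voucher,length_mm,width_mm,thickness_mm``
* trait: ``species,value``
* geography: ``species,<AREA>,...`` with 0/1 entries
* multipliers: square matrix with area codes as header row and first column
* binary traits: ``species,<trait>,...`` with 0/1 entries
* species map: ``accession,species``
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .morphometrics import SeedRecord, records_from_dataframe, records_to_dataframe

__all__ = [
    "read_measurements",
    "write_measurements",
    "read_trait",
    "write_trait",
    "read_geography",
    "write_geography",
    "read_multipliers",
    "write_multipliers",
    "read_binary_traits",
    "write_binary_traits",
    "read_species_map",
]


def read_measurements(path) -> list[SeedRecord]:
    return records_from_dataframe(pd.read_csv(path))


def write_measurements(records, path) -> None:
    records_to_dataframe(records).to_csv(path, index=False)


def read_trait(path) -> dict[str, float]:
    df = pd.read_csv(path)
    if not {"species", "value"} <= set(df.columns):
        raise ValueError("trait CSV must have columns species,value")
    return dict(zip(df["species"].astype(str), df["value"].astype(float)))


def write_trait(trait: Mapping[str, float], path) -> None:
    pd.DataFrame(
        {"species": list(trait), "value": list(trait.values())}
    ).to_csv(path, index=False)


def read_geography(path) -> tuple[dict[str, frozenset[str]], tuple[str, ...]]:
    """Returns (species -> area set, area codes in column order)."""
    df = pd.read_csv(path)
    if df.columns[0] != "species":
        raise ValueError("geography CSV must start with a 'species' column")
    areas = tuple(df.columns[1:])
    ranges = {}
    for row in df.itertuples(index=False):
        sp = str(row[0])
        present = frozenset(a for a, v in zip(areas, row[1:]) if int(v) == 1)
        if not present:
            raise ValueError(f"species {sp!r} occupies no area")
        ranges[sp] = present
    return ranges, areas


def write_geography(ranges: Mapping[str, frozenset[str]], areas, path) -> None:
    rows = [
        {"species": sp, **{a: int(a in r) for a in areas}}
        for sp, r in ranges.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_multipliers(path) -> tuple[np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("multiplier CSV must be square with matching row/col codes")
    return df.to_numpy(dtype=float), tuple(df.columns)


def write_multipliers(matrix: np.ndarray, areas, path) -> None:
    pd.DataFrame(matrix, index=list(areas), columns=list(areas)).to_csv(path)


def read_binary_traits(path) -> dict[str, dict[str, int]]:
    """Returns trait name -> (species -> 0/1)."""
    df = pd.read_csv(path)
    if df.columns[0] != "species":
        raise ValueError("binary-trait CSV must start with a 'species' column")
    out: dict[str, dict[str, int]] = {}
    for trait in df.columns[1:]:
        col = {}
        for sp, v in zip(df["species"].astype(str), df[trait]):
            if pd.isna(v):
                continue
            if int(v) not in (0, 1):
                raise ValueError(f"trait {trait!r} value for {sp!r} must be 0/1")
            col[sp] = int(v)
        out[trait] = col
    return out


def write_binary_traits(traits: Mapping[str, Mapping[str, int]], path) -> None:
    species = sorted({sp for col in traits.values() for sp in col})
    rows = [
        {"species": sp, **{t: traits[t].get(sp, "") for t in traits}}
        for sp in species
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_species_map(path) -> dict[str, str]:
    df = pd.read_csv(path)
    if not {"accession", "species"} <= set(df.columns):
        raise ValueError("species map CSV must have columns accession,species")
    return dict(zip(df["accession"].astype(str), df["species"].astype(str)))
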