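"""Core data containers and delimited-text I/O for the trait pipeline.

The pipeline works on three kinds of tables: a station x species abundance
table (ind/m3) with station metadata, a station x environment table, and a
species x trait assignment table.  Trait assignments draw on a fixed
catalogue of four categorical traits (17 modalities in total) which are
one-hot encoded into the species x trait matrix used for clustering:

* body length class  -- small (<1 mm), medium (1-2 mm), large (2-5 mm),
  giant (>5 mm); class boundaries are half-open, lower-inclusive
* feeding type       -- active ambush, passive ambush, current, mixed
* trophic group      -- carnivore, omnivore, omnivore-carnivore,
  omnivore-herbivore, omnivore-detritivore
* reproductive mode  -- free spawner, egg brooding, parthenogenesis,
  alternation of generations

All files are comma-separated UTF-8 with "." decimals, one file per table
kind.  Abundances are individuals per cubic metre, obtained from net counts
with :func:`standardize_abundance`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SEASONS",
    "TRAITS",
    "TRAIT_COLUMNS",
    "ENV_VARIABLES",
    "ValidationError",
    "Station",
    "AbundanceTable",
    "EnvTable",
    "TraitAssignment",
    "TraitMatrix",
    "body_length_class_from_mm",
    "standardize_abundance",
    "encode_traits",
    "read_abundance_csv",
    "write_abundance_csv",
    "read_env_csv",
    "write_env_csv",
    "read_traits_csv",
    "write_traits_csv",
]

SEASONS = ("spring", "summer", "autumn")

BODY_LENGTH = ("small", "medium", "large", "giant")
FEEDING = ("active_ambush", "passive_ambush", "current", "mixed")
TROPHIC = (
    "carnivore",
    "omnivore",
    "omnivore_carnivore",
    "omnivore_herbivore",
    "omnivore_detritivore",
)
REPRODUCTION = (
    "free_spawner",
    "egg_brooding",
    "parthenogenesis",
    "alternation_of_generations",
)

#: Trait catalogue in fixed column order: 4 body-length + 4 feeding +
#: 5 trophic + 4 reproductive modalities = 17 binary columns.
TRAITS: Mapping[str, tuple[str, ...]] = {
    "body_length": BODY_LENGTH,
    "feeding_type": FEEDING,
    "trophic_group": TROPHIC,
    "reproductive_mode": REPRODUCTION,
}

TRAIT_COLUMNS: tuple[str, ...] = tuple(
    f"{trait}:{modality}" for trait, modalities in TRAITS.items() for modality in modalities
)

#: Slices of TRAIT_COLUMNS belonging to each trait block.
TRAIT_BLOCKS: Mapping[str, slice] = {}
_start = 0
for _trait, _mods in TRAITS.items():
    TRAIT_BLOCKS[_trait] = slice(_start, _start + len(_mods))  # type: ignore[index]
    _start += len(_mods)
del _start, _trait, _mods

ENV_VARIABLES = ("SST", "SBT", "SSS", "SBS", "SChla", "BChla")

_STATION_META = ("station_id", "season", "latitude", "longitude", "tow_depth")


class ValidationError(ValueError):
    """A table violated one of its structural invariants."""


@dataclass(frozen=True)
class Station:
    """One sampling site of a seasonal cruise.

    ``tow_depth`` is the length of the vertical net haul in metres (from
    about 3 m above the bottom to the surface).
    """

    id: str
    season: str
    latitude: float
    longitude: float
    tow_depth: float

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ValidationError(
                f"station {self.id!r}: unknown season {self.season!r}; "
                f"expected one of {SEASONS}"
            )
        if not (self.tow_depth > 0 and math.isfinite(self.tow_depth)):
            raise ValidationError(
                f"station {self.id!r}: tow_depth must be positive, got {self.tow_depth}"
            )


def _check_matrix(values: np.ndarray, n_rows: int, n_cols: int, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.shape != (n_rows, n_cols):
        raise ValidationError(
            f"{what}: value matrix shape {values.shape} does not match "
            f"metadata ({n_rows} stations x {n_cols} columns)"
        )
    return values


@dataclass
class AbundanceTable:
    """Station x species abundance matrix in individuals per m3."""

    stations: list[Station]
    species: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_matrix(
            self.values, len(self.stations), len(self.species), "abundance table"
        )
        if len(set(self.species)) != len(self.species):
            raise ValidationError("abundance table: species labels are not unique")
        bad = np.argwhere(~np.isfinite(self.values) | (self.values < 0))
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"abundance table: invalid value {self.values[i, j]!r} at "
                f"station {self.stations[i].id!r}, species {self.species[j]!r}"
            )

    @property
    def seasons(self) -> list[str]:
        return [s.season for s in self.stations]

    def season_subset(self, season: str) -> "AbundanceTable":
        idx = [i for i, s in enumerate(self.stations) if s.season == season]
        return AbundanceTable(
            stations=[self.stations[i] for i in idx],
            species=list(self.species),
            values=self.values[idx, :],
        )

    def to_dataframe(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "station_id": [s.id for s in self.stations],
                "season": [s.season for s in self.stations],
                "latitude": [s.latitude for s in self.stations],
                "longitude": [s.longitude for s in self.stations],
                "tow_depth": [s.tow_depth for s in self.stations],
            }
        )
        vals = pd.DataFrame(self.values, columns=list(self.species))
        return pd.concat([meta, vals], axis=1)

    def equals(self, other: "AbundanceTable") -> bool:
        return (
            self.stations == other.stations
            and self.species == other.species
            and np.allclose(self.values, other.values, rtol=0, atol=1e-12)
        )


@dataclass
class EnvTable:
    """Station x environmental-variable matrix (SST, SBT, SSS, SBS, Chl a)."""

    stations: list[Station]
    variables: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_matrix(
            self.values, len(self.stations), len(self.variables), "environment table"
        )
        unknown = [v for v in self.variables if v not in ENV_VARIABLES]
        if unknown:
            raise ValidationError(f"environment table: unknown variables {unknown}")
        for j, var in enumerate(self.variables):
            if var in ("SChla", "BChla") and np.any(self.values[:, j] < 0):
                i = int(np.argmax(self.values[:, j] < 0))
                raise ValidationError(
                    f"environment table: negative {var} at station "
                    f"{self.stations[i].id!r}"
                )

    def to_dataframe(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "station_id": [s.id for s in self.stations],
                "season": [s.season for s in self.stations],
                "latitude": [s.latitude for s in self.stations],
                "longitude": [s.longitude for s in self.stations],
                "tow_depth": [s.tow_depth for s in self.stations],
            }
        )
        vals = pd.DataFrame(self.values, columns=list(self.variables))
        return pd.concat([meta, vals], axis=1)

    def equals(self, other: "EnvTable") -> bool:
        return (
            self.stations == other.stations
            and self.variables == other.variables
            and np.allclose(self.values, other.values, rtol=0, atol=1e-12)
        )


@dataclass(frozen=True)
class TraitAssignment:
    """One modality per trait for a single taxon."""

    species: str
    body_length: str
    feeding_type: str
    trophic_group: str
    reproductive_mode: str

    def __post_init__(self) -> None:
        for trait in TRAITS:
            value = getattr(self, trait)
            if value not in TRAITS[trait]:
                raise ValidationError(
                    f"species {self.species!r}: {value!r} is not a modality of "
                    f"{trait} (choose from {TRAITS[trait]})"
                )

    def modality(self, trait: str) -> str:
        return getattr(self, trait)


@dataclass
class TraitMatrix:
    """Species x binary trait-modality matrix (one-hot per trait block)."""

    species: list[str]
    values: np.ndarray
    columns: tuple[str, ...] = field(default=TRAIT_COLUMNS)

    def __post_init__(self) -> None:
        self.values = _check_matrix(
            self.values, len(self.species), len(TRAIT_COLUMNS), "trait matrix"
        )
        if len(set(self.species)) != len(self.species):
            raise ValidationError("trait matrix: species labels are not unique")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValidationError("trait matrix: values must be 0 or 1")
        for trait, block in TRAIT_BLOCKS.items():
            sums = self.values[:, block].sum(axis=1)
            bad = np.nonzero(sums != 1)[0]
            if bad.size:
                raise ValidationError(
                    f"trait matrix: species {self.species[int(bad[0])]!r} has "
                    f"{int(sums[bad[0]])} modalities set in block {trait!r} "
                    "(exactly one required)"
                )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.astype(int), index=list(self.species), columns=list(self.columns)
        )

    def modality_of(self, species: str, trait: str) -> str:
        """Decode the assigned modality of one trait for one species."""
        i = self.species.index(species)
        block = TRAIT_BLOCKS[trait]
        j = int(np.argmax(self.values[i, block]))
        return TRAITS[trait][j]


def body_length_class_from_mm(length_mm: float) -> str:
    """Map an adult body length in mm to its class.

    Boundaries are half-open and lower-inclusive: [0,1) small, [1,2) medium,
    [2,5) large, [5,inf) giant.
    """
    if not (length_mm > 0 and math.isfinite(length_mm)):
        raise ValidationError(f"body length must be positive, got {length_mm}")
    if length_mm < 1:
        return "small"
    if length_mm < 2:
        return "medium"
    if length_mm < 5:
        return "large"
    return "giant"


def standardize_abundance(count: float, tow_depth: float, mouth_area: float = 0.25) -> float:
    """Convert a net count to abundance in ind/m3.

    The filtered volume of a vertical haul is ``mouth_area * tow_depth``
    (WP2 net default mouth area 0.25 m2), so abundance is
    ``count / (mouth_area * tow_depth)``.
    """
    if count < 0:
        raise ValidationError(f"count must be non-negative, got {count}")
    if not tow_depth > 0:
        raise ValidationError(f"tow_depth must be positive, got {tow_depth}")
    if not mouth_area > 0:
        raise ValidationError(f"mouth_area must be positive, got {mouth_area}")
    return count / (mouth_area * tow_depth)


def encode_traits(assignments: Sequence[TraitAssignment]) -> TraitMatrix:
    """One-hot encode trait assignments into the species x trait matrix."""
    species = [a.species for a in assignments]
    if len(set(species)) != len(species):
        seen: set[str] = set()
        dup = next(s for s in species if s in seen or seen.add(s))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate species label {dup!r}")
    values = np.zeros((len(assignments), len(TRAIT_COLUMNS)))
    col_index = {c: j for j, c in enumerate(TRAIT_COLUMNS)}
    for i, a in enumerate(assignments):
        for trait in TRAITS:
            values[i, col_index[f"{trait}:{a.modality(trait)}"]] = 1.0
    return TraitMatrix(species=species, values=values)


# ---------------------------------------------------------------------------
# CSV I/O


def _read_station_meta(df: pd.DataFrame, path: str) -> list[Station]:
    missing = [c for c in _STATION_META if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing metadata columns {missing}")
    stations = []
    for _, row in df.iterrows():
        stations.append(
            Station(
                id=str(row["station_id"]),
                season=str(row["season"]),
                latitude=float(row["latitude"]),
                longitude=float(row["longitude"]),
                tow_depth=float(row["tow_depth"]),
            )
        )
    return stations


def read_abundance_csv(path: str) -> AbundanceTable:
    df = pd.read_csv(path)
    stations = _read_station_meta(df, str(path))
    species = [c for c in df.columns if c not in _STATION_META]
    return AbundanceTable(
        stations=stations, species=species, values=df[species].to_numpy(dtype=float)
    )


def write_abundance_csv(table: AbundanceTable, path: str) -> None:
    table.to_dataframe().to_csv(path, index=False)


def read_env_csv(path: str) -> EnvTable:
    df = pd.read_csv(path)
    stations = _read_station_meta(df, str(path))
    variables = [c for c in df.columns if c not in _STATION_META]
    return EnvTable(
        stations=stations, variables=variables, values=df[variables].to_numpy(dtype=float)
    )


def write_env_csv(table: EnvTable, path: str) -> None:
    table.to_dataframe().to_csv(path, index=False)


def read_traits_csv(path: str) -> list[TraitAssignment]:
    df = pd.read_csv(path)
    needed = ["species", *TRAITS]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return [
        TraitAssignment(
            species=str(row["species"]),
            body_length=str(row["body_length"]),
            feeding_type=str(row["feeding_type"]),
            trophic_group=str(row["trophic_group"]),
            reproductive_mode=str(row["reproductive_mode"]),
        )
        for _, row in df.iterrows()
    ]


def write_traits_csv(assignments: Iterable[TraitAssignment], path: str) -> None:
    rows = [
        {"species": a.species, **{trait: a.modality(trait) for trait in TRAITS}}
        for a in assignments
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
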