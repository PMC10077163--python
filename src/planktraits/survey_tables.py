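"""Published summary tables from the 2018 South Yellow Sea mesozooplankton
survey, transcribed as reference inputs.

The survey ran three seasonal cruises (spring: 11 stations, summer: 16,
autumn: 16) with a WP2 net (mouth area 0.25 m2, 200 um mesh).  Its printed
summary tables are used here as desk-scale inputs: seasonal mean abundance
per taxonomic component, the dominance index of the dominant species, the
trait-modality profiles of the eight functional groups, and seasonal
means/sds of the environmental variables.

Entries printed as "< 0.1" ind/m3 are stored as 0.05 (midpoint convention)
and listed in :data:`TABLE1_BELOW_DETECTION`; dominance entries printed as
"< 0.01" are stored as 0.005.  These stand-in values never decide any
reference comparison.  Surface/bottom salinity means are not printed in the
survey report (only the ordering SSS > SBS each season); the defaults here
are realistic shelf values respecting that ordering.
"""

from __future__ import annotations

__all__ = [
    "TABLE1_ABUNDANCE",
    "TABLE1_TOTALS",
    "TABLE1_BELOW_DETECTION",
    "TABLE2_DOMINANCE",
    "TABLE2_ABUNDANCE",
    "TABLE3_PROFILES",
    "TABLE3_GROUP_SIZES",
    "ENV_SEASONAL_MEAN",
    "ENV_SEASONAL_SD",
    "GROUP_ENV_COUPLING_SIGNS",
]

#: Seasonal mean abundance (ind/m3) per taxonomic component.  Missing keys
#: mean the component was not detected that season.
TABLE1_ABUNDANCE: dict[str, dict[str, float]] = {
    "spring": {
        "Hydromedusae": 1.6,
        "Cladocerans": 0.3,
        "Copepods": 1262.7,
        "Amphipods": 2.2,
        "Euphausiids": 0.5,
        "Decapods": 0.05,
        "Chaetognaths": 6.4,
        "Tunicates": 8.7,
        "Pelagic larvae": 285.9,
    },
    "summer": {
        "Hydromedusae": 22.3,
        "Siphonophorae": 32.4,
        "Ctenophores": 0.7,
        "Polychaetes": 0.05,
        "Ostracods": 0.05,
        "Cladocerans": 78.1,
        "Copepods": 1609.1,
        "Amphipods": 10.0,
        "Isopods": 0.05,
        "Cumaceans": 0.05,
        "Euphausiids": 1.8,
        "Decapods": 4.7,
        "Chaetognaths": 90.0,
        "Tunicates": 46.9,
        "Pelagic larvae": 205.1,
    },
    "autumn": {
        "Hydromedusae": 0.7,
        "Siphonophorae": 1.0,
        "Ctenophores": 0.3,
        "Cladocerans": 0.5,
        "Copepods": 1258.0,
        "Amphipods": 6.7,
        "Isopods": 0.05,
        "Cumaceans": 0.1,
        "Mysids": 0.4,
        "Euphausiids": 1.1,
        "Decapods": 0.1,
        "Chaetognaths": 46.0,
        "Tunicates": 45.4,
        "Pelagic larvae": 50.3,
    },
}

#: Printed seasonal totals (ind/m3).  Note: the autumn components above sum
#: to ~1410.6, which disagrees with the printed total; shares quoted against
#: the printed totals therefore differ slightly from shares computed from
#: the components.
TABLE1_TOTALS: dict[str, float] = {
    "spring": 1568.2,
    "summer": 2102.4,
    "autumn": 1328.6,
}

#: (season, component) entries printed as "< 0.1" and stored as 0.05.
TABLE1_BELOW_DETECTION: frozenset[tuple[str, str]] = frozenset(
    {
        ("spring", "Decapods"),
        ("summer", "Polychaetes"),
        ("summer", "Ostracods"),
        ("summer", "Isopods"),
        ("summer", "Cumaceans"),
        ("autumn", "Isopods"),
    }
)

#: Dominance index Y per dominant species per season.  None = not detected;
#: 0.005 stands for entries printed "< 0.01".
TABLE2_DOMINANCE: dict[str, dict[str, float | None]] = {
    "Calanus sinicus": {"spring": 0.11, "summer": 0.03, "autumn": 0.03},
    "Paracalanus parvus": {"spring": 0.08, "summer": 0.29, "autumn": 0.64},
    "Centropages dorsispinatus": {"spring": None, "summer": 0.05, "autumn": 0.005},
    "Centropages abdominalis": {"spring": 0.09, "summer": None, "autumn": None},
    "Acartia pacifica": {"spring": 0.005, "summer": 0.04, "autumn": 0.005},
    "Oithona similis": {"spring": 0.52, "summer": 0.12, "autumn": 0.17},
    "Oithona plumifera": {"spring": 0.005, "summer": 0.04, "autumn": 0.005},
    "Corycaeus affinis": {"spring": 0.01, "summer": 0.02, "autumn": 0.02},
    "Oikopleura dioica": {"spring": 0.005, "summer": 0.02, "autumn": 0.03},
    "Bivalve larvae": {"spring": 0.07, "summer": 0.005, "autumn": 0.005},
    "Polychaeta larvae": {"spring": 0.005, "summer": 0.07, "autumn": 0.005},
    "Copepod nauplii": {"spring": 0.04, "summer": 0.005, "autumn": 0.005},
}

#: Mean abundance (ind/m3) of the dominant species per season (None = not
#: detected; 0.05 stands for "< 0.1").
TABLE2_ABUNDANCE: dict[str, dict[str, float | None]] = {
    "Calanus sinicus": {"spring": 202.4, "summer": 52.8, "autumn": 33.7},
    "Paracalanus parvus": {"spring": 242.1, "summer": 546.9, "autumn": 874.9},
    "Centropages dorsispinatus": {"spring": None, "summer": 320.1, "autumn": 0.05},
    "Centropages abdominalis": {"spring": 208.1, "summer": None, "autumn": None},
    "Acartia pacifica": {"spring": 0.05, "summer": 128.5, "autumn": 2.4},
    "Oithona similis": {"spring": 546.4, "summer": 198.8, "autumn": 202.8},
    "Oithona plumifera": {"spring": 11.2, "summer": 81.4, "autumn": 3.8},
    "Corycaeus affinis": {"spring": 19.6, "summer": 50.1, "autumn": 86.6},
    "Oikopleura dioica": {"spring": 8.5, "summer": 40.8, "autumn": 45.0},
    "Bivalve larvae": {"spring": 208.0, "summer": 9.5, "autumn": 16.2},
    "Polychaeta larvae": {"spring": 1.1, "summer": 153.2, "autumn": 6.3},
    "Copepod nauplii": {"spring": 55.3, "summer": 13.6, "autumn": 4.9},
}

#: Trait-modality profile of each of the eight functional groups: group id
#: -> size, higher taxa, and the modalities listed per trait.
TABLE3_PROFILES: dict[int, dict] = {
    1: {
        "size": 30,
        "taxa": ["Copepods", "Cumaceans", "Tunicates"],
        "body_length": ["small", "medium", "large", "giant"],
        "feeding_type": ["active_ambush", "current", "mixed"],
        "trophic_group": ["omnivore_herbivore"],
        "reproductive_mode": ["free_spawner", "egg_brooding"],
    },
    2: {
        "size": 7,
        "taxa": ["Polychaetes", "Amphipods", "Chaetognaths"],
        "body_length": ["giant"],
        "feeding_type": ["active_ambush"],
        "trophic_group": ["carnivore"],
        "reproductive_mode": ["free_spawner", "egg_brooding"],
    },
    3: {
        "size": 29,
        "taxa": ["Hydromedusae", "Siphonophorae", "Ctenophores"],
        "body_length": ["small", "medium", "large", "giant"],
        "feeding_type": ["passive_ambush"],
        "trophic_group": ["carnivore"],
        "reproductive_mode": ["free_spawner"],
    },
    4: {
        "size": 12,
        "taxa": ["Copepods"],
        "body_length": ["small", "medium", "large"],
        "feeding_type": ["active_ambush"],
        "trophic_group": ["omnivore_carnivore"],
        "reproductive_mode": ["free_spawner", "egg_brooding"],
    },
    5: {
        "size": 9,
        "taxa": ["Ostracods", "Copepods"],
        "body_length": ["small", "medium"],
        "feeding_type": ["current"],
        "trophic_group": ["omnivore_detritivore"],
        "reproductive_mode": ["free_spawner", "egg_brooding"],
    },
    6: {
        "size": 2,
        "taxa": ["Cladocerans"],
        "body_length": ["medium"],
        "feeding_type": ["active_ambush", "current"],
        "trophic_group": ["omnivore_herbivore", "omnivore_carnivore"],
        "reproductive_mode": ["parthenogenesis"],
    },
    7: {
        "size": 3,
        "taxa": ["Tunicates"],
        "body_length": ["medium", "large"],
        "feeding_type": ["current"],
        "trophic_group": ["omnivore_herbivore"],
        "reproductive_mode": ["alternation_of_generations"],
    },
    8: {
        "size": 6,
        "taxa": ["Mysids", "Euphausiids", "Decapods"],
        "body_length": ["giant"],
        "feeding_type": ["mixed"],
        "trophic_group": ["omnivore", "omnivore_carnivore"],
        "reproductive_mode": ["free_spawner", "egg_brooding"],
    },
}

TABLE3_GROUP_SIZES: tuple[int, ...] = tuple(
    TABLE3_PROFILES[g]["size"] for g in sorted(TABLE3_PROFILES)
)

#: Seasonal mean of each environmental variable (SST/SBT degC, SSS/SBS
#: practical salinity, Chl a ug/L).  Salinities are unprinted-but-realistic
#: defaults (see module docstring).
ENV_SEASONAL_MEAN: dict[str, dict[str, float]] = {
    "spring": {"SST": 10.1, "SBT": 9.2, "SSS": 31.6, "SBS": 31.2, "SChla": 1.80, "BChla": 1.87},
    "summer": {"SST": 27.2, "SBT": 15.7, "SSS": 30.9, "SBS": 30.5, "SChla": 1.84, "BChla": 1.10},
    "autumn": {"SST": 16.6, "SBT": 14.2, "SSS": 31.3, "SBS": 31.0, "SChla": 1.35, "BChla": 1.12},
}

ENV_SEASONAL_SD: dict[str, dict[str, float]] = {
    "spring": {"SST": 1.4, "SBT": 1.8, "SSS": 0.8, "SBS": 0.8, "SChla": 1.13, "BChla": 0.91},
    "summer": {"SST": 0.8, "SBT": 7.1, "SSS": 1.0, "SBS": 1.0, "SChla": 1.59, "BChla": 1.11},
    "autumn": {"SST": 0.8, "SBT": 3.2, "SSS": 0.8, "SBS": 0.8, "SChla": 0.50, "BChla": 0.83},
}

#: Reported sign of each functional group's association with the
#: environmental variables (constrained-ordination arrows): +1 positive,
#: -1 negative, 0 none reported.  Order of variables: SST, SBT, SSS, SBS,
#: SChla, BChla.
GROUP_ENV_COUPLING_SIGNS: dict[int, dict[str, int]] = {
    1: {"SST": 1, "SChla": 1},
    2: {"SST": 1, "SSS": -1},
    3: {"SST": 1},
    4: {"SST": 1, "SChla": 1},
    5: {"SST": 1, "SBT": 1},
    6: {"SST": 1, "SChla": 1},
    7: {},
    8: {},
}
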