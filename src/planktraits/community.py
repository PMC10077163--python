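"""Dominance screening, composition shares, functional richness and the
seasonal significance tests.

The dominance index of species *i* within one season is ``Y = (n_i / N) *
f_i`` where ``n_i / N`` is the species' share of the summed abundance over
the season's stations and ``f_i`` is its occurrence frequency (fraction of
stations with abundance > 0).  Species with ``Y >= 0.02`` are flagged
dominant (threshold inclusive).
"""

from __future__ import annotations

import itertools
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AbundanceTable, TraitMatrix, TRAITS, ValidationError
from .clustering import FunctionalGroupAssignment

__all__ = [
    "DOMINANCE_THRESHOLD",
    "dominance",
    "count_dominant_taxa",
    "dominant_taxa_from_y",
    "composition",
    "modality_mapping",
    "functional_richness",
    "anova_seasons",
    "wilcoxon_rank_sum",
]

DOMINANCE_THRESHOLD = 0.02


def dominance(abundance: AbundanceTable, season: str) -> pd.DataFrame:
    """Per-species dominance table for one season.

    Returns a DataFrame indexed by species with columns ``mean_abundance``,
    ``sd``, ``share``, ``occurrence_frequency``, ``dominance`` and
    ``dominant``.
    """
    sub = abundance.season_subset(season)
    if not sub.stations:
        raise ValidationError(f"no stations in season {season!r}")
    V = sub.values
    totals = V.sum(axis=0)
    N = totals.sum()
    if N <= 0:
        raise ValidationError(f"season {season!r} has zero total abundance")
    share = totals / N
    freq = (V > 0).mean(axis=0)
    y = share * freq
    return pd.DataFrame(
        {
            "mean_abundance": V.mean(axis=0),
            "sd": V.std(axis=0, ddof=1) if V.shape[0] > 1 else np.zeros(V.shape[1]),
            "share": share,
            "occurrence_frequency": freq,
            "dominance": y,
            "dominant": y >= DOMINANCE_THRESHOLD,
        },
        index=pd.Index(sub.species, name="species"),
    )


def count_dominant_taxa(tables: Iterable[pd.DataFrame]) -> int:
    """Number of taxa flagged dominant in at least one season."""
    seen: set[str] = set()
    for table in tables:
        seen |= set(table.index[table["dominant"]])
    return len(seen)


def dominant_taxa_from_y(
    y_by_species: Mapping[str, Mapping[str, float | None]],
    threshold: float = DOMINANCE_THRESHOLD,
) -> set[str]:
    """Apply the Y >= threshold rule to already-computed dominance values
    (e.g. a published dominance table); ``None`` means not detected."""
    return {
        species
        for species, by_season in y_by_species.items()
        if any(y is not None and y >= threshold for y in by_season.values())
    }


def composition(
    abundance: AbundanceTable,
    mapping: Mapping[str, str],
    by: str = "season",
    excluded: Sequence[str] = (),
) -> pd.DataFrame:
    """Relative-abundance share of each key per season or per station.

    ``mapping`` sends each species to a grouping key (taxon group, trait
    modality, or functional group label).  Species in ``excluded`` are
    removed from both numerator and denominator; any other unmapped species
    with nonzero abundance is an error.
    """
    if by not in ("season", "station"):
        raise ValueError("by must be 'season' or 'station'")
    excluded_set = set(excluded)
    keep_idx: list[int] = []
    for j, sp in enumerate(abundance.species):
        if sp in excluded_set:
            continue
        if sp not in mapping:
            if abundance.values[:, j].sum() > 0:
                raise ValidationError(
                    f"species {sp!r} has abundance but no grouping key and is "
                    "not in the excluded list"
                )
            continue
        keep_idx.append(j)
    keys = sorted({mapping[abundance.species[j]] for j in keep_idx})
    key_pos = {k: i for i, k in enumerate(keys)}

    if by == "season":
        groups = sorted(set(abundance.seasons), key=abundance.seasons.index)
        col_of = {i: groups.index(s.season) for i, s in enumerate(abundance.stations)}
    else:
        groups = [s.id for s in abundance.stations]
        col_of = {i: i for i in range(len(abundance.stations))}

    sums = np.zeros((len(keys), len(groups)))
    for j in keep_idx:
        row = key_pos[mapping[abundance.species[j]]]
        for i in range(len(abundance.stations)):
            sums[row, col_of[i]] += abundance.values[i, j]
    totals = sums.sum(axis=0)
    shares = np.divide(sums, totals, out=np.zeros_like(sums), where=totals > 0)
    return pd.DataFrame(shares, index=pd.Index(keys, name="key"), columns=groups)


def modality_mapping(matrix: TraitMatrix, trait: str) -> dict[str, str]:
    """Species -> assigned modality of one trait, from the one-hot matrix."""
    if trait not in TRAITS:
        raise ValueError(f"unknown trait {trait!r}")
    return {sp: matrix.modality_of(sp, trait) for sp in matrix.species}


def functional_richness(
    abundance: AbundanceTable, groups: FunctionalGroupAssignment
) -> pd.Series:
    """Number of functional groups with positive abundance at each station."""
    group_of = groups.as_dict()
    counts = []
    for i, st in enumerate(abundance.stations):
        present = {
            group_of[sp]
            for j, sp in enumerate(abundance.species)
            if sp in group_of and abundance.values[i, j] > 0
        }
        counts.append(len(present))
    return pd.Series(counts, index=[s.id for s in abundance.stations], name="richness")


def anova_seasons(
    values: Sequence[float], seasons: Sequence[str]
) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of per-station values across seasons."""
    if len(values) != len(seasons):
        raise ValidationError("values and season labels must align")
    groups: dict[str, list[float]] = {}
    for v, s in zip(values, seasons):
        groups.setdefault(s, []).append(v)
    if len(groups) < 2:
        raise ValidationError("ANOVA requires at least 2 seasons")
    for s, g in groups.items():
        if len(g) < 2:
            raise ValidationError(f"season {s!r} has fewer than 2 observations")
    f, p = stats.f_oneway(*groups.values())
    return float(f), float(p)


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(W, p)`` where ``W`` is the sum of the midranks of ``x`` in
    the pooled ranking.  The p value comes from exact enumeration of all
    rank splits when ``n_x + n_y <= 12`` (midranks make this well defined
    under ties), otherwise from the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    nx, ny = x.size, y.size
    n = nx + ny
    ranks = stats.rankdata(np.concatenate([x, y]))
    w = float(ranks[:nx].sum())
    if n <= 12:
        mu = nx * (n + 1) / 2.0
        obs_dev = abs(w - mu)
        hits = total = 0
        for combo in itertools.combinations(range(n), nx):
            total += 1
            if abs(ranks[list(combo)].sum() - mu) >= obs_dev - 1e-12:
                hits += 1
        p = hits / total
    else:
        p = float(
            stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
        )
    return w, min(p, 1.0)
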