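"""End-to-end orchestration: encode -> cluster -> dominance -> composition
-> seasonal tests -> RDA, with a JSON-serializable run report.

A run is configured either from synthetic cruises (``simulate=True``) or
from the three CSV inputs (abundance, environment, trait assignments).
Every artifact ordering is deterministic: groups are numbered by
decreasing size, species alphabetically within groups, seasons in cruise
order (spring, summer, autumn).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .datamodel import (
    SEASONS,
    TRAITS,
    AbundanceTable,
    EnvTable,
    TraitMatrix,
    ValidationError,
    encode_traits,
    read_abundance_csv,
    read_env_csv,
    read_traits_csv,
)
from .clustering import (
    FunctionalGroupAssignment,
    cut_tree,
    elbow_select,
    export_dendrogram,
    gower,
    ward_cluster,
)
from .community import (
    anova_seasons,
    composition,
    count_dominant_taxa,
    dominance,
    functional_richness,
    modality_mapping,
    wilcoxon_rank_sum,
)
from .ordination import rda_fit, rda_permutation_test
from .synthetic import SimulationConfig, fixture_taxa, generate_community, generate_env

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "summarize_groups"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    CLI flags override config-file values (documented precedence:
    flag > config file > default).
    """

    simulate: bool = True
    seed: int = 0
    abundance_csv: str | None = None
    env_csv: str | None = None
    traits_csv: str | None = None
    taxa_csv: str | None = None
    excluded_species: list[str] = field(default_factory=list)
    gower_mode: str = "categorical_traits"
    ward_squared: bool = True
    k_max: int | None = None
    k_override: int | None = None
    n_permutations: int = 199
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunReport:
    """Everything one run computed, re-derivable from inputs + config."""

    config: dict[str, Any]
    version: str
    input_checksums: dict[str, str]
    selected_k: int
    elbow_k: list[int]
    elbow_wss: list[float]
    group_summary: list[dict[str, Any]]
    dominance_tables: dict[str, list[dict[str, Any]]]
    dominant_taxa_count: int
    compositions: dict[str, dict[str, dict[str, float]]]
    richness: dict[str, int]
    anova_dominant: dict[str, dict[str, float]]
    wilcoxon_traits: dict[str, dict[str, float]]
    rda: dict[str, dict[str, Any]]

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(asdict(self), indent=indent, sort_keys=True)


def summarize_groups(
    groups: FunctionalGroupAssignment,
    traits: TraitMatrix,
    taxa_classes: Mapping[str, str] | None = None,
) -> list[dict[str, Any]]:
    """Per-group summary: size, higher taxa, modalities present per trait."""
    missing = [s for s in traits.species if s not in groups.as_dict()]
    if missing:
        raise ValidationError(f"group assignment missing species {missing[:3]}")
    taxa_classes = taxa_classes or {}
    out = []
    for g in range(1, groups.k + 1):
        members = sorted(groups.members(g))
        summary: dict[str, Any] = {
            "group": g,
            "size": len(members),
            "taxa": sorted({taxa_classes.get(s, "Unassigned") for s in members}),
            "species": members,
        }
        for trait, modalities in TRAITS.items():
            present = {traits.modality_of(s, trait) for s in members}
            summary[trait] = [m for m in modalities if m in present]
        out.append(summary)
    return out


def _sha256_file(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def _load_inputs(
    config: PipelineConfig,
) -> tuple[AbundanceTable, EnvTable, TraitMatrix, dict[str, str], dict[str, str]]:
    checksums: dict[str, str] = {}
    if config.simulate:
        sim = SimulationConfig(seed=config.seed)
        env = generate_env(sim)
        abundance, _truth = generate_community(sim, env)
        from .synthetic import table3_fixture

        traits, _planted = table3_fixture()
        taxa = fixture_taxa()
        for name, table in (("abundance", abundance), ("environment", env)):
            checksums[name] = _sha256_text(table.to_dataframe().to_csv(index=False))
        checksums["traits"] = _sha256_text(traits.to_dataframe().to_csv())
        return abundance, env, traits, taxa, checksums

    for name, path in (
        ("abundance", config.abundance_csv),
        ("environment", config.env_csv),
        ("traits", config.traits_csv),
    ):
        if path is None:
            raise ValidationError(f"config must supply {name}_csv unless simulate=True")
        checksums[name] = _sha256_file(path)
    abundance = read_abundance_csv(config.abundance_csv)
    env = read_env_csv(config.env_csv)
    assignments = read_traits_csv(config.traits_csv)
    traits = encode_traits(assignments)
    known = set(traits.species) | set(config.excluded_species)
    for j, sp in enumerate(abundance.species):
        if sp not in known and abundance.values[:, j].sum() > 0:
            raise ValidationError(
                f"species {sp!r} has abundance but no trait assignment and is "
                "not in excluded_species"
            )
    taxa: dict[str, str] = {}
    if config.taxa_csv:
        df = pd.read_csv(config.taxa_csv)
        taxa = dict(zip(df["species"].astype(str), df["taxon"].astype(str)))
        checksums["taxa"] = _sha256_file(config.taxa_csv)
    return abundance, env, traits, taxa, checksums


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages and return (and optionally write) the report."""
    from . import __version__

    abundance, env, traits, taxa, checksums = _load_inputs(config)

    d = gower(traits, config.gower_mode)
    dendrogram = ward_cluster(d, squared=config.ward_squared)
    curve = elbow_select(d, dendrogram, config.k_max)
    k = config.k_override or curve.selected_k
    groups = cut_tree(dendrogram, k)
    group_summary = summarize_groups(groups, traits, taxa)

    seasons_present = [s for s in SEASONS if s in set(abundance.seasons)]
    dom_tables = {s: dominance(abundance, s) for s in seasons_present}
    dominant_count = count_dominant_taxa(dom_tables.values())

    group_label = {sp: f"Group {g}" for sp, g in groups.as_dict().items()}
    comps: dict[str, pd.DataFrame] = {
        "functional_group": composition(
            abundance, group_label, by="season", excluded=config.excluded_species
        )
    }
    if taxa:
        comps["taxon"] = composition(
            abundance,
            {sp: taxa[sp] for sp in abundance.species if sp in taxa},
            by="season",
            excluded=config.excluded_species,
        )
    for trait in TRAITS:
        comps[trait] = composition(
            abundance,
            modality_mapping(traits, trait),
            by="season",
            excluded=config.excluded_species,
        )

    richness = functional_richness(abundance, groups)

    anova_results: dict[str, dict[str, float]] = {}
    if len(seasons_present) >= 2:
        dominant_species = sorted(
            {sp for t in dom_tables.values() for sp in t.index[t["dominant"]]}
        )
        season_labels = abundance.seasons
        for sp in dominant_species:
            j = abundance.species.index(sp)
            try:
                f, p = anova_seasons(abundance.values[:, j], season_labels)
            except ValidationError:
                continue
            anova_results[sp] = {"F": f, "p": p}

    wilcoxon_results: dict[str, dict[str, float]] = {}
    for trait in TRAITS:
        mapping = modality_mapping(traits, trait)
        shares = composition(
            abundance, mapping, by="station", excluded=config.excluded_species
        )
        for modality in shares.index:
            per_station = shares.loc[modality]
            by_season = {
                s: [
                    per_station[st.id]
                    for st in abundance.stations
                    if st.season == s
                ]
                for s in seasons_present
            }
            for a in range(len(seasons_present)):
                for b in range(a + 1, len(seasons_present)):
                    sa, sb = seasons_present[a], seasons_present[b]
                    w, p = wilcoxon_rank_sum(by_season[sa], by_season[sb])
                    wilcoxon_results[f"{trait}:{modality}|{sa}-vs-{sb}"] = {
                        "W": w,
                        "p": p,
                    }

    group_abund = pd.DataFrame(
        {
            f"Group {g}": [
                sum(
                    abundance.values[i, j]
                    for j, sp in enumerate(abundance.species)
                    if group_label.get(sp) == f"Group {g}"
                )
                for i in range(len(abundance.stations))
            ]
            for g in range(1, groups.k + 1)
        },
        index=[s.id for s in abundance.stations],
    )
    env_df = pd.DataFrame(
        env.values, index=[s.id for s in env.stations], columns=env.variables
    )
    rda_out: dict[str, dict[str, Any]] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = rda_fit(group_abund, env_df)
        p_perm = rda_permutation_test(
            group_abund, env_df, n_perm=config.n_permutations, seed=config.seed
        )
        rda_out["pooled"] = {
            "explained_fraction": fit.explained_fraction,
            "constrained_eigenvalues": fit.constrained_eigenvalues.tolist(),
            "permutation_p": p_perm,
            "predictors": fit.predictors_used,
        }
        for season in seasons_present:
            ids = [s.id for s in abundance.stations if s.season == season]
            if len(ids) <= 2:
                continue
            sfit = rda_fit(group_abund.loc[ids], env_df.loc[ids])
            rda_out[season] = {
                "explained_fraction": sfit.explained_fraction,
                "constrained_eigenvalues": sfit.constrained_eigenvalues.tolist(),
                "predictors": sfit.predictors_used,
            }

    report = RunReport(
        config={**asdict(config)},
        version=__version__,
        input_checksums=checksums,
        selected_k=k,
        elbow_k=curve.k_values,
        elbow_wss=curve.wss,
        group_summary=group_summary,
        dominance_tables={
            s: t.reset_index().to_dict(orient="records") for s, t in dom_tables.items()
        },
        dominant_taxa_count=dominant_count,
        compositions={
            name: {str(c): df[c].to_dict() for c in df.columns}
            for name, df in comps.items()
        },
        richness=richness.to_dict(),
        anova_dominant=anova_results,
        wilcoxon_traits=wilcoxon_results,
        rda=rda_out,
    )

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        (out / "dendrogram.nwk").write_text(export_dendrogram(dendrogram, "newick"))
        (out / "groups.csv").write_text(
            pd.DataFrame(
                {"species": groups.species, "group": groups.group_ids}
            ).to_csv(index=False)
        )
        for s, t in dom_tables.items():
            t.to_csv(out / f"dominance_{s}.csv")
        for name, df in comps.items():
            df.to_csv(out / f"composition_{name}.csv")
        richness.to_frame().to_csv(out / "richness.csv")
        group_abund.to_csv(out / "group_abundance.csv")
    return report
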