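"""Locality-level summaries and trophic-conflict counts.

For each fossil assemblage: relative species richness by clade, relative
abundance by diet class (specimen counts when available, equal weights
otherwise), and the number of potential trophic conflicts — unordered
pairs of co-occurring herbivores sharing the same feeding guild at FFG
or FFsG resolution.  Herbivores absent from the morphometric sample can
inherit their clade's majority guild.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging

import numpy as np
import pandas as pd

from .guild_clustering import ConsensusGuilds

logger = logging.getLogger("guildspace.assemblage")

__all__ = ["Assemblage", "ConflictReport", "assemblage_summaries",
           "count_ffg_conflicts", "assemblages_from_table"]


@dataclasses.dataclass
class Assemblage:
    locality: str
    bin: str
    taxa: list[str]
    counts: dict[str, float] | None = None   # per-taxon specimen counts
    diets: dict[str, str] | None = None      # taxon -> herbivore|faunivore


@dataclasses.dataclass
class ConflictReport:
    locality: str
    resolution: str                          # FFG | FFsG
    n_conflicts: int                         # same-guild unordered pairs
    pairs: list[tuple[str, str]]
    n_conflicted_taxa: int                   # taxa in any shared guild
    n_herbivores: int
    excluded: list[str]


def assemblages_from_table(table: pd.DataFrame,
                           taxa: pd.DataFrame) -> list[Assemblage]:
    """Build assemblages from the occurrence CSV plus the taxon table."""
    diet_map = taxa.set_index("taxon_id")["diet"].to_dict()
    out = []
    for (loc, b), sub in table.groupby(["locality", "bin"], sort=True):
        members = list(sub["taxon_id"])
        counts = None
        if "count" in sub.columns and sub["count"].notna().all():
            counts = dict(zip(sub["taxon_id"], sub["count"].astype(float)))
        diets = {t: diet_map.get(t, "unknown") for t in members}
        out.append(Assemblage(str(loc), str(b), members, counts, diets))
    return out


def assemblage_summaries(a: Assemblage, taxonomy: pd.Series) -> dict:
    """Relative richness by clade and relative abundance by diet.

    Proportions sum to 1 within each panel; abundance falls back to
    equal weights (logged) when any count is missing.
    """
    if not a.taxa:
        raise ValueError(f"empty assemblage: {a.locality}")
    clades = pd.Series({t: taxonomy.get(t, "unknown") for t in a.taxa})
    richness = (clades.value_counts() / len(a.taxa)).to_dict()
    if a.counts and all(t in a.counts for t in a.taxa):
        weights = pd.Series({t: float(a.counts[t]) for t in a.taxa})
    else:
        logger.info("%s: no full abundance counts; using equal weights",
                    a.locality)
        weights = pd.Series(1.0, index=a.taxa)
    diets = pd.Series({t: (a.diets or {}).get(t, "unknown") for t in a.taxa})
    abundance = (weights.groupby(diets).sum() / weights.sum()).to_dict()
    return {"locality": a.locality, "richness_by_clade": richness,
            "abundance_by_diet": abundance}


def count_ffg_conflicts(
    a: Assemblage,
    guilds: ConsensusGuilds,
    resolution: str = "FFG",
    clade_guilds: dict | None = None,
    taxonomy: pd.Series | None = None,
    include_inconsistent: bool = True,
) -> ConflictReport:
    """Count same-guild pairs among the assemblage's herbivores.

    Herbivores outside the guild table inherit their clade's majority
    guild when ``clade_guilds``/``taxonomy`` are supplied (FFG resolution
    only); taxa that still lack a label are excluded with a log entry.
    """
    labels = guilds.labels(resolution)
    inconsistent = set(guilds.inconsistent)
    herbivores = [t for t in a.taxa
                  if (a.diets or {}).get(t, "herbivore") == "herbivore"]
    guild_of: dict[str, str] = {}
    excluded: list[str] = []
    for t in herbivores:
        if t in labels.index:
            if not include_inconsistent and t in inconsistent:
                excluded.append(t)
            else:
                guild_of[t] = str(labels[t])
        elif clade_guilds is not None and taxonomy is not None \
                and t in taxonomy.index:
            g = clade_guilds.get(str(taxonomy[t]), "unresolved")
            if g == "unresolved":
                excluded.append(t)
            else:
                guild_of[t] = g
        else:
            excluded.append(t)
    if excluded:
        logger.info("%s: %d herbivore(s) without a %s label excluded",
                    a.locality, len(excluded), resolution)
    pairs = [(s, t) for s, t in itertools.combinations(sorted(guild_of), 2)
             if guild_of[s] == guild_of[t]]
    conflicted = {t for pair in pairs for t in pair}
    return ConflictReport(
        locality=a.locality,
        resolution=resolution.upper(),
        n_conflicts=len(pairs),
        pairs=pairs,
        n_conflicted_taxa=len(conflicted),
        n_herbivores=len(guild_of),
        excluded=excluded,
    )


def conflict_table(reports: list[ConflictReport]) -> pd.DataFrame:
    rows = [{
        "locality": r.locality, "resolution": r.resolution,
        "n_conflicts": r.n_conflicts, "n_conflicted_taxa": r.n_conflicted_taxa,
        "n_herbivores": r.n_herbivores,
        "pairs": ";".join(f"{s}|{t}" for s, t in r.pairs),
    } for r in reports]
    return pd.DataFrame(rows)
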