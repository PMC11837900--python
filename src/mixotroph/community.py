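"""Mycorrhizal OTU filtering and read-count / relative-abundance summaries.

Starting from an OTU read-count table with family/genus taxonomy, the module
(1) retains only OTUs assigned to guilds considered potentially orchid
mycorrhizal and (2) pools reads per stratum (morph, organ, population, or any
subset) and taxon to produce the relative-abundance profile of the fungal
community — raw read sums, no rarefaction or depth normalization.

Percentages are computed on pooled reads per group, never as means of
per-sample percentages: "X reads, Y% of all reads" style reporting.  The
denominator is the total retained (whitelisted) reads of the stratum being
described; ``filter_mycorrhizal`` is a separate step so callers who want the
unfiltered denominator can simply skip it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from mixotroph.io import Guild

logger = logging.getLogger("mixotroph")

__all__ = ["GuildMap", "filter_mycorrhizal", "aggregate_reads", "dominance_summary"]

#: Families named in orchid-mycorrhizal work and their default guilds.
DEFAULT_FAMILY_GUILDS: dict[str, Guild] = {
    "Psathyrellaceae": Guild.SAPROTROPH_NONRHIZOCTONIA,
    "Ceratobasidiaceae": Guild.RHIZOCTONIA,
    "Tulasnellaceae": Guild.RHIZOCTONIA,
    "Serendipitaceae": Guild.RHIZOCTONIA,
    "Thelephoraceae": Guild.ECM,
    "Russulaceae": Guild.ECM,
    "Inocybaceae": Guild.ECM,
    "Mortierellaceae": Guild.NON_MYCORRHIZAL,
}

#: Guilds treated as potentially orchid mycorrhizal by default.
DEFAULT_WHITELIST: frozenset[Guild] = frozenset({
    Guild.RHIZOCTONIA,
    Guild.SAPROTROPH_NONRHIZOCTONIA,
    Guild.ECM,
    Guild.OTHER_ORCHID_MYC,
})

_META_COLS = ("otu_id", "family", "genus", "guild")


@dataclass(frozen=True)
class GuildMap:
    """Family → guild assignment with per-OTU overrides and a whitelist.

    ``otu_overrides`` handles cases where one family straddles guilds, e.g.
    an OTU of a rhizoctonia family that falls in an ECM-forming clade.
    """

    family_guilds: dict[str, Guild] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_GUILDS))
    otu_overrides: dict[str, Guild] = field(default_factory=dict)
    whitelist: frozenset[Guild] = DEFAULT_WHITELIST

    def __post_init__(self) -> None:
        if not self.whitelist:
            raise ValueError("guild whitelist must be non-empty")

    def guild_of(self, otu_id: str, family: str) -> Guild:
        if otu_id in self.otu_overrides:
            return Guild(self.otu_overrides[otu_id])
        try:
            return Guild(self.family_guilds[family])
        except KeyError:
            raise KeyError(
                f"family {family!r} (OTU {otu_id!r}) is absent from the guild map"
            ) from None


def filter_mycorrhizal(otus: pd.DataFrame, guilds: GuildMap | None = None) -> pd.DataFrame:
    """Retain only OTUs whose guild is in the whitelist; order preserved.

    The guild column is re-derived from the map (so overrides apply); every
    family present must resolve, otherwise a KeyError names the family.
    """
    if guilds is None:
        guilds = GuildMap()
    if otus.empty:
        return otus.copy()
    assigned = [guilds.guild_of(r.otu_id, r.family).value for r in otus.itertuples()]
    out = otus.copy()
    out["guild"] = assigned
    keep = out["guild"].isin({g.value for g in guilds.whitelist})
    out = out[keep].reset_index(drop=True)
    logger.info("filter_mycorrhizal: %d OTUs in, %d retained", len(otus), len(out))
    return out


def aggregate_reads(otus: pd.DataFrame, meta: pd.DataFrame,
                    level: str = "family",
                    group_by: list[str] | tuple[str, ...] = ("morph",),
                    ) -> pd.DataFrame:
    """Pool reads per (group, taxon) and compute within-group fractions.

    Parameters
    ----------
    otus
        OTU table (``otu_id, family, genus, guild`` + one column per sample).
    meta
        Sample metadata; every sample column of `otus` must appear.
    level : {"family", "genus", "otu"}
        Taxonomic level at which reads are summed.
    group_by
        Subset of ``{"morph", "organ", "population"}`` defining the strata.

    Returns
    -------
    DataFrame with columns: the group keys, ``taxon``, ``n_otus`` (OTUs with
    ≥1 read in the group), ``total_reads``, ``fraction`` (of the group's
    total; missing when the group has zero reads, never a division by zero)
    and ``percent`` (fraction × 100).
    """
    group_by = list(group_by)
    allowed = {"morph", "organ", "population"}
    bad = [k for k in group_by if k not in allowed]
    if bad:
        raise ValueError(f"unknown group_by keys {bad}; allowed: {sorted(allowed)}")
    if level not in ("family", "genus", "otu"):
        raise ValueError(f"unknown level {level!r}")
    taxon_col = {"family": "family", "genus": "genus", "otu": "otu_id"}[level]

    sample_cols = [c for c in otus.columns if c not in _META_COLS]
    known = set(meta["sample_id"])
    orphans = [s for s in sample_cols if s not in known]
    if orphans:
        raise ValueError(f"samples without metadata: {orphans}")

    # long form: one row per (otu, sample) with reads > 0 kept for n_otus
    long = otus.melt(id_vars=list(_META_COLS), value_vars=sample_cols,
                     var_name="sample_id", value_name="reads")
    long = long.merge(meta, on="sample_id", how="left")
    long["taxon"] = long[taxon_col]

    keys = group_by + ["taxon"]
    agg = long.groupby(keys, sort=True)["reads"].sum().rename("total_reads").reset_index()
    n_otus = (long[long["reads"] > 0].groupby(keys)["otu_id"].nunique()
              .rename("n_otus").reset_index())
    agg = agg.merge(n_otus, on=keys, how="left")
    agg["n_otus"] = agg["n_otus"].fillna(0)
    group_totals = agg.groupby(group_by, sort=False)["total_reads"].transform("sum")
    agg["fraction"] = agg["total_reads"].where(group_totals > 0) / group_totals.where(group_totals > 0)
    agg["percent"] = agg["fraction"] * 100.0
    agg["total_reads"] = agg["total_reads"].astype(int)
    agg["n_otus"] = agg["n_otus"].astype(int)
    logger.info("aggregate_reads: %d OTUs x %d samples -> %d (group, taxon) rows",
                len(otus), len(sample_cols), len(agg))
    return agg[group_by + ["taxon", "n_otus", "total_reads", "fraction", "percent"]]


def dominance_summary(table: pd.DataFrame, top_k: int = 3,
                      group_by: list[str] | None = None) -> pd.DataFrame:
    """Top-k taxa per group by fraction, ties broken lexicographically.

    `table` is the output of :func:`aggregate_reads`; `group_by` defaults to
    whatever grouping columns that table carries.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if group_by is None:
        group_by = [c for c in ("morph", "organ", "population") if c in table.columns]
    ordered = table.sort_values(
        group_by + ["fraction", "taxon"], ascending=[True] * len(group_by) + [False, True],
        kind="mergesort")
    if group_by:
        out = ordered.groupby(group_by, sort=False).head(top_k)
    else:
        out = ordered.head(top_k)
    return out.reset_index(drop=True)
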