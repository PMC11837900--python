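"""Synthetic datasets with the plot-nested structure of the field design.

The generator emulates a three-population study in which five 2 m × 2 m
quadrats (plots) per population each contain at least three autotrophic
reference plants and a handful of focal orchids.  Reference deltas are drawn
around a population/plot-shifted base value; focal specimens receive their
group's enrichment offset *relative to the plot's true reference mean*, so
the estimator's use of the sampled reference mean introduces realistic
baseline-estimation error — the property the ≥3-references design controls.
Protocorms occur only in populations flagged for them (by default one,
matching a design where the fully mycoheterotrophic endpoint was sampled at
a single site).

OTU tables are Dirichlet-multinomial: each sample's taxon proportions are
drawn from a Dirichlet centred on its (morph, organ) composition profile
with a concentration parameter controlling between-sample variation, then
reads are multinomial at a fixed depth.

All randomness flows from one seed through per-dataset substreams
(:func:`numpy.random.SeedSequence.spawn`), so the three datasets are
independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mixotroph.io import Category, Morph, Organ, Guild

logger = logging.getLogger("mixotroph")

__all__ = ["PopulationDesign", "SimulationConfig", "simulate_isotope_dataset",
           "simulate_otu_table", "simulate_traits", "write_dataset"]


@dataclass(frozen=True)
class PopulationDesign:
    """Sampling design of one population (site)."""

    name: str
    n_plots: int = 5
    n_refs_per_plot: int = 3
    n_rhizome: int = 0       # focal plants with coralloid rhizomes
    n_roots: int = 0         # focal plants without
    n_protocorm: int = 0     # protocorms (only where the design found them)


def _default_populations() -> list[PopulationDesign]:
    # per-site focal counts follow the isotopic sampling design:
    # 4/8, 4/5 and 8/6 plants with/without coralloid rhizomes; protocorms
    # were encountered at the third site only (n = 5).
    return [
        PopulationDesign("Ebetsu", n_rhizome=4, n_roots=8),
        PopulationDesign("Jozankei", n_rhizome=4, n_roots=5),
        PopulationDesign("Ekari", n_rhizome=8, n_roots=6, n_protocorm=5),
    ]


def _default_composition() -> dict[tuple[str, str], dict[str, float]]:
    # Dominant-family fractions pinned to the observed per-stratum dominance
    # (92.17% / 85.14% Psathyrellaceae in rhizomes and roots of coralloid
    # plants; 45.78% Ceratobasidiaceae and 28.58% Psathyrellaceae in plants
    # without rhizomes); the split of the remainder over minor families is
    # an assumption.
    return {
        (Morph.WITH_RHIZOME.value, Organ.RHIZOME.value): {
            "Psathyrellaceae": 0.9217, "Ceratobasidiaceae": 0.0583,
            "Tulasnellaceae": 0.012, "Serendipitaceae": 0.008},
        (Morph.WITH_RHIZOME.value, Organ.ROOT.value): {
            "Psathyrellaceae": 0.8514, "Ceratobasidiaceae": 0.1286,
            "Tulasnellaceae": 0.012, "Serendipitaceae": 0.008},
        (Morph.WITHOUT_RHIZOME.value, Organ.ROOT.value): {
            "Ceratobasidiaceae": 0.4578, "Psathyrellaceae": 0.2858,
            "Tulasnellaceae": 0.15, "Serendipitaceae": 0.1064},
    }


_FAMILY_GUILD = {
    "Psathyrellaceae": Guild.SAPROTROPH_NONRHIZOCTONIA.value,
    "Ceratobasidiaceae": Guild.RHIZOCTONIA.value,
    "Tulasnellaceae": Guild.RHIZOCTONIA.value,
    "Serendipitaceae": Guild.RHIZOCTONIA.value,
}
_FAMILY_GENUS = {
    "Psathyrellaceae": "Coprinopsis",
    "Ceratobasidiaceae": "Ceratobasidium",
    "Tulasnellaceae": "Tulasnella",
    "Serendipitaceae": "Serendipita",
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic datasets.

    Isotope defaults are the reported group statistics: autotrophic
    references at δ13C −31.5 ± 1.5‰ and δ15N −1.8 ± 1.3‰; enrichment
    offsets (mean/SD, ‰) of 3.9/1.7 (ε13C) and 3.8/1.1 (ε15N) for plants
    with coralloid rhizomes, 1.3/1.7 and 3.1/1.5 for plants without, and
    6.7/0.2 (ε13C) for protocorms.  The protocorm ε15N default 1.1/0.7 is
    *derived* from printed δ15N group means (−0.7 − (−1.8)), not itself a
    printed value.  Plot/population effect SDs (0.5‰) are design
    assumptions, not reported values.
    """

    seed: int = 0
    populations: list[PopulationDesign] = field(default_factory=_default_populations)
    autotroph_mean_delta13C: float = -31.5
    autotroph_sd_delta13C: float = 1.5
    autotroph_mean_delta15N: float = -1.8
    autotroph_sd_delta15N: float = 1.3
    group_eps13C: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        Category.OP_RHIZOME.value: (3.9, 1.7),
        Category.OP_ROOTS.value: (1.3, 1.7),
        Category.OP_PROTOCORM.value: (6.7, 0.2)})
    group_eps15N: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        Category.OP_RHIZOME.value: (3.8, 1.1),
        Category.OP_ROOTS.value: (3.1, 1.5),
        Category.OP_PROTOCORM.value: (1.1, 0.7)})  # derived default, see class docstring
    plot_effect_sd: float = 0.5
    population_effect_sd: float = 0.5
    composition: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=_default_composition)
    otus_per_family: int = 2
    total_reads_per_sample: int = 20_000
    overdispersion: float = 50.0
    trait_means: dict[str, dict[str, tuple[float, float]]] = field(default_factory=lambda: {
        Morph.WITH_RHIZOME.value: {
            "scape_height_mm": (364.2, 84.9), "n_scapes": (1.4, 0.5),
            "n_flowers": (34.2, 10.1), "n_leaves": (1.8, 0.4),
            "leaf_length_mm": (317.3, 79.7), "leaf_width_mm": (25.2, 4.4),
            "fv_fm": (0.750, 0.021)},
        Morph.WITHOUT_RHIZOME.value: {
            "scape_height_mm": (270.0, 67.3), "n_scapes": (1.2, 0.4),
            "n_flowers": (23.3, 7.4), "n_leaves": (1.7, 0.5),
            "leaf_length_mm": (252.4, 79.9), "leaf_width_mm": (21.9, 5.5),
            "fv_fm": (0.753, 0.022)}})
    n_individuals: dict[str, int] = field(default_factory=lambda: {
        Morph.WITH_RHIZOME.value: 9, Morph.WITHOUT_RHIZOME.value: 10})

    def __post_init__(self) -> None:
        problems = []
        for name in ("autotroph_sd_delta13C", "autotroph_sd_delta15N",
                     "plot_effect_sd", "population_effect_sd"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        for attr in ("group_eps13C", "group_eps15N"):
            for g, (_, sd) in getattr(self, attr).items():
                if sd < 0:
                    problems.append(f"{attr}[{g}] SD must be >= 0")
        for p in self.populations:
            if p.n_refs_per_plot < 3:
                problems.append(f"population {p.name}: n_refs_per_plot must be >= 3")
            if p.n_plots < 1:
                problems.append(f"population {p.name}: n_plots must be >= 1")
        for key, profile in self.composition.items():
            total = sum(profile.values())
            if abs(total - 1.0) > 1e-9:
                problems.append(f"composition profile {key} sums to {total}, not 1")
        if self.overdispersion <= 0:
            problems.append("overdispersion (Dirichlet concentration) must be > 0")
        if problems:
            raise ValueError("invalid simulation config: " + "; ".join(problems))

    def zero_noise(self) -> "SimulationConfig":
        """Copy with every SD set to 0 — the deterministic fixed point."""
        return dataclasses.replace(
            self,
            autotroph_sd_delta13C=0.0, autotroph_sd_delta15N=0.0,
            plot_effect_sd=0.0, population_effect_sd=0.0,
            group_eps13C={g: (m, 0.0) for g, (m, _) in self.group_eps13C.items()},
            group_eps15N={g: (m, 0.0) for g, (m, _) in self.group_eps15N.items()},
            trait_means={mo: {t: (m, 0.0) for t, (m, _) in d.items()}
                         for mo, d in self.trait_means.items()})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        """Load a config from YAML; unspecified fields keep their defaults."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "populations" in raw:
            raw["populations"] = [PopulationDesign(**p) for p in raw["populations"]]
        if "composition" in raw:
            raw["composition"] = {tuple(k.split("/")): v
                                  for k, v in raw["composition"].items()}
        for attr in ("group_eps13C", "group_eps15N"):
            if attr in raw:
                raw[attr] = {g: tuple(v) for g, v in raw[attr].items()}
        return cls(**raw)


def _streams(config: SimulationConfig) -> dict[str, np.random.Generator]:
    """One independent generator per dataset, all derived from config.seed."""
    root = np.random.SeedSequence(config.seed)
    iso, otu, traits = root.spawn(3)
    return {"isotope": np.random.default_rng(iso),
            "otu": np.random.default_rng(otu),
            "traits": np.random.default_rng(traits)}


def simulate_isotope_dataset(config: SimulationConfig
                             ) -> tuple[pd.DataFrame, dict]:
    """Draw a plot-structured isotope dataset.

    Returns ``(specimens, truth)``: the specimen table in the isotope-CSV
    schema, and a ground-truth record with every drawn plot/population
    effect and each specimen's true enrichment offset, for recovery tests.
    """
    rng = _streams(config)["isotope"]
    rows, truth_effects, truth_eps = [], {}, {}
    for pop in config.populations:
        pop_eff13 = rng.normal(0.0, config.population_effect_sd)
        pop_eff15 = rng.normal(0.0, config.population_effect_sd)
        truth_effects[pop.name] = {"delta13C": pop_eff13, "delta15N": pop_eff15,
                                   "plots": {}}
        # round-robin assignment of focal specimens to plots
        assignments: list[tuple[str, int]] = []
        for cat, count in ((Category.OP_RHIZOME.value, pop.n_rhizome),
                           (Category.OP_ROOTS.value, pop.n_roots),
                           (Category.OP_PROTOCORM.value, pop.n_protocorm)):
            assignments += [(cat, i % pop.n_plots) for i in range(count)]
        for p in range(pop.n_plots):
            plot_id = f"{pop.name}-Q{p + 1}"
            plot_eff13 = rng.normal(0.0, config.plot_effect_sd)
            plot_eff15 = rng.normal(0.0, config.plot_effect_sd)
            base13 = config.autotroph_mean_delta13C + pop_eff13 + plot_eff13
            base15 = config.autotroph_mean_delta15N + pop_eff15 + plot_eff15
            truth_effects[pop.name]["plots"][plot_id] = {
                "true_ref_mean_delta13C": base13, "true_ref_mean_delta15N": base15}
            for r in range(pop.n_refs_per_plot):
                sid = f"{plot_id}-ref{r + 1}"
                rows.append((sid, pop.name, plot_id, Category.AUTO_REF.value,
                             base13 + rng.normal(0.0, config.autotroph_sd_delta13C),
                             base15 + rng.normal(0.0, config.autotroph_sd_delta15N)))
            for j, (cat, plot_idx) in enumerate(assignments):
                if plot_idx != p:
                    continue
                m13, s13 = config.group_eps13C[cat]
                m15, s15 = config.group_eps15N[cat]
                eps13 = m13 + rng.normal(0.0, s13)
                eps15 = m15 + rng.normal(0.0, s15)
                sid = f"{plot_id}-{cat.lower()}{j + 1}"
                truth_eps[sid] = {"eps13C": eps13, "eps15N": eps15}
                rows.append((sid, pop.name, plot_id, cat,
                             base13 + eps13, base15 + eps15))
    specimens = pd.DataFrame(rows, columns=["specimen_id", "population", "plot_id",
                                            "category", "delta13C", "delta15N"])
    truth = {"seed": config.seed, "effects": truth_effects,
             "specimen_eps": truth_eps}
    logger.info("simulate_isotope_dataset: %d specimens across %d populations",
                len(specimens), len(config.populations))
    return specimens, truth


def simulate_otu_table(config: SimulationConfig
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a Dirichlet-multinomial OTU table plus sample metadata.

    Each adult focal individual contributes one sample per organ its morph
    carries (rhizome-bearing plants: rhizome and root; plants without:
    root).  Families are split into `otus_per_family` OTUs with uneven
    within-family weights (first OTU dominant).
    """
    rng = _streams(config)["otu"]
    families = sorted({f for prof in config.composition.values() for f in prof})
    otu_ids, tax_rows = [], []
    for fam in families:
        for i in range(config.otus_per_family):
            oid = f"{fam[:6]}_OTU{i + 1}"
            otu_ids.append((fam, oid))
            tax_rows.append((oid, fam, _FAMILY_GENUS.get(fam, ""),
                             _FAMILY_GUILD.get(fam, Guild.OTHER_ORCHID_MYC.value)))
    # within a family the first OTU dominates (geometric 4:1 decay)
    fam_weights = {fam: np.array([4.0 ** -i for i in range(config.otus_per_family)])
                   for fam in families}
    for fam in families:
        fam_weights[fam] /= fam_weights[fam].sum()

    meta_rows, count_cols = [], {}
    for pop in config.populations:
        for morph, count in ((Morph.WITH_RHIZOME.value, pop.n_rhizome),
                             (Morph.WITHOUT_RHIZOME.value, pop.n_roots)):
            for i in range(count):
                ind = f"{pop.name}-{morph.lower()}{i + 1}"
                organs = ([Organ.RHIZOME.value, Organ.ROOT.value]
                          if morph == Morph.WITH_RHIZOME.value else [Organ.ROOT.value])
                for organ in organs:
                    profile = config.composition.get((morph, organ))
                    if profile is None:
                        continue
                    sample_id = f"{ind}-{organ.lower()}"
                    meta_rows.append((sample_id, ind, pop.name, morph, organ))
                    base = np.array([profile.get(fam, 0.0) * fam_weights[fam][i_o]
                                     for fam, oid in otu_ids
                                     for i_o in [int(oid.rsplit("OTU", 1)[1]) - 1]])
                    alpha = base * config.overdispersion
                    positive = alpha > 0
                    p = np.zeros_like(base)
                    p[positive] = rng.dirichlet(alpha[positive])
                    count_cols[sample_id] = rng.multinomial(
                        config.total_reads_per_sample, p)
    otus = pd.DataFrame(tax_rows, columns=["otu_id", "family", "genus", "guild"])
    for sid, counts in count_cols.items():
        otus[sid] = counts
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "individual_id",
                                            "population", "morph", "organ"])
    logger.info("simulate_otu_table: %d OTUs x %d samples", len(otus), len(meta))
    return otus, meta


def simulate_traits(config: SimulationConfig) -> pd.DataFrame:
    """Draw per-individual phenotypes: Normal(mean, sd), truncated at zero.

    Count traits are rounded to the nearest non-negative integer and Fv/Fm
    is clipped to [0, 1].
    """
    rng = _streams(config)["traits"]
    int_traits = {"n_scapes", "n_flowers", "n_leaves"}
    rows = []
    for morph, n in config.n_individuals.items():
        spec = config.trait_means[morph]
        for i in range(n):
            row = {"individual_id": f"{morph.lower()}-{i + 1}", "morph": morph}
            for trait, (mean, sd) in spec.items():
                val = max(0.0, mean + rng.normal(0.0, sd))
                if trait in int_traits:
                    val = int(round(val))
                elif trait == "fv_fm":
                    val = min(1.0, val)
                row[trait] = val
            rows.append(row)
    frame = pd.DataFrame(rows)
    logger.info("simulate_traits: %d individuals", len(frame))
    return frame


def write_dataset(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate all three datasets and write them as plain-text tables.

    Writes ``specimens.csv``, ``otu.tsv``, ``tax.tsv``, ``samples.csv``,
    ``traits.csv`` and ``truth.json`` under `outdir`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    specimens, truth = simulate_isotope_dataset(config)
    otus, meta = simulate_otu_table(config)
    traits = simulate_traits(config)
    paths = {
        "specimens": outdir / "specimens.csv",
        "otu": outdir / "otu.tsv",
        "tax": outdir / "tax.tsv",
        "samples": outdir / "samples.csv",
        "traits": outdir / "traits.csv",
        "truth": outdir / "truth.json",
    }
    specimens.to_csv(paths["specimens"], index=False)
    sample_cols = [c for c in otus.columns
                   if c not in ("otu_id", "family", "genus", "guild")]
    otus[["otu_id"] + sample_cols].to_csv(paths["otu"], sep="\t", index=False)
    otus[["otu_id", "family", "genus", "guild"]].to_csv(paths["tax"], sep="\t", index=False)
    meta.to_csv(paths["samples"], index=False)
    traits.to_csv(paths["traits"], index=False)
    paths["truth"].write_text(json.dumps(truth, indent=1, default=float) + "\n")
    return paths
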