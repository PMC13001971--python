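"""Synthetic wetland-like species lists.

The generator emulates the structure of real wetland inventories: a large
share of primary producers, consumer guilds from insects to top predators,
body masses spanning many orders of magnitude (log-uniform within guild),
a consistent taxonomy tree so taxonomic collapse is meaningful, and mixed
aquatic/terrestrial habitat use.  It does not attempt geographic structure
or abundances; it is the controlled stand-in for mined species lists when
exercising and validating the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .species_table import SpeciesRecord, SpeciesTable, slugify

GUILDS = ("producer", "herbivore", "insectivore", "carnivore", "omnivore", "detritivore")

DEFAULT_GUILD_PROPORTIONS = {
    "producer": 0.30,
    "herbivore": 0.25,
    "insectivore": 0.15,
    "carnivore": 0.15,
    "omnivore": 0.10,
    "detritivore": 0.05,
}

#: log10 body-mass range (g) per guild; overall span >= 6 decades.
DEFAULT_MASS_RANGES = {
    "producer": (-2.0, 4.0),
    "herbivore": (-3.0, 5.0),
    "insectivore": (-3.0, 2.0),
    "carnivore": (-1.0, 5.0),
    "omnivore": (-2.0, 4.0),
    "detritivore": (-4.0, 1.0),
}

DEFAULT_HABITAT_MIX = {"aquatic": 0.35, "terrestrial": 0.45, "both": 0.20}

_CONSUMER_DIET_POOL = ("herbivore", "insectivore", "carnivore", "omnivore", "detritivore")


@dataclass
class CommunityConfig:
    """Knobs of one synthetic community."""

    n: int = 60
    guild_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GUILD_PROPORTIONS)
    )
    mass_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MASS_RANGES)
    )
    specialist_fraction: float = 0.3
    habitat_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HABITAT_MIX))
    #: Probabilities of genus sizes 1, 2, 3...: local assemblages are
    #: dominated by monospecific genera (site-level genus:species ratios
    #: around 0.8), so genus richness scales almost proportionally with
    #: species richness.
    genus_size_probs: tuple[float, ...] = (0.8, 0.15, 0.05)
    genera_per_family: int = 2
    families_per_order: int = 2
    orders_per_class: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"need n >= 2, got {self.n}")
        total = sum(self.guild_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"guild proportions must sum to 1, got {total}")
        for guild, (lo, hi) in self.mass_ranges.items():
            if not lo < hi:
                raise ValueError(f"invalid mass range for {guild}: ({lo}, {hi})")
        if not 0 <= self.specialist_fraction <= 1:
            raise ValueError("specialist fraction must be in [0, 1]")
        if abs(sum(self.genus_size_probs) - 1.0) > 1e-9:
            raise ValueError("genus size probabilities must sum to 1")


def _guild_counts(cfg: CommunityConfig) -> dict[str, int]:
    """Largest-remainder rounding of guild proportions to exactly n."""
    raw = {g: cfg.guild_proportions.get(g, 0.0) * cfg.n for g in GUILDS}
    counts = {g: int(np.floor(v)) for g, v in raw.items()}
    short = cfg.n - sum(counts.values())
    for g in sorted(raw, key=lambda g: raw[g] - counts[g], reverse=True)[:short]:
        counts[g] += 1
    if cfg.guild_proportions.get("producer", 0) > 0 and counts["producer"] < 1:
        raise ValueError("infeasible proportions: fewer than one producer")
    return counts


def _consumer_class(mass: float, habitat: set[str], rng: np.random.Generator) -> tuple[str, str]:
    """(phylum, class) for a consumer from its mass and habitat: small ->
    insects, mid-sized strict aquatics -> fish, the rest -> tetrapods."""
    if mass <= 1.0:
        return "Arthropoda", "Insecta"
    if habitat == {"aquatic"} and mass <= 1e4:
        return "Chordata", "Actinopterygii"
    if habitat == {"aquatic", "terrestrial"} and mass <= 1e3:
        return "Chordata", "Amphibia"
    return "Chordata", "Mammalia" if rng.uniform() < 0.5 else "Aves"


def generate_community(
    cfg: CommunityConfig | None = None, rng: np.random.Generator | None = None
) -> SpeciesTable:
    """Generate one seed-deterministic wetland-like species list."""
    cfg = cfg or CommunityConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    counts = _guild_counts(cfg)

    habitat_states = sorted(cfg.habitat_mix)
    habitat_probs = np.array([cfg.habitat_mix[s] for s in habitat_states])
    habitat_probs = habitat_probs / habitat_probs.sum()

    # draw raw species, then group them into a consistent taxonomy
    drafts = []
    for guild in GUILDS:
        lo, hi = cfg.mass_ranges[guild]
        for _ in range(counts[guild]):
            mass = 10.0 ** rng.uniform(lo, hi)
            if guild == "producer":
                habitat = {"aquatic"} if rng.uniform() < cfg.habitat_mix.get("aquatic", 0.3) else {
                    "terrestrial"
                }
                phylum, klass = "Tracheophyta", "Magnoliopsida"
                diet: set[str] = set()
            else:
                state = habitat_states[rng.choice(len(habitat_states), p=habitat_probs)]
                habitat = {"aquatic", "terrestrial"} if state == "both" else {state}
                phylum, klass = _consumer_class(mass, habitat, rng)
                diet = {guild}
                if rng.uniform() > cfg.specialist_fraction:
                    extras = [d for d in _CONSUMER_DIET_POOL if d != guild]
                    diet.add(extras[rng.integers(len(extras))])
            drafts.append((guild, phylum, klass, mass, habitat, diet))

    # taxonomy tree: within each class, chunk species into genera, genera
    # into families, and so on, so same genus implies same family etc.
    by_class: dict[tuple[str, str], list[int]] = {}
    for idx, d in enumerate(drafts):
        by_class.setdefault((d[1], d[2]), []).append(idx)

    size_probs = np.asarray(cfg.genus_size_probs)
    records = []
    for (phylum, klass), members in sorted(by_class.items()):
        # genus sizes drawn from the configured distribution (mostly 1)
        genus_of = []
        g = -1
        remaining = 0
        for _ in members:
            if remaining == 0:
                g += 1
                remaining = 1 + int(rng.choice(len(size_probs), p=size_probs))
            genus_of.append(g)
            remaining -= 1
        for pos, idx in enumerate(members):
            guild, _, _, mass, habitat, diet = drafts[idx]
            g = genus_of[pos]
            f = g // cfg.genera_per_family
            o = f // cfg.families_per_order
            genus = f"{klass[:4]}gen{g + 1}"
            name = f"{genus} sp{pos + 1}"
            size = (mass / 0.01) ** (1.0 / 3.0)  # inverse fallback allometry
            records.append(
                SpeciesRecord(
                    taxon_id=slugify(name),
                    name=name,
                    taxonomy={
                        "phylum": phylum,
                        "class": klass,
                        "order": f"{klass[:4]}ord{o + 1}",
                        "family": f"{klass[:4]}fam{f + 1}",
                        "genus": genus,
                        "species": name,
                    },
                    body_mass=mass,
                    body_size=size,
                    diet=set(diet),
                    habitat=set(habitat),
                    is_producer=guild == "producer",
                )
            )
    records.sort(key=lambda r: r.taxon_id)
    seed_tag = cfg.seed if cfg.seed is not None else "x"
    return SpeciesTable(site_id=f"synthetic_{seed_tag}_n{cfg.n}", records=records)


def inject_missing(
    table: SpeciesTable, trait: str, fraction: float, rng: np.random.Generator
) -> SpeciesTable:
    """Blank a trait in round(fraction * N) uniformly chosen records."""
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    if trait not in ("body_mass", "body_size", "diet", "habitat"):
        raise ValueError(f"unknown trait {trait!r}")
    out = table.copy()
    k = int(round(fraction * out.n_species))
    if k == 0:
        return out
    for idx in rng.choice(out.n_species, size=k, replace=False):
        rec = out.records[idx]
        if trait in ("body_mass", "body_size"):
            setattr(rec, trait, None)
        else:
            setattr(rec, trait, set())
        rec.trait_provenance[trait] = "unresolved"
    return out
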