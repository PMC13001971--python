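"""Trait enrichment: fill missing traits before network construction.

Two complementary strategies mirror how sparse species lists are usually
completed: (i) allometric length->mass relationships per taxon group, and
(ii) nearest-taxonomic-relative inference, walking up the ranks
genus -> family -> order -> class -> phylum among the co-listed taxa.
Numeric traits are imputed with the geometric mean of the relatives
(masses span many orders of magnitude, so an arithmetic mean would be
dominated by the largest relative); categorical traits take the union.

Also here: the coarse-graining of free-text diet terms into the closed
diet vocabulary, and the trait-perturbation machinery used by the
robustness experiments.
"""

from __future__ import annotations

import csv
import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .species_table import (
    DIET_CATEGORIES,
    TAXONOMY_RANKS,
    SpeciesRecord,
    SpeciesTable,
)

_SEARCH_ORDER = ("genus", "family", "order", "class", "phylum")
_NUMERIC_TRAITS = ("body_mass", "body_size")
_CATEGORICAL_TRAITS = ("diet", "habitat")
IMPUTABLE_TRAITS = _NUMERIC_TRAITS + _CATEGORICAL_TRAITS

PERTURB_MODES = ("randomize_diet", "fix_diet_herbivory", "randomize_mass")


def _data_text(name: str) -> str:
    return importlib.resources.files("trophonet.data").joinpath(name).read_text()


@dataclass
class AllometryTable:
    """mass = a * size**b per taxon group, with a mandatory fallback."""

    groups: dict[tuple[str, str], tuple[float, float]]
    fallback: tuple[float, float]

    def __post_init__(self) -> None:
        for key, (a, _) in list(self.groups.items()) + [(("*", "*"), self.fallback)]:
            if not a > 0:
                raise ValueError(f"allometry coefficient a must be > 0 for {key}")

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "AllometryTable":
        text = Path(path).read_text() if path else _data_text("allometry.yaml")
        raw = yaml.safe_load(text)
        groups = {
            (g["rank"], g["name"]): (float(g["a"]), float(g["b"]))
            for g in raw.get("groups", [])
        }
        fb = raw["fallback"]
        return cls(groups=groups, fallback=(float(fb["a"]), float(fb["b"])))

    def lookup(self, record: SpeciesRecord) -> tuple[float, float]:
        """Most specific matching group (genus outwards), else fallback."""
        for rank in _SEARCH_ORDER:
            name = record.rank_name(rank)
            if name and (rank, name) in self.groups:
                return self.groups[(rank, name)]
        return self.fallback


def impute_mass_from_size(
    size: float, group_key: SpeciesRecord | tuple[str, str] | None, table: AllometryTable
) -> float:
    """Allometric mass (g) from length (cm): mass = a * size**b."""
    if not size > 0:
        raise ValueError(f"body size must be > 0, got {size}")
    if isinstance(group_key, SpeciesRecord):
        a, b = table.lookup(group_key)
    elif group_key is not None and tuple(group_key) in table.groups:
        a, b = table.groups[tuple(group_key)]
    else:
        a, b = table.fallback
    return a * size**b


def enrich_masses(table: SpeciesTable, allometry: AllometryTable) -> SpeciesTable:
    """Fill missing body masses from body sizes where available."""
    out = table.copy()
    for rec in out.records:
        if rec.body_mass is None and rec.body_size is not None:
            rec.body_mass = impute_mass_from_size(rec.body_size, rec, allometry)
            rec.trait_provenance["body_mass"] = "imputed_allometric"
    return out


def _trait_present(rec: SpeciesRecord, trait: str) -> bool:
    value = getattr(rec, trait)
    return value is not None and value != set()


def impute_from_taxonomy(table: SpeciesTable, trait: str) -> SpeciesTable:
    """Impute a missing trait from the closest co-listed taxonomic relatives.

    Relatives are searched at genus, then family, order, class, phylum;
    the first rank with at least one informative relative is used.  A second
    pass over an already-imputed table changes nothing (values are read from
    a snapshot of the input).
    """
    if trait not in IMPUTABLE_TRAITS:
        raise ValueError(f"unknown trait {trait!r}; expected one of {IMPUTABLE_TRAITS}")
    donors = [r for r in table.records if _trait_present(r, trait)]
    out = table.copy()
    for rec in out.records:
        if _trait_present(rec, trait):
            continue
        if trait == "diet" and rec.is_producer:
            continue
        relatives: list[SpeciesRecord] = []
        for rank in _SEARCH_ORDER:
            name = rec.rank_name(rank)
            if not name:
                continue
            relatives = [
                d for d in donors if d.taxon_id != rec.taxon_id and d.rank_name(rank) == name
            ]
            if relatives:
                break
        if not relatives:
            rec.trait_provenance[trait] = "unresolved"
            continue
        if trait in _NUMERIC_TRAITS:
            logs = [math.log(getattr(d, trait)) for d in relatives]
            setattr(rec, trait, math.exp(sum(logs) / len(logs)))
        else:
            union: set[str] = set()
            for d in relatives:
                union |= getattr(d, trait)
            setattr(rec, trait, union)
        rec.trait_provenance[trait] = "imputed_taxonomic"
    return out


@dataclass
class EnrichmentReport:
    """Per-trait provenance counts; each trait's counts sum to N."""

    n: int
    counts: dict[str, dict[str, int]]
    audit: list[dict] = field(default_factory=list)


def enrichment_report(table: SpeciesTable) -> EnrichmentReport:
    counts = {
        t: {"measured": 0, "imputed_allometric": 0, "imputed_taxonomic": 0, "unresolved": 0}
        for t in IMPUTABLE_TRAITS
    }
    audit = []
    for rec in table.records:
        row = {"taxon_id": rec.taxon_id}
        for trait in IMPUTABLE_TRAITS:
            prov = rec.trait_provenance.get(trait, "unresolved")
            counts[trait][prov] += 1
            row[trait] = prov
        audit.append(row)
    return EnrichmentReport(n=table.n_species, counts=counts, audit=audit)


# --- diet coarse-graining --------------------------------------------------


def load_diet_mapping(path: str | Path | None = None) -> dict[str, str]:
    """term -> diet category table (shipped default covers common free-text
    diet terms)."""
    if path:
        text = Path(path).read_text()
    else:
        text = _data_text("diet_terms.csv")
    mapping = {}
    for row in csv.DictReader(text.splitlines()):
        cat = row["category"].strip().lower()
        if cat not in DIET_CATEGORIES:
            raise ValueError(f"diet mapping target {cat!r} outside vocabulary")
        mapping[row["term"].strip().lower()] = cat
    return mapping


def coarse_grain_diet(raw_terms: set[str], mapping: dict[str, str] | None = None) -> set[str]:
    """Map free-text diet terms into the closed vocabulary.

    Exact lookup first, then longest-substring match (so ``"freshwater
    fish"`` hits ``"fish"``); unmapped terms contribute ``unknown``.  The
    result is never empty.
    """
    if mapping is None:
        mapping = load_diet_mapping()
    out: set[str] = set()
    for term in raw_terms:
        term = term.strip().lower()
        if term in mapping:
            out.add(mapping[term])
            continue
        hits = [k for k in mapping if k in term]
        if hits:
            out.add(mapping[max(hits, key=len)])
        else:
            out.add("unknown")
    return out or {"unknown"}


def enrich_diets(table: SpeciesTable, mapping: dict[str, str] | None = None) -> SpeciesTable:
    """Coarse-grain raw diet terms for every consumer lacking categories."""
    out = table.copy()
    for rec in out.records:
        if rec.is_producer or rec.diet:
            continue
        if rec.diet_raw:
            rec.diet = coarse_grain_diet(rec.diet_raw, mapping)
            rec.trait_provenance["diet"] = "measured"
    return out


def enrich(
    table: SpeciesTable,
    allometry: AllometryTable | None = None,
    diet_mapping: dict[str, str] | None = None,
) -> SpeciesTable:
    """Full enrichment pipeline: coarse-grain diets, allometric masses,
    then taxonomic inference for every still-missing trait."""
    allometry = allometry or AllometryTable.from_yaml()
    out = enrich_diets(table, diet_mapping)
    out = enrich_masses(out, allometry)
    for trait in ("body_size", "body_mass", "diet", "habitat"):
        out = impute_from_taxonomy(out, trait)
    # a size recovered taxonomically can still feed the allometric step
    out = enrich_masses(out, allometry)
    return out


# --- trait perturbation ----------------------------------------------------


def perturb_traits(
    table: SpeciesTable,
    fraction: float,
    mode: str,
    rng: np.random.Generator,
) -> SpeciesTable:
    """Corrupt a fraction of consumer trait values for robustness runs.

    Exactly ``round(fraction * N_consumers)`` consumers are altered.
    ``randomize_diet`` redraws one category from the pool observed in the
    table; ``fix_diet_herbivory`` overwrites the diet with ``{herbivore}``;
    ``randomize_mass`` resamples log-mass uniformly within the observed
    log-mass range of the table.
    """
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    if mode not in PERTURB_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {PERTURB_MODES}")
    out = table.copy()
    consumers = [r for r in out.records if not r.is_producer]
    k = int(round(fraction * len(consumers)))
    if k == 0:
        return out
    chosen = rng.choice(len(consumers), size=k, replace=False)
    if mode == "randomize_diet":
        pool = sorted({c for r in table.records for c in r.diet})
        if not pool:
            raise ValueError("no diet categories observed in the table")
    elif mode == "randomize_mass":
        masses = [r.body_mass for r in table.records if r.body_mass is not None]
        if not masses:
            raise ValueError("no masses observed in the table")
        lo, hi = math.log10(min(masses)), math.log10(max(masses))
    for idx in sorted(chosen):
        rec = consumers[idx]
        if mode == "fix_diet_herbivory":
            rec.diet = {"herbivore"}
        elif mode == "randomize_diet":
            rec.diet = {pool[rng.integers(len(pool))]}
        else:
            rec.body_mass = 10 ** rng.uniform(lo, hi)
    return out
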