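"""Domain types and file I/O for species lists and trophic networks.

A :class:`SpeciesTable` is the primary input of the whole pipeline: one row
per taxon, annotated with taxonomy ranks, body mass/size, diet terms,
habitat and a primary-producer flag.  Networks are exchanged as plain
edge-list CSVs (consumer, resource) plus a node table so they can be opened
in standard network software.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

TAXONOMY_RANKS = ("phylum", "class", "order", "family", "genus", "species")

#: Closed diet vocabulary every coarse-grained term maps into.
DIET_CATEGORIES = frozenset(
    {
        "herbivore",
        "carnivore",
        "insectivore",
        "piscivore",
        "omnivore",
        "detritivore",
        "planktivore",
        "scavenger",
        "unknown",
    }
)

HABITATS = frozenset({"aquatic", "terrestrial"})

PROVENANCE_LEVELS = ("measured", "imputed_allometric", "imputed_taxonomic", "unresolved")

#: Default CSV column schema; override any entry via the ``schema`` argument
#: of :func:`read_species_list`.
DEFAULT_SCHEMA = {
    "name": "name",
    "phylum": "phylum",
    "class": "class",
    "order": "order",
    "family": "family",
    "genus": "genus",
    "species": "species",
    "body_mass": "mass_g",
    "body_size": "size_cm",
    "diet": "diet",
    "habitat": "habitat",
    "is_producer": "producer",
}

_TRAITS = ("body_mass", "body_size", "diet", "habitat")


def slugify(name: str) -> str:
    """Lower-case a taxon name into a stable identifier."""
    slug = re.sub(r"[^a-z0-9]+", "_", name.strip().lower()).strip("_")
    if not slug:
        raise ValueError(f"cannot derive a taxon_id from name {name!r}")
    return slug


@dataclass
class SpeciesRecord:
    """One taxon of a species list.

    ``trait_provenance`` tracks, per trait, whether the value was measured,
    imputed (allometrically or from taxonomic relatives) or is unresolved.
    Producers consume nothing in this model, so their diet is kept empty.
    """

    taxon_id: str
    name: str
    taxonomy: dict[str, str] = field(default_factory=dict)
    body_mass: float | None = None
    body_size: float | None = None
    diet_raw: set[str] = field(default_factory=set)
    diet: set[str] = field(default_factory=set)
    habitat: set[str] = field(default_factory=set)
    is_producer: bool = False
    trait_provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.body_mass is not None and not self.body_mass > 0:
            raise ValueError(f"{self.taxon_id}: body_mass must be > 0, got {self.body_mass}")
        if self.body_size is not None and not self.body_size > 0:
            raise ValueError(f"{self.taxon_id}: body_size must be > 0, got {self.body_size}")
        bad = self.diet - DIET_CATEGORIES
        if bad:
            raise ValueError(f"{self.taxon_id}: diet categories {sorted(bad)} outside vocabulary")
        bad = self.habitat - HABITATS
        if bad:
            raise ValueError(f"{self.taxon_id}: habitats {sorted(bad)} outside vocabulary")
        if self.is_producer:
            self.diet = set()
        for trait in _TRAITS:
            self.trait_provenance.setdefault(
                trait, "measured" if self._has_trait(trait) else "unresolved"
            )

    def _has_trait(self, trait: str) -> bool:
        value = getattr(self, trait)
        return value is not None and value != set()

    def rank_name(self, rank: str) -> str | None:
        return self.taxonomy.get(rank)

    def copy(self) -> "SpeciesRecord":
        return replace(
            self,
            taxonomy=dict(self.taxonomy),
            diet_raw=set(self.diet_raw),
            diet=set(self.diet),
            habitat=set(self.habitat),
            trait_provenance=dict(self.trait_provenance),
        )


@dataclass
class SpeciesTable:
    """Ordered species list of one site."""

    site_id: str
    records: list[SpeciesRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 1:
            raise ValueError("a species table needs at least one record")
        seen: set[str] = set()
        for rec in self.records:
            if rec.taxon_id in seen:
                raise ValueError(f"duplicate taxon_id {rec.taxon_id!r} in site {self.site_id}")
            seen.add(rec.taxon_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def n_species(self) -> int:
        return len(self.records)

    @property
    def producers(self) -> list[SpeciesRecord]:
        return [r for r in self.records if r.is_producer]

    @property
    def consumers(self) -> list[SpeciesRecord]:
        return [r for r in self.records if not r.is_producer]

    @property
    def taxon_ids(self) -> list[str]:
        return [r.taxon_id for r in self.records]

    def get(self, taxon_id: str) -> SpeciesRecord:
        for rec in self.records:
            if rec.taxon_id == taxon_id:
                return rec
        raise KeyError(taxon_id)

    def copy(self) -> "SpeciesTable":
        return SpeciesTable(self.site_id, [r.copy() for r in self.records])


@dataclass
class EligibilityReport:
    eligible: bool
    reasons: list[str]


def eligibility_check(
    table: SpeciesTable, min_species: int = 30, min_producers: int = 10
) -> EligibilityReport:
    """Site-selection rule: strictly more than ``min_species`` taxa and at
    least ``min_producers`` primary producers."""
    reasons = []
    n = table.n_species
    n_prod = len(table.producers)
    if not n > min_species:
        reasons.append(f"species richness {n} not > {min_species}")
    if n_prod < min_producers:
        reasons.append(f"only {n_prod} primary producers, need >= {min_producers}")
    return EligibilityReport(eligible=not reasons, reasons=reasons)


def _parse_set(cell) -> set[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
        return set()
    return {t.strip().lower() for t in re.split(r"[;|,]", str(cell)) if t.strip()}


def _parse_bool(cell) -> bool:
    return str(cell).strip().lower() in {"1", "true", "yes", "y", "t"}


def _parse_mass(cell, taxon: str, what: str) -> float | None:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
        return None
    try:
        value = float(cell)
    except (TypeError, ValueError):
        warnings.warn(f"{taxon}: unparseable {what} {cell!r}, treated as missing")
        return None
    if value <= 0:
        warnings.warn(f"{taxon}: non-positive {what} {cell!r}, treated as missing")
        return None
    return value


def read_species_list(
    path: str | Path, schema: dict[str, str] | None = None, site_id: str | None = None
) -> SpeciesTable:
    """Read a species-list CSV into a :class:`SpeciesTable`.

    ``schema`` maps logical field names (keys of :data:`DEFAULT_SCHEMA`) to
    the actual column headers of the file.  Missing trait cells become
    missing values with provenance ``unresolved``; a duplicate taxon id is a
    hard error so that two rows can never be silently merged into one node.
    """
    path = Path(path)
    cols = dict(DEFAULT_SCHEMA)
    if schema:
        cols.update(schema)
    df = pd.read_csv(path, dtype=str)
    if cols["name"] not in df.columns:
        raise ValueError(f"{path}: required column {cols['name']!r} missing")
    if cols["is_producer"] not in df.columns:
        raise ValueError(f"{path}: required column {cols['is_producer']!r} missing")

    records = []
    for _, row in df.iterrows():
        name = str(row[cols["name"]]).strip()
        taxon_id = slugify(name)
        taxonomy = {}
        for rank in TAXONOMY_RANKS:
            col = cols.get(rank)
            if col in df.columns:
                value = row[col]
                if value is not None and str(value).strip() not in {"", "nan"}:
                    taxonomy[rank] = str(value).strip()
        diet_raw = _parse_set(row[cols["diet"]]) if cols["diet"] in df.columns else set()
        diet = diet_raw & DIET_CATEGORIES
        habitat = (
            _parse_set(row[cols["habitat"]]) & HABITATS if cols["habitat"] in df.columns else set()
        )
        records.append(
            SpeciesRecord(
                taxon_id=taxon_id,
                name=name,
                taxonomy=taxonomy,
                body_mass=_parse_mass(
                    row.get(cols["body_mass"]) if cols["body_mass"] in df.columns else None,
                    taxon_id,
                    "body mass",
                ),
                body_size=_parse_mass(
                    row.get(cols["body_size"]) if cols["body_size"] in df.columns else None,
                    taxon_id,
                    "body size",
                ),
                diet_raw=diet_raw,
                diet=diet,
                habitat=habitat,
                is_producer=_parse_bool(row[cols["is_producer"]]),
            )
        )
    return SpeciesTable(site_id or path.stem, records)


def write_species_list(table: SpeciesTable, path: str | Path) -> None:
    """Inverse of :func:`read_species_list` under the default schema."""
    rows = []
    for rec in table.records:
        row = {"name": rec.name}
        for rank in TAXONOMY_RANKS:
            row[rank] = rec.taxonomy.get(rank, "")
        row["mass_g"] = "" if rec.body_mass is None else repr(rec.body_mass)
        row["size_cm"] = "" if rec.body_size is None else repr(rec.body_size)
        row["diet"] = ";".join(sorted(rec.diet or rec.diet_raw))
        row["habitat"] = ";".join(sorted(rec.habitat))
        row["producer"] = int(rec.is_producer)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# --- network I/O -----------------------------------------------------------


def _node_path(edge_path: Path) -> Path:
    return edge_path.with_suffix(".nodes.csv")


def write_network_csv(net, path: str | Path, node_path: str | Path | None = None) -> None:
    """Write a directed edge list (consumer_id, resource_id) plus a node
    table (``<path stem>.nodes.csv`` by default)."""
    path = Path(path)
    node_path = Path(node_path) if node_path else _node_path(path)
    consumers, resources = np.nonzero(net.matrix)
    ids = net.index
    pd.DataFrame(
        {
            "consumer_id": [ids[i] for i in consumers],
            "resource_id": [ids[j] for j in resources],
        }
    ).to_csv(path, index=False)
    pd.DataFrame({"taxon_id": ids}).to_csv(node_path, index=False)


def read_network_csv(path: str | Path, node_path: str | Path | None = None):
    """Read a network written by :func:`write_network_csv`; an edge that
    references a taxon absent from the node table is a hard error."""
    from .anm_core import TrophicNetwork  # local import to avoid a cycle

    path = Path(path)
    node_path = Path(node_path) if node_path else _node_path(path)
    nodes = pd.read_csv(node_path, dtype=str)
    ids = list(nodes["taxon_id"])
    pos = {t: i for i, t in enumerate(ids)}
    matrix = np.zeros((len(ids), len(ids)), dtype=np.int8)
    edges = pd.read_csv(path, dtype=str)
    for _, row in edges.iterrows():
        c, r = row["consumer_id"], row["resource_id"]
        if c not in pos or r not in pos:
            missing = c if c not in pos else r
            raise ValueError(f"{path}: edge references unknown node {missing!r}")
        matrix[pos[c], pos[r]] = 1
    return TrophicNetwork(index=ids, matrix=matrix)
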