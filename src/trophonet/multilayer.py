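"""Multilayer trophic networks: 2 habitat layers x 2 life stages.

Each animal is unfolded into a larval and an adult node; on the niche
axis the larva weighs one order of magnitude less than the adult.
Producers stay single nodes in their own layer.  Trophic links obey the
allometric and diet criteria *and* a compartment operator that only
admits links between co-occupied (stage, layer) compartments; ontogenic
edges join each species' larva to its adult, and movement edges mark the
adults able to cross the air-water interface (once, e.g. mosquitoes, or
repeatedly, e.g. frogs).  Amphibious adults are single nodes with
membership in both layers rather than duplicated per layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .anm_core import (
    BuildParams,
    GRAZER_DIETS,
    allometric_criterion,
    diet_criterion,
    sample_niche,
)
from .species_table import SpeciesRecord, SpeciesTable

STAGES = ("larva", "adult")
LAYERS = ("aquatic", "terrestrial")
CROSSING = ("never", "once", "repeatedly")

#: Maximum community size for a multilayer build; beyond this the stage- and
#: layer-unfolded network becomes unmanageably large.
MAX_MULTILAYER_SPECIES = 200

#: Larval niche mass = adult mass / LARVA_MASS_FACTOR.
LARVA_MASS_FACTOR = 10.0

#: (rank, name) -> life-history rule for mixed-habitat taxa.
DEFAULT_LIFE_HISTORY_RULES: list[tuple[str, str, str]] = [
    ("class", "Amphibia", "amphibious_repeated"),
    ("order", "Odonata", "amphibious_repeated"),
    ("order", "Anura", "amphibious_repeated"),
    ("family", "Culicidae", "cross_once"),
    ("order", "Diptera", "cross_once"),
    ("class", "Aves", "adult_crossing_only"),
]


@dataclass(frozen=True)
class StagedNode:
    """(species, stage) node with its layer membership."""

    taxon_id: str
    stage: str
    layers: frozenset[str]
    niche_mass: float | None
    can_cross: str = "never"
    flagged: bool = False

    @property
    def layer(self) -> str:
        """Primary layer (aquatic first for bi-layer membership)."""
        return sorted(self.layers)[0]

    def compartments(self) -> set[tuple[str, str]]:
        return {(self.stage, layer) for layer in self.layers}


@dataclass
class CompartmentOperator:
    """4x4 binary matrix over (stage, layer) compartments stating which
    compartment pairs may host a trophic link; the default admits only
    within-compartment links."""

    matrix: np.ndarray = field(
        default_factory=lambda: np.eye(4, dtype=int)
    )

    _ORDER = [(s, l) for s in STAGES for l in LAYERS]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=int)
        if self.matrix.shape != (4, 4):
            raise ValueError("compartment operator must be 4x4")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("compartment operator must be symmetric")
        if not np.all(np.diag(self.matrix) == 1):
            raise ValueError("compartment operator diagonal must be all ones")

    def allows(self, a: StagedNode, b: StagedNode) -> bool:
        idx = {c: i for i, c in enumerate(self._ORDER)}
        return any(
            self.matrix[idx[ca], idx[cb]]
            for ca in a.compartments()
            for cb in b.compartments()
        )


@dataclass
class MultilayerNetwork:
    nodes: list[StagedNode]
    trophic_edges: list[tuple[StagedNode, StagedNode]]
    ontogenic_edges: list[tuple[StagedNode, StagedNode]]
    movement_edges: list[StagedNode]
    operator: CompartmentOperator


def _match_rule(rec: SpeciesRecord, rules: list[tuple[str, str, str]]) -> str | None:
    for rank, name, rule in rules:
        if rec.rank_name(rank) == name:
            return rule
    return None


def assign_compartments(
    table: SpeciesTable, rules: list[tuple[str, str, str]] | None = None
) -> list[StagedNode]:
    """Unfold each taxon into staged nodes with layer membership.

    Single-habitat taxa put both stages in that layer and never cross.
    Mixed-habitat taxa go through the life-history rule table; an unmatched
    mixed taxon defaults to an aquatic larva and a repeatedly crossing
    adult, and is flagged for review.
    """
    rules = rules if rules is not None else DEFAULT_LIFE_HISTORY_RULES
    nodes: list[StagedNode] = []
    for rec in table.records:
        if not rec.habitat:
            raise ValueError(f"{rec.taxon_id}: empty habitat set; enrich the table first")
        mass = rec.body_mass
        if rec.is_producer:
            nodes.append(
                StagedNode(rec.taxon_id, "adult", frozenset(rec.habitat), mass, "never")
            )
            continue
        larva_mass = None if mass is None else mass / LARVA_MASS_FACTOR
        if rec.habitat == {"terrestrial"} or rec.habitat == {"aquatic"}:
            layer = frozenset(rec.habitat)
            nodes.append(StagedNode(rec.taxon_id, "larva", layer, larva_mass, "never"))
            nodes.append(StagedNode(rec.taxon_id, "adult", layer, mass, "never"))
            continue
        rule = _match_rule(rec, rules)
        flagged = rule is None
        rule = rule or "amphibious_repeated"
        if rule == "amphibious_repeated":
            nodes.append(
                StagedNode(rec.taxon_id, "larva", frozenset({"aquatic"}), larva_mass, "never", flagged)
            )
            nodes.append(
                StagedNode(
                    rec.taxon_id,
                    "adult",
                    frozenset({"aquatic", "terrestrial"}),
                    mass,
                    "repeatedly",
                    flagged,
                )
            )
        elif rule == "cross_once":
            nodes.append(
                StagedNode(rec.taxon_id, "larva", frozenset({"aquatic"}), larva_mass, "never")
            )
            nodes.append(
                StagedNode(rec.taxon_id, "adult", frozenset({"terrestrial"}), mass, "once")
            )
        elif rule == "adult_crossing_only":
            nodes.append(
                StagedNode(rec.taxon_id, "larva", frozenset({"terrestrial"}), larva_mass, "never")
            )
            nodes.append(
                StagedNode(
                    rec.taxon_id,
                    "adult",
                    frozenset({"aquatic", "terrestrial"}),
                    mass,
                    "repeatedly",
                )
            )
        else:
            raise ValueError(f"unknown life-history rule {rule!r}")
    return nodes


def build_multilayer(
    table: SpeciesTable,
    params: BuildParams | None = None,
    rules: list[tuple[str, str, str]] | None = None,
    rng: np.random.Generator | None = None,
    operator: CompartmentOperator | None = None,
) -> MultilayerNetwork:
    """Apply the niche model on the stage-unfolded community.

    Niche positions are min-max log-mass over all consumer staged nodes
    (larvae at a tenth of the adult mass), so larvae sit at or below their
    adults.  A trophic link requires the allometric criterion, the diet
    criterion of the consuming species, and operator-compatible
    compartments; producer nodes take the probabilistic grazing link under
    the same compartment veto.
    """
    if table.n_species > MAX_MULTILAYER_SPECIES:
        raise ValueError(
            f"{table.n_species} species exceeds the multilayer cap of "
            f"{MAX_MULTILAYER_SPECIES}"
        )
    params = params or BuildParams()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    operator = operator or CompartmentOperator()
    nodes = assign_compartments(table, rules)
    records = {rec.taxon_id: rec for rec in table.records}

    consumer_nodes = [nd for nd in nodes if not records[nd.taxon_id].is_producer]
    for nd in consumer_nodes:
        if nd.niche_mass is None:
            raise ValueError(f"consumer {nd.taxon_id} has no body mass; enrich the table first")
    logm = np.array([math.log10(nd.niche_mass) for nd in consumer_nodes])
    lo, hi = logm.min(), logm.max()
    n_of: dict[StagedNode, float] = {}
    for nd in nodes:
        if records[nd.taxon_id].is_producer:
            n_of[nd] = 0.0
        else:
            value = math.log10(nd.niche_mass)
            n_of[nd] = 0.5 if hi == lo else (value - lo) / (hi - lo)

    niche: dict[StagedNode, tuple[float, float]] = {}
    for nd in consumer_nodes:
        niche[nd] = sample_niche(n_of[nd], params.C, params.niche_mode, rng)

    trophic: list[tuple[StagedNode, StagedNode]] = []
    for consumer in consumer_nodes:
        crec = records[consumer.taxon_id]
        c_i, r_i = niche[consumer]
        for resource in nodes:
            if resource.taxon_id == consumer.taxon_id:
                continue
            if not operator.allows(consumer, resource):
                continue
            rrec = records[resource.taxon_id]
            if rrec.is_producer:
                if (not crec.diet or crec.diet & GRAZER_DIETS) and rng.uniform() < params.C:
                    trophic.append((consumer, resource))
            elif allometric_criterion(n_of[resource], c_i, r_i) and diet_criterion(crec, rrec):
                trophic.append((consumer, resource))

    ontogenic = []
    by_taxon: dict[str, dict[str, StagedNode]] = {}
    for nd in nodes:
        by_taxon.setdefault(nd.taxon_id, {})[nd.stage] = nd
    for taxon, stages in sorted(by_taxon.items()):
        if "larva" in stages and "adult" in stages:
            ontogenic.append((stages["larva"], stages["adult"]))

    movement = [nd for nd in nodes if nd.can_cross != "never"]
    return MultilayerNetwork(
        nodes=nodes,
        trophic_edges=trophic,
        ontogenic_edges=ontogenic,
        movement_edges=movement,
        operator=operator,
    )


def multilayer_edge_table(ml: MultilayerNetwork):
    """Tidy edge list with an edge-type column, ready for CSV export."""
    import pandas as pd

    rows = []
    for a, b in ml.trophic_edges:
        rows.append(
            {
                "edge_type": "trophic",
                "source_taxon": a.taxon_id, "source_stage": a.stage,
                "target_taxon": b.taxon_id, "target_stage": b.stage,
            }
        )
    for a, b in ml.ontogenic_edges:
        rows.append(
            {
                "edge_type": "ontogenic",
                "source_taxon": a.taxon_id, "source_stage": a.stage,
                "target_taxon": b.taxon_id, "target_stage": b.stage,
            }
        )
    for nd in ml.movement_edges:
        rows.append(
            {
                "edge_type": "movement",
                "source_taxon": nd.taxon_id, "source_stage": nd.stage,
                "target_taxon": nd.taxon_id, "target_stage": nd.stage,
            }
        )
    return pd.DataFrame(rows)
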