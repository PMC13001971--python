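"""Rarefaction experiments: taxonomic collapse, random and functional
species removal, and standardized-difference comparison of the perturbed
networks against the unperturbed ensemble.

Collapsed nodes take the *arithmetic* mean of their members' numeric
traits (the deliberate asymmetry with geometric-mean imputation reflects
that aggregation averages a known group, while imputation guesses across
orders of magnitude) and the union of their categorical traits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anm_core import BuildParams, build_ensemble
from .descriptors import compute_descriptors
from .species_table import SpeciesRecord, SpeciesTable, slugify

COLLAPSE_RANKS = ("genus", "family", "order")
RAREFACTION_KINDS = ("taxonomic", "random", "functional_diet", "functional_mass")

#: Default mass-class edges: the four decades from 10^1 to 10^5 g.
DEFAULT_MASS_EDGES = (1e1, 1e2, 1e3, 1e4, 1e5)


@dataclass
class RarefactionSpec:
    """What to remove or collapse."""

    kind: str
    rank: str | None = None
    fraction: float = 0.9
    group: str | None = None
    mass_class: int | None = None
    mass_edges: tuple[float, ...] = field(default_factory=lambda: DEFAULT_MASS_EDGES)

    def __post_init__(self) -> None:
        if self.kind not in RAREFACTION_KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if not 0 <= self.fraction <= 1:
            raise ValueError("fraction must be in [0, 1]")
        if any(a >= b for a, b in zip(self.mass_edges, self.mass_edges[1:])):
            raise ValueError("mass class edges must be increasing")
        if self.kind == "taxonomic" and self.rank not in COLLAPSE_RANKS:
            raise ValueError(f"rank must be one of {COLLAPSE_RANKS}")


TAXONOMY_ORDER = ("phylum", "class", "order", "family", "genus", "species")


def collapse_to_rank(table: SpeciesTable, rank: str) -> SpeciesTable:
    """One node per distinct name at ``rank``.

    Numeric traits of the collapsed node are arithmetic means of the
    members (size and mass separately), diet and habitat are unions, and
    the node is a producer if any member is.  Records lacking the rank
    pass through unchanged.  Never increases N; idempotent at a rank.
    """
    if rank not in COLLAPSE_RANKS:
        raise ValueError(f"rank must be one of {COLLAPSE_RANKS}")
    keep_ranks = TAXONOMY_ORDER[: TAXONOMY_ORDER.index(rank) + 1]
    groups: dict[str, list[SpeciesRecord]] = {}
    passthrough: list[SpeciesRecord] = []
    for rec in table.records:
        name = rec.rank_name(rank)
        if name is None:
            passthrough.append(rec.copy())
        else:
            groups.setdefault(name, []).append(rec)

    records = list(passthrough)
    for name, members in groups.items():
        if len(members) == 1 and members[0].rank_name(rank) == members[0].name:
            records.append(members[0].copy())
            continue
        masses = [m.body_mass for m in members if m.body_mass is not None]
        sizes = [m.body_size for m in members if m.body_size is not None]
        diet: set[str] = set()
        habitat: set[str] = set()
        raw: set[str] = set()
        for m in members:
            diet |= m.diet
            habitat |= m.habitat
            raw |= m.diet_raw
        taxonomy = {
            r: members[0].taxonomy[r] for r in keep_ranks if r in members[0].taxonomy
        }
        taxonomy[rank] = name
        records.append(
            SpeciesRecord(
                taxon_id=slugify(name),
                name=name,
                taxonomy=taxonomy,
                body_mass=float(np.mean(masses)) if masses else None,
                body_size=float(np.mean(sizes)) if sizes else None,
                diet_raw=raw,
                diet=diet,
                habitat=habitat,
                is_producer=any(m.is_producer for m in members),
            )
        )
    records.sort(key=lambda r: r.taxon_id)
    return SpeciesTable(site_id=f"{table.site_id}_{rank}", records=records)


def random_rarefaction(
    table: SpeciesTable, fraction: float, rng: np.random.Generator
) -> SpeciesTable:
    """Remove exactly round(fraction * N) uniformly chosen records."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    k = int(round(fraction * table.n_species))
    if table.n_species - k < 2:
        raise ValueError("removal would leave fewer than 2 species")
    if k == 0:
        return table.copy()
    drop = set(rng.choice(table.n_species, size=k, replace=False).tolist())
    records = [rec.copy() for i, rec in enumerate(table.records) if i not in drop]
    return SpeciesTable(site_id=table.site_id, records=records)


def _group_members(table: SpeciesTable, spec: RarefactionSpec) -> list[int]:
    if spec.kind == "functional_diet":
        group = spec.group
        if group in ("producer", "plants", "plant"):
            return [i for i, r in enumerate(table.records) if r.is_producer]
        if group is None or group.rstrip("s") not in (
            "herbivore", "carnivore", "insectivore", "omnivore", "detritivore",
            "piscivore", "planktivore", "scavenger",
        ):
            raise ValueError(f"unknown functional group {spec.group!r}")
        cat = group.rstrip("s")
        return [i for i, r in enumerate(table.records) if cat in r.diet]
    # functional_mass
    if spec.mass_class is None or not 0 <= spec.mass_class < len(spec.mass_edges) - 1:
        raise ValueError(f"mass_class must index into {spec.mass_edges}")
    lo, hi = spec.mass_edges[spec.mass_class], spec.mass_edges[spec.mass_class + 1]
    return [
        i
        for i, r in enumerate(table.records)
        if not r.is_producer and r.body_mass is not None and lo <= r.body_mass < hi
    ]


def functional_rarefaction(
    table: SpeciesTable, spec: RarefactionSpec, rng: np.random.Generator
) -> SpeciesTable:
    """Remove round(fraction * group size) members of one diet group or
    mass decade; every other record is untouched."""
    members = _group_members(table, spec)
    if not members:
        raise ValueError("functional group is empty")
    k = int(round(spec.fraction * len(members)))
    if k == 0:
        return table.copy()
    drop = set(np.asarray(members)[rng.choice(len(members), size=k, replace=False)].tolist())
    records = [rec.copy() for i, rec in enumerate(table.records) if i not in drop]
    if len(records) < 2:
        raise ValueError("removal would leave fewer than 2 species")
    return SpeciesTable(site_id=table.site_id, records=records)


def apply_rarefaction(
    table: SpeciesTable, spec: RarefactionSpec, rng: np.random.Generator
) -> SpeciesTable:
    if spec.kind == "taxonomic":
        return collapse_to_rank(table, spec.rank)
    if spec.kind == "random":
        return random_rarefaction(table, spec.fraction, rng)
    return functional_rarefaction(table, spec, rng)


def standardized_difference(x: float, baseline) -> float:
    """|x - mean(baseline)| / sd(baseline); an exact-zero spread yields an
    +inf sentinel with a warning."""
    baseline = np.asarray(list(baseline), dtype=float)
    if baseline.size < 3:
        raise ValueError(f"baseline needs >= 3 values, got {baseline.size}")
    sd = baseline.std(ddof=1)
    if sd == 0:
        if x != baseline.mean():
            warnings.warn("baseline standard deviation is 0; reporting +inf")
            return math.inf
        return 0.0
    return float(abs(x - baseline.mean()) / sd)


#: Scalar descriptors reported by rarefaction experiments (cheap, stable).
REPORT_DESCRIPTORS = (
    "N", "AVL", "CON", "IND", "OUT", "ASYM", "MAXDEG", "MAXIND", "MAXOUT",
    "TOP", "BAS", "INT", "AVGL", "MAXCHAIN", "LOOP1", "NEST", "MOD", "PART", "CLUST",
)


def _scalar_frame(ensemble, table, descriptors, **kwargs) -> pd.DataFrame:
    kwargs.setdefault("max_chains", 20_000)
    kwargs.setdefault("max_chain_len", 20)
    kwargs.setdefault("max_loops", 2_000)
    rows = []
    for net in ensemble:
        ds = compute_descriptors(net, table, **kwargs)
        rows.append({d: ds.scalars[d] for d in descriptors})
    return pd.DataFrame(rows)


def rarefaction_experiment(
    table: SpeciesTable,
    spec: RarefactionSpec,
    params: BuildParams | None = None,
    rng: np.random.Generator | None = None,
    n_replicates: int | None = None,
    descriptors: tuple[str, ...] = REPORT_DESCRIPTORS,
    redraw_per_replicate: bool = True,
) -> pd.DataFrame:
    """Original vs perturbed ensembles, per-descriptor standardized
    differences.

    The removal is redrawn for every perturbed replicate (so replicate
    spread includes sampling noise of the removal itself).  Returns a tidy
    frame with columns (descriptor, original_mean, original_sd,
    perturbed_value, standardized_difference).
    """
    params = params or BuildParams()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    original = build_ensemble(table, params, rng, n_replicates=n_replicates)
    count = len(original)
    if redraw_per_replicate and spec.kind in ("random", "functional_diet", "functional_mass"):
        perturbed_nets = []
        for _ in range(count):
            sub = apply_rarefaction(table, spec, rng)
            perturbed_nets.extend(build_ensemble(sub, params, rng, n_replicates=1).networks)
        perturbed_frames = [
            _scalar_frame([net], None, descriptors) for net in perturbed_nets
        ]
        perturbed = pd.concat(perturbed_frames, ignore_index=True)
    else:
        sub = apply_rarefaction(table, spec, rng)
        perturbed = _scalar_frame(
            build_ensemble(sub, params, rng, n_replicates=count), None, descriptors
        )
    base = _scalar_frame(original, table, descriptors)

    rows = []
    for d in descriptors:
        baseline = base[d].dropna()
        x = float(perturbed[d].mean())
        sd = float(baseline.std(ddof=1))
        rows.append(
            {
                "descriptor": d,
                "original_mean": float(baseline.mean()),
                "original_sd": sd,
                "perturbed_value": x,
                "standardized_difference": standardized_difference(x, baseline)
                if len(baseline) >= 3
                else math.nan,
            }
        )
    return pd.DataFrame(rows)
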