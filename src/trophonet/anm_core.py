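"""The diet/habitat-constrained Allometric Niche Model (ANM).

Every species occupies a position ``n`` on a [0, 1] niche axis set by its
relative log body mass within the community.  Each consumer draws a feeding
optimum ``c`` and feeding range ``r`` and eats every species whose position
falls inside ``[c - r/2, c + r/2]``, *provided* its recorded diet is
compatible with the resource's taxonomic class.  Primary producers sit at
``n = 0``, consume nothing, and are eaten with probability ``C`` by any
herbivore irrespective of size (a grazer rarely consumes the whole plant,
so the plant-herbivore allometric relationship vanishes).  A staged
relaxation pass guarantees every consumer eats something and every
producer is eaten, which uneven species lists cannot always satisfy under
the strict rules.

Two niche parameterizations are provided.  ``classic`` scales the feeding
range with the position, ``r = n * x`` with ``x ~ Beta(1, 1/(2C) - 1)``,
which gives the target connectance ``C`` in expectation.  ``literal`` draws
``r ~ Beta(1, 2C)`` truncated to ``r <= 2n``; at the default ``C = 0.12``
its mean untruncated range is ~0.81, near-saturating the axis, so it is
kept only for fidelity experiments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .species_table import SpeciesRecord, SpeciesTable

NICHE_MODES = ("classic", "literal")

#: Which resource classes each diet category may feed on.  ``omnivore``
#: (and the agnostic ``unknown``) are wildcards; ``detritivore`` is treated
#: as basal, feeding on the producer pool.
DEFAULT_DIET_RULES: dict[str, frozenset[str]] = {
    "herbivore": frozenset({"producer"}),
    "carnivore": frozenset({"animal", "insect", "fish"}),
    "insectivore": frozenset({"insect"}),
    "piscivore": frozenset({"fish"}),
    "omnivore": frozenset({"producer", "animal", "insect", "fish", "plankton"}),
    "detritivore": frozenset({"producer"}),
    "planktivore": frozenset({"plankton"}),
    "scavenger": frozenset({"animal", "insect", "fish"}),
    "unknown": frozenset({"producer", "animal", "insect", "fish", "plankton"}),
}

#: Diet categories that may take the producer -> consumer probabilistic link.
GRAZER_DIETS = frozenset({"herbivore", "omnivore", "detritivore", "unknown"})

_FISH_CLASSES = frozenset(
    {"Actinopterygii", "Chondrichthyes", "Sarcopterygii", "Agnatha", "Osteichthyes"}
)
#: Mass ceiling (g) under which an aquatic animal also counts as plankton.
PLANKTON_MASS_G = 0.1


@dataclass
class BuildParams:
    """Knobs of one network build."""

    C: float = 0.12
    niche_mode: str = "classic"
    K: int = 100
    relaxation: bool = True
    allow_cannibalism: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.C < 0.5:
            raise ValueError(f"C must be in (0, 0.5), got {self.C}")
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        if self.niche_mode not in NICHE_MODES:
            raise ValueError(f"niche_mode must be one of {NICHE_MODES}")


@dataclass
class NicheParams:
    """Per-species niche axis coordinates (aligned with the table order)."""

    n: np.ndarray
    c: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        for name, arr in (("n", self.n), ("c", self.c), ("r", self.r)):
            if np.any(arr < -1e-12):
                raise ValueError(f"niche parameter {name} must be non-negative")


@dataclass
class TrophicNetwork:
    """Binary consumer x resource matrix: ``matrix[j, k] = 1`` iff species
    ``j`` consumes species ``k``."""

    index: list[str]
    matrix: np.ndarray
    params_used: BuildParams | None = None
    niche: NicheParams | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        n = len(self.index)
        if self.matrix.shape != (n, n):
            raise ValueError(f"matrix shape {self.matrix.shape} does not match {n} taxa")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("matrix must be binary")

    @property
    def n_species(self) -> int:
        return len(self.index)

    @property
    def n_links(self) -> int:
        return int(self.matrix.sum())

    @property
    def connectance(self) -> float:
        return self.n_links / self.n_species**2

    def edges(self) -> list[tuple[str, str]]:
        rows, cols = np.nonzero(self.matrix)
        return [(self.index[i], self.index[j]) for i, j in zip(rows, cols)]


@dataclass
class NetworkEnsemble:
    """Replicate networks of one site, sharing a species index."""

    site_id: str
    networks: list[TrophicNetwork] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.networks:
            raise ValueError("an ensemble needs at least one replicate")
        ref = self.networks[0].index
        for net in self.networks[1:]:
            if net.index != ref:
                raise ValueError("all replicates must share one species index")

    def __len__(self) -> int:
        return len(self.networks)

    def __iter__(self):
        return iter(self.networks)

    @property
    def index(self) -> list[str]:
        return self.networks[0].index


# --- niche axis ------------------------------------------------------------


def trophic_positions(table: SpeciesTable) -> np.ndarray:
    """Niche positions from relative log body mass.

    Consumers are min-max scaled on log10 mass over the consumer masses;
    producers sit at 0.  With a single consumer (or all consumer masses
    equal) the consumers sit at 0.5.
    """
    n = np.zeros(table.n_species)
    logm = {}
    for i, rec in enumerate(table.records):
        if rec.is_producer:
            continue
        if rec.body_mass is None:
            raise ValueError(f"consumer {rec.taxon_id!r} has no body mass; enrich the table first")
        logm[i] = math.log10(rec.body_mass)
    if not logm:
        return n
    lo, hi = min(logm.values()), max(logm.values())
    for i, value in logm.items():
        n[i] = 0.5 if hi == lo else (value - lo) / (hi - lo)
    return n


def sample_niche(
    n_i: float, C: float, mode: str, rng: np.random.Generator
) -> tuple[float, float]:
    """Draw (feeding optimum c, feeding range r) for one consumer.

    In both modes ``c ~ U[r/2, n]`` so the feeding interval never extends
    below the producer end of the axis.  ``n = 0`` forces ``(0, 0)``.
    """
    if not 0 < C < 0.5:
        raise ValueError(f"C must be in (0, 0.5), got {C}")
    if mode not in NICHE_MODES:
        raise ValueError(f"unknown niche mode {mode!r}")
    if n_i == 0:
        return 0.0, 0.0
    if mode == "classic":
        beta = 1.0 / (2.0 * C) - 1.0
        r = n_i * rng.beta(1.0, beta)
    else:
        # Beta(1, 2C) truncated to r <= 2 n_i via inverse-CDF sampling
        beta = 2.0 * C
        cap = min(2.0 * n_i, 1.0)
        u = rng.uniform(0.0, 1.0 - (1.0 - cap) ** beta)
        r = 1.0 - (1.0 - u) ** (1.0 / beta)
    c = rng.uniform(r / 2.0, n_i)
    return c, r


def allometric_criterion(n_j: float, c_i: float, r_i: float) -> bool:
    """Resource position inside the closed feeding interval."""
    return c_i - r_i / 2.0 <= n_j <= c_i + r_i / 2.0


# --- diet rules ------------------------------------------------------------


def resource_class(record: SpeciesRecord) -> frozenset[str]:
    """Coarse resource classes a taxon belongs to, from taxonomy plus the
    producer flag.  Small aquatic animals double as plankton."""
    if record.is_producer:
        return frozenset({"producer"})
    classes = {"animal"}
    klass = record.rank_name("class")
    if klass == "Insecta":
        classes.add("insect")
    if klass in _FISH_CLASSES:
        classes.add("fish")
    if (
        "aquatic" in record.habitat
        and record.body_mass is not None
        and record.body_mass <= PLANKTON_MASS_G
    ):
        classes.add("plankton")
    return frozenset(classes)


def diet_criterion(
    consumer: SpeciesRecord,
    resource: SpeciesRecord,
    rules: dict[str, frozenset[str]] | None = None,
) -> bool:
    """True iff any of the consumer's diet categories is compatible with
    the resource's class.  An empty diet is treated as ``unknown``
    (agnostic, compatible with anything)."""
    rules = rules if rules is not None else DEFAULT_DIET_RULES
    targets = resource_class(resource)
    diets = consumer.diet or {"unknown"}
    return any(rules.get(d, frozenset()) & targets for d in diets)


def producer_link(
    producer: SpeciesRecord,
    consumer: SpeciesRecord,
    C: float,
    rng: np.random.Generator,
) -> bool:
    """Producer eaten with probability C by any grazer irrespective of size."""
    if not producer.is_producer:
        raise ValueError(f"{producer.taxon_id} is not a producer")
    if not consumer.diet & GRAZER_DIETS and consumer.diet:
        return False
    return bool(rng.uniform() < C)


# --- network construction --------------------------------------------------


def _check_enriched(table: SpeciesTable) -> None:
    deficient = [
        r.taxon_id for r in table.records if not r.is_producer and r.body_mass is None
    ]
    if deficient:
        raise ValueError(f"consumers without body mass: {deficient}")


def build_network(
    table: SpeciesTable,
    params: BuildParams | None = None,
    rng: np.random.Generator | None = None,
    rules: dict[str, frozenset[str]] | None = None,
    niche: NicheParams | None = None,
    producer_draws: np.ndarray | None = None,
) -> TrophicNetwork:
    """Build one trophic network from an enriched species table.

    For every consumer-resource pair the link is set iff the allometric
    *and* the diet criterion hold; producer resources instead take the
    probabilistic grazing link.  With relaxation on, spare nodes are then
    connected (see :func:`relax_spare_nodes`).

    ``niche`` (precomputed niche parameters) and ``producer_draws`` (an
    N x N matrix of uniforms deciding the grazing coin flips) bypass the
    corresponding random draws, which makes the rule-application stage
    fully deterministic and independently checkable.
    """
    params = params or BuildParams()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    _check_enriched(table)
    records = table.records
    N = len(records)
    if niche is None:
        n = trophic_positions(table)
        c = np.zeros(N)
        r = np.zeros(N)
        for i, rec in enumerate(records):
            if not rec.is_producer:
                c[i], r[i] = sample_niche(n[i], params.C, params.niche_mode, rng)
        niche = NicheParams(n=n, c=c, r=r)
    n, c, r = niche.n, niche.c, niche.r

    T = np.zeros((N, N), dtype=np.int8)
    for i, consumer in enumerate(records):
        if consumer.is_producer:
            continue
        for j, resource in enumerate(records):
            if i == j and not params.allow_cannibalism:
                continue
            if resource.is_producer:
                if producer_draws is not None:
                    grazes = (
                        not consumer.diet or consumer.diet & GRAZER_DIETS
                    ) and producer_draws[i, j] < params.C
                else:
                    grazes = producer_link(resource, consumer, params.C, rng)
                if grazes:
                    T[i, j] = 1
            elif allometric_criterion(n[j], c[i], r[i]) and diet_criterion(
                consumer, resource, rules
            ):
                T[i, j] = 1
    net = TrophicNetwork(index=table.taxon_ids, matrix=T, params_used=params, niche=niche)
    if not any(not rec.is_producer for rec in records):
        warnings.warn(f"site {table.site_id}: producers only, zero-link network")
        return net
    if params.relaxation and N >= 2:
        net = relax_spare_nodes(net, table, niche, params, rng)
    return net


def relax_spare_nodes(
    net: TrophicNetwork,
    table: SpeciesTable,
    niche: NicheParams,
    params: BuildParams,
    rng: np.random.Generator,
) -> TrophicNetwork:
    """Staged relaxation forcing a network without spare nodes.

    (1) A starving consumer drops the diet filter and links to the resource
    inside its feeding interval whose position is closest to its optimum;
    (2) if its interval is empty, it links to the resource nearest its
    optimum overall; (3) an uneaten producer is linked from a uniformly
    drawn grazer, or any consumer when no grazer is listed.  Self links
    never satisfy the feeding requirement.
    """
    if table.n_species < 2:
        raise ValueError("cannot relax a single-species table")
    T = net.matrix.copy()
    records = table.records
    order = sorted(range(len(records)), key=lambda i: records[i].taxon_id)

    for i in order:
        rec = records[i]
        if rec.is_producer:
            continue
        off_diag = T[i].sum() - T[i, i]
        if off_diag > 0:
            continue
        in_range = [
            j
            for j in range(len(records))
            if j != i and allometric_criterion(niche.n[j], niche.c[i], niche.r[i])
        ]
        candidates = in_range or [j for j in range(len(records)) if j != i]
        best = min(
            candidates,
            key=lambda j: (abs(niche.n[j] - niche.c[i]), records[j].taxon_id),
        )
        T[i, best] = 1

    grazers = [
        i
        for i, rec in enumerate(records)
        if not rec.is_producer and (not rec.diet or rec.diet & GRAZER_DIETS)
    ]
    consumers = [i for i, rec in enumerate(records) if not rec.is_producer]
    for j in order:
        if not records[j].is_producer:
            continue
        if T[:, j].sum() > 0:
            continue
        pool = grazers or consumers
        if not pool:
            continue
        eater = pool[rng.integers(len(pool))]
        T[eater, j] = 1
    return TrophicNetwork(
        index=net.index, matrix=T, params_used=params, niche=niche
    )


def replicate_count(N: int, K: int = 100) -> int:
    """Number of replicates, inversely proportional to log10(N) with a
    floor of 3 so consistency across replicates is always defined."""
    if N < 2:
        raise ValueError(f"need N >= 2, got {N}")
    return max(3, int(round(K / math.log10(N))))


def build_ensemble(
    table: SpeciesTable,
    params: BuildParams | None = None,
    rng: np.random.Generator | None = None,
    rules: dict[str, frozenset[str]] | None = None,
    n_replicates: int | None = None,
) -> NetworkEnsemble:
    """Replicate networks with fresh niche draws, one shared species index."""
    params = params or BuildParams()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    count = n_replicates or replicate_count(table.n_species, params.K)
    nets = [build_network(table, params, rng, rules) for _ in range(count)]
    return NetworkEnsemble(site_id=table.site_id, networks=nets)


def pure_anm_network(
    N: int, C: float, rng: np.random.Generator, niche_mode: str = "classic"
) -> TrophicNetwork:
    """Baseline allometric niche model without functional constraints.

    Positions are uniform on [0, 1]; every species is a consumer and links
    follow the allometric criterion alone (cannibalistic self-links are
    kept, as in the classic niche model, so the realized connectance is
    centred on C)."""
    if N < 2:
        raise ValueError(f"need N >= 2, got {N}")
    n = rng.uniform(0.0, 1.0, N)
    c = np.zeros(N)
    r = np.zeros(N)
    for i in range(N):
        c[i], r[i] = sample_niche(n[i], C, niche_mode, rng)
    lo = c - r / 2.0
    hi = c + r / 2.0
    T = ((n[None, :] >= lo[:, None]) & (n[None, :] <= hi[:, None])).astype(np.int8)
    params = BuildParams(C=C, niche_mode=niche_mode, relaxation=False, allow_cannibalism=True)
    return TrophicNetwork(
        index=[f"node_{i:04d}" for i in range(N)],
        matrix=T,
        params_used=params,
        niche=NicheParams(n=n, c=c, r=r),
    )


def pure_anm_ensemble(
    N: int, C: float, n_replicates: int, rng: np.random.Generator
) -> NetworkEnsemble:
    nets = [pure_anm_network(N, C, rng) for _ in range(n_replicates)]
    return NetworkEnsemble(site_id=f"pure_anm_N{N}", networks=nets)
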