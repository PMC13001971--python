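"""Topological and taxonomic descriptors of trophic networks.

All topological quantities are measured on the binary trophic matrix T
(``T[j, k] = 1`` iff species j consumes species k).  Row sums are prey
counts (in-degree, generality side); column sums are consumer counts
(out-degree, vulnerability side).

Notable conventions:

* ``MAXDEG`` and ``MAXCHAIN`` split the historically overloaded "maximum
  links" name into maximum node degree and maximum Cohen-chain length.
* ``IND``/``OUT`` average over species with non-zero respective degree
  (otherwise both would collapse onto ``AVL``).
* ``LOOP1 = sum|T - T^T| / (2 N^2)``, a link-asymmetry measure, is kept
  under its traditional name; the count of mutual (2-cycle) pairs is
  exposed separately as ``mutual_pairs``.
* Chain and loop enumeration is capped (chains default 10**6, length 30)
  because the number of chains grows non-linearly with N; truncation is
  flagged, never silent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .anm_core import NetworkEnsemble, TrophicNetwork
from .species_table import SpeciesTable

SCALAR_DESCRIPTORS = (
    "N", "G", "F", "O", "CL", "P", "ABS", "ABM", "beta",
    "AVL", "CON", "IND", "OUT", "ASYM", "MAXDEG", "MAXIND", "MAXOUT",
    "TOP", "BAS", "INT", "PC",
    "AVGL", "MINL", "MAXCHAIN", "NCHA", "NLOOPS", "LOOP1",
    "MOD", "PART", "CLUST", "NEST",
)
VECTOR_DESCRIPTORS = ("DEG", "GEN", "VUL")


@dataclass
class DescriptorSet:
    """One network's descriptor values; unavailable entries stay None."""

    scalars: dict[str, float | None] = field(default_factory=dict)
    vectors: dict[str, np.ndarray] = field(default_factory=dict)
    model_errors: dict[str, float] = field(default_factory=dict)
    truncated: bool = False

    def __getitem__(self, key: str):
        if key in self.scalars:
            return self.scalars[key]
        if key in self.vectors:
            return self.vectors[key]
        raise KeyError(key)


# --- degrees ---------------------------------------------------------------


def _freq(counts: np.ndarray) -> np.ndarray:
    """Relative-frequency vector indexed by degree value."""
    if counts.size == 0:
        return np.zeros(1)
    out = np.bincount(counts.astype(int)) / counts.size
    return out


def degree_distributions(net: TrophicNetwork) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(DEG, GEN, VUL) relative-frequency distributions over nodes."""
    T = net.matrix
    prey = T.sum(axis=1)
    consumers = T.sum(axis=0)
    return _freq(prey + consumers), _freq(prey), _freq(consumers)


def connectivity_stats(net: TrophicNetwork) -> dict[str, float]:
    T = net.matrix
    N = net.n_species
    L = int(T.sum())
    indeg = T.sum(axis=1)   # prey per consumer
    outdeg = T.sum(axis=0)  # consumers per resource
    denom = (indeg + outdeg).sum()
    return {
        "AVL": L / N,
        "CON": L / N**2,
        "IND": float(indeg[indeg > 0].mean()) if (indeg > 0).any() else 0.0,
        "OUT": float(outdeg[outdeg > 0].mean()) if (outdeg > 0).any() else 0.0,
        "ASYM": float(np.abs(indeg - outdeg).sum() / denom) if denom else 0.0,
        "MAXDEG": int((indeg + outdeg).max()) if N else 0,
        "MAXIND": int(indeg.max()) if N else 0,
        "MAXOUT": int(outdeg.max()) if N else 0,
    }


# --- trophic roles ---------------------------------------------------------


def _basal_mask(net: TrophicNetwork, table: SpeciesTable | None) -> np.ndarray:
    """Basal species: primary producers and strict detritivores when trait
    data is available, else species without prey."""
    if table is not None:
        return np.array(
            [
                rec.is_producer or (rec.diet != set() and rec.diet <= {"detritivore"})
                for rec in table.records
            ]
        )
    off = net.matrix.copy()
    np.fill_diagonal(off, 0)
    return off.sum(axis=1) == 0


def trophic_fractions(
    net: TrophicNetwork, table: SpeciesTable | None = None
) -> dict[str, float]:
    """TOP / BAS / INT fractions and the producer-consumer ratio
    PC = BAS / (1 - BAS)."""
    N = net.n_species
    basal = _basal_mask(net, table)
    off = net.matrix.copy()
    np.fill_diagonal(off, 0)
    eaten = off.sum(axis=0) > 0
    top = (~basal) & (~eaten)
    BAS = basal.mean()
    TOP = top.mean()
    if BAS == 1.0:
        warnings.warn("all species basal; PC reported as +inf")
        PC = math.inf
    else:
        PC = BAS / (1.0 - BAS)
    return {"TOP": float(TOP), "BAS": float(BAS), "INT": float(1.0 - TOP - BAS), "PC": float(PC)}


# --- chains and loops ------------------------------------------------------


def cohen_chains(
    net: TrophicNetwork,
    table: SpeciesTable | None = None,
    max_chains: int = 10**6,
    max_len: int = 30,
    max_steps: int | None = None,
) -> dict[str, float]:
    """Enumerate maximal simple resource -> consumer paths from basal to top
    nodes.  Prefixes of a longer chain are not counted as separate chains;
    length is the node count.  Enumeration is depth-first with caps (chain
    count, chain length, and total visited partial paths), and a hit cap
    sets ``truncated``."""
    N = net.n_species
    off = net.matrix.copy()
    np.fill_diagonal(off, 0)
    basal = _basal_mask(net, table)
    eaten_by = [np.nonzero(off[:, k])[0] for k in range(N)]  # consumers of k
    if max_steps is None:
        max_steps = 20 * max_chains

    lengths: list[int] = []
    truncated = False
    steps = 0

    def dfs(node: int, path_len: int, on_path: np.ndarray) -> bool:
        nonlocal truncated, steps
        steps += 1
        if steps > max_steps or path_len > max_len:
            truncated = True
            return True
        succ = eaten_by[node]
        if len(succ) == 0:
            # a chain ends only at a top node; an isolated basal node or a
            # path stuck inside a cycle contributes nothing
            if not basal[node]:
                lengths.append(path_len)
                if len(lengths) >= max_chains:
                    truncated = True
                    return True
            return False
        for nxt in succ:
            if on_path[nxt]:
                continue
            on_path[nxt] = True
            stop = dfs(nxt, path_len + 1, on_path)
            on_path[nxt] = False
            if stop:
                return True
        return False

    for b in np.nonzero(basal)[0]:
        on_path = np.zeros(N, dtype=bool)
        on_path[b] = True
        if dfs(b, 1, on_path):
            break

    if not lengths:
        return {"NCHA": 0, "AVGL": 0.0, "MINL": 0, "MAXCHAIN": 0, "truncated": truncated}
    return {
        "NCHA": len(lengths),
        "AVGL": float(np.mean(lengths)),
        "MINL": int(min(lengths)),
        "MAXCHAIN": int(max(lengths)),
        "truncated": truncated,
    }


def loops(
    net: TrophicNetwork, max_loops: int = 10**5, max_len: int = 30
) -> dict[str, float]:
    """NLOOPS: simple directed cycles of length >= 2 (bounded enumeration).
    LOOP1: the printed link-asymmetry formula sum|T - T^T| / (2 N^2)."""
    T = net.matrix
    N = net.n_species
    G = nx.from_numpy_array(T, create_using=nx.DiGraph)
    count = 0
    truncated = False
    for cycle in nx.simple_cycles(G, length_bound=max_len):
        if len(cycle) >= 2:
            count += 1
            if count >= max_loops:
                truncated = True
                break
    loop1 = float(np.abs(T - T.T).sum()) / (2.0 * N**2)
    mutual = int((T * T.T).sum() - np.diag(T).sum()) // 2
    return {"NLOOPS": count, "LOOP1": loop1, "mutual_pairs": mutual, "truncated": truncated}


# --- nestedness ------------------------------------------------------------


def nestedness(net: TrophicNetwork) -> float:
    """Fraction of links misplaced relative to a perfectly nested reference.

    Rows and columns are reordered by decreasing degree (stable for ties);
    the reference packs each row's links into its leftmost cells of the
    reordered matrix, which is a maximally nested stepped region with the
    same size and link count.  NEST = misplaced links / L, in [0, 1];
    an empty network scores 0 by convention."""
    T = net.matrix
    L = int(T.sum())
    if L == 0:
        return 0.0
    row_order = np.argsort(-T.sum(axis=1), kind="stable")
    col_order = np.argsort(-T.sum(axis=0), kind="stable")
    M = T[np.ix_(row_order, col_order)]
    misplaced = 0
    for row in M:
        d = int(row.sum())
        misplaced += d - int(row[:d].sum())
    return misplaced / L


# --- ensemble-level --------------------------------------------------------


def model_error(
    x_obs, baseline: NetworkEnsemble, descriptor: str, table: SpeciesTable | None = None
) -> float:
    """Absolute deviation of a descriptor from its baseline expectation.

    Scalars: ``|x_obs - mean(baseline)|``.  Vectors (DEG/GEN/VUL): mean
    absolute difference between the observed relative-frequency vector and
    the baseline mean vector, zero-padded to common support."""
    if len(baseline) < 20:
        raise ValueError(f"baseline needs >= 20 replicates, got {len(baseline)}")
    if descriptor in VECTOR_DESCRIPTORS:
        x_obs = np.asarray(x_obs, dtype=float)
        idx = VECTOR_DESCRIPTORS.index(descriptor)
        vecs = [degree_distributions(net)[idx] for net in baseline]
        width = max(max(len(v) for v in vecs), len(x_obs))
        mean = np.zeros(width)
        for v in vecs:
            mean[: len(v)] += v / len(vecs)
        obs = np.zeros(width)
        obs[: len(x_obs)] = x_obs
        return float(np.abs(obs - mean).mean())
    values = [_scalar_value(net, descriptor) for net in baseline]
    return float(abs(float(x_obs) - np.mean(values)))


def _scalar_value(net: TrophicNetwork, descriptor: str) -> float:
    """One scalar descriptor, computing only the family it belongs to."""
    if descriptor == "N":
        return net.n_species
    if descriptor in ("AVL", "CON", "IND", "OUT", "ASYM", "MAXDEG", "MAXIND", "MAXOUT"):
        return connectivity_stats(net)[descriptor]
    if descriptor in ("TOP", "BAS", "INT", "PC"):
        return trophic_fractions(net)[descriptor]
    if descriptor in ("NCHA", "AVGL", "MINL", "MAXCHAIN"):
        return cohen_chains(net)[descriptor]
    if descriptor in ("NLOOPS", "LOOP1"):
        return loops(net)[descriptor]
    if descriptor == "NEST":
        return nestedness(net)
    raise ValueError(f"unsupported scalar descriptor {descriptor!r} for model error")


@dataclass
class TCProfile:
    """Per-link topological consistency: the fraction of replicates each
    observed link appears in, plus the histogram of those fractions."""

    link_tc: dict[tuple[str, str], float]
    histogram: dict[float, float]


def topological_consistency(ens: NetworkEnsemble) -> TCProfile:
    if len(ens) < 2:
        raise ValueError("topological consistency needs >= 2 replicates")
    counts: dict[tuple[str, str], int] = {}
    for net in ens:
        for edge in net.edges():
            counts[edge] = counts.get(edge, 0) + 1
    R = len(ens)
    link_tc = {edge: c / R for edge, c in counts.items()}
    hist: dict[float, float] = {}
    for tc in link_tc.values():
        hist[tc] = hist.get(tc, 0) + 1
    total = sum(hist.values())
    return TCProfile(link_tc=link_tc, histogram={k: v / total for k, v in hist.items()})


def beta_diversity(site: SpeciesTable | set, others: set, rank: str | None = None) -> float:
    """Jaccard-style compositional uniqueness, beta = 2 * shared / (N_i + N_T).

    0 means every taxon of the site is unique; computable at any taxonomic
    rank by passing ``rank`` (site names are then the distinct rank names)."""
    if isinstance(site, SpeciesTable):
        if rank is None:
            names = {rec.name for rec in site.records}
        else:
            names = {rec.rank_name(rank) for rec in site.records if rec.rank_name(rank)}
    else:
        names = set(site)
    if not names or not others:
        raise ValueError("both species sets must be non-empty")
    shared = len(names & others)
    return 2.0 * shared / (len(names) + len(others))


def taxonomic_richness(table: SpeciesTable) -> dict[str, float | None]:
    """Distinct-name counts per rank plus mean consumer body size/mass."""
    out: dict[str, float | None] = {"N": table.n_species}
    for key, rank in (("G", "genus"), ("F", "family"), ("O", "order"), ("CL", "class"), ("P", "phylum")):
        names = {rec.rank_name(rank) for rec in table.records if rec.rank_name(rank)}
        out[key] = len(names) if names else None
    sizes = [r.body_size for r in table.consumers if r.body_size is not None]
    masses = [r.body_mass for r in table.consumers if r.body_mass is not None]
    out["ABS"] = float(np.mean(sizes)) if sizes else None
    out["ABM"] = float(np.mean(masses)) if masses else None
    return out


# --- heavy-tail diagnostics ------------------------------------------------


def fit_powerlaw_exponent(degrees: np.ndarray, kmin: int = 1) -> float:
    """Discrete maximum-likelihood power-law exponent for degrees >= kmin.

    Maximizes the zeta likelihood P(k) = k^-alpha / zeta(alpha, kmin)
    numerically (exact discrete MLE, no continuous approximation)."""
    from scipy.optimize import minimize_scalar
    from scipy.special import zeta

    k = np.asarray(degrees, dtype=float)
    k = k[k >= kmin]
    if k.size < 2:
        return math.nan
    log_sum = np.log(k).sum()

    def nll(alpha: float) -> float:
        return k.size * math.log(zeta(alpha, kmin)) + alpha * log_sum

    res = minimize_scalar(nll, bounds=(1.01, 10.0), method="bounded")
    return float(res.x)


def survival_function(degrees: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical P(K >= k) over the positive degrees."""
    k = np.sort(np.asarray(degrees)[np.asarray(degrees) > 0])
    uniq = np.unique(k)
    sf = np.array([(k >= u).mean() for u in uniq])
    return uniq, sf


# --- one-call summary ------------------------------------------------------


def compute_descriptors(
    net: TrophicNetwork,
    table: SpeciesTable | None = None,
    pooled_species: set | None = None,
    baseline: NetworkEnsemble | None = None,
    louvain_seed: int = 0,
    max_chains: int = 10**6,
    max_chain_len: int = 30,
    max_loops: int = 10**5,
) -> DescriptorSet:
    """Compute the full descriptor set for one network.

    Taxonomic entries need ``table``; beta diversity needs
    ``pooled_species``; model errors need a pure-ANM ``baseline`` ensemble.
    """
    from .community_structure import clustering_coefficient, louvain_partition

    scalars: dict[str, float | None] = {k: None for k in SCALAR_DESCRIPTORS}
    scalars["N"] = net.n_species
    scalars.update(connectivity_stats(net))
    scalars.update(trophic_fractions(net, table))
    chains = cohen_chains(net, table, max_chains=max_chains, max_len=max_chain_len)
    loop_stats = loops(net, max_loops=max_loops)
    truncated = bool(chains.pop("truncated") or loop_stats.pop("truncated"))
    loop_stats.pop("mutual_pairs")
    scalars.update(chains)
    scalars.update(loop_stats)
    scalars["NEST"] = nestedness(net)
    part = louvain_partition(net, seed=louvain_seed)
    scalars["MOD"] = part.modularity
    scalars["PART"] = part.n_modules
    scalars["CLUST"] = clustering_coefficient(net)
    if table is not None:
        scalars.update(taxonomic_richness(table))
        if pooled_species is not None:
            scalars["beta"] = beta_diversity(table, pooled_species)
    deg, gen, vul = degree_distributions(net)
    vectors = {"DEG": deg, "GEN": gen, "VUL": vul}
    errors = {}
    if baseline is not None:
        for name in ("CON", "AVL", "MAXDEG"):
            errors[f"ME_{name}"] = model_error(scalars[name], baseline, name)
        for name in VECTOR_DESCRIPTORS:
            errors[f"ME_{name}"] = model_error(vectors[name], baseline, name)
    return DescriptorSet(scalars=scalars, vectors=vectors, model_errors=errors, truncated=truncated)


def descriptor_matrix(
    ensembles: dict[str, NetworkEnsemble],
    tables: dict[str, SpeciesTable] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """One row per (site, replicate): the morphospace export."""
    rows = []
    for site, ens in ensembles.items():
        table = tables.get(site) if tables else None
        for rep, net in enumerate(ens):
            ds = compute_descriptors(net, table, **kwargs)
            row = {"site_id": site, "replicate": rep, **ds.scalars}
            rows.append(row)
    return pd.DataFrame(rows)
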