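"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from first principles (explicit path
enumeration, pair-by-pair rule evaluation) rather than calling the library
code paths they check.
"""

import itertools

import numpy as np

_FISH = {"Actinopterygii", "Chondrichthyes", "Sarcopterygii", "Agnatha", "Osteichthyes"}
_GRAZERS = {"herbivore", "omnivore", "detritivore", "unknown"}
_COMPAT = {
    "herbivore": {"producer"},
    "carnivore": {"animal", "insect", "fish"},
    "insectivore": {"insect"},
    "piscivore": {"fish"},
    "omnivore": {"producer", "animal", "insect", "fish", "plankton"},
    "detritivore": {"producer"},
    "planktivore": {"plankton"},
    "scavenger": {"animal", "insect", "fish"},
    "unknown": {"producer", "animal", "insect", "fish", "plankton"},
}


def brute_force_chains(matrix, basal):
    """All simple resource->consumer paths from basal to top nodes, found by
    exhaustive enumeration of node sequences."""
    matrix = np.asarray(matrix)
    N = matrix.shape[0]
    off = matrix.copy()
    np.fill_diagonal(off, 0)
    consumers_of = {k: set(np.nonzero(off[:, k])[0]) for k in range(N)}
    top = {k for k in range(N) if not consumers_of[k] and not basal[k]}
    lengths = []
    for length in range(1, N + 1):
        for path in itertools.permutations(range(N), length):
            if not basal[path[0]] or path[-1] not in top:
                continue
            if all(path[t + 1] in consumers_of[path[t]] for t in range(length - 1)):
                lengths.append(length)
    return lengths


def brute_force_cycles(matrix):
    """Count simple directed cycles of length >= 2 (canonical rotations)."""
    matrix = np.asarray(matrix)
    N = matrix.shape[0]
    count = 0
    for length in range(2, N + 1):
        for path in itertools.permutations(range(N), length):
            if path[0] != min(path):
                continue
            if all(matrix[path[t + 1], path[t]] for t in range(length - 1)) and matrix[
                path[0], path[-1]
            ]:
                count += 1
    return count


def _resource_classes(rec):
    if rec.is_producer:
        return {"producer"}
    classes = {"animal"}
    klass = rec.taxonomy.get("class")
    if klass == "Insecta":
        classes.add("insect")
    if klass in _FISH:
        classes.add("fish")
    if "aquatic" in rec.habitat and rec.body_mass is not None and rec.body_mass <= 0.1:
        classes.add("plankton")
    return classes


def brute_force_anm(records, niche, producer_draws, C):
    """Pair-by-pair evaluation of the three linking rules (allometric
    interval, diet compatibility, probabilistic grazing) on frozen draws."""
    N = len(records)
    M = np.zeros((N, N), dtype=int)
    for i, cons in enumerate(records):
        if cons.is_producer:
            continue
        diets = cons.diet or {"unknown"}
        for j, res in enumerate(records):
            if i == j:
                continue
            if res.is_producer:
                grazes = bool(diets & _GRAZERS)
                M[i, j] = int(grazes and producer_draws[i, j] < C)
            else:
                lo = niche.c[i] - niche.r[i] / 2
                hi = niche.c[i] + niche.r[i] / 2
                inside = lo <= niche.n[j] <= hi
                compatible = any(_COMPAT[d] & _resource_classes(res) for d in diets)
                M[i, j] = int(inside and compatible)
    return M
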