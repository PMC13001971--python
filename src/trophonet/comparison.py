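"""Link-by-link validation against reference food webs.

A predicted interaction counts as a match only when both interacting
species and the direction agree with the reference edge list.  Because an
ensemble samples a different subset of plausible links per replicate, both
a union recall (reference links recovered by at least one replicate) and a
mean per-replicate recall are reported, together with an over-estimation
rate and a full-confusion accuracy; the connectivity-matched random
network provides the chance baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .anm_core import NetworkEnsemble, TrophicNetwork


@dataclass
class ComparisonResult:
    recall_union: float
    recall_mean: float
    underestimated: float
    overestimated: float
    accuracy_mean: float

    def __post_init__(self) -> None:
        assert abs(self.recall_union + self.underestimated - 1.0) < 1e-9


def _aligned_matrices(ens: NetworkEnsemble, ref: TrophicNetwork):
    """Outer-join the species indexes; taxa on one side only become
    isolated nodes (with a warning)."""
    if ens.index == ref.index:
        return [net.matrix for net in ens], ref.matrix, len(ref.index)
    union = sorted(set(ens.index) | set(ref.index))
    missing = set(ens.index) ^ set(ref.index)
    warnings.warn(f"species indexes differ; outer join over {len(union)} taxa ({len(missing)} unmatched)")
    pos = {t: i for i, t in enumerate(union)}
    n = len(union)

    def embed(matrix, index):
        out = np.zeros((n, n), dtype=np.int8)
        ix = [pos[t] for t in index]
        out[np.ix_(ix, ix)] = matrix
        return out

    return [embed(net.matrix, ens.index) for net in ens], embed(ref.matrix, ref.index), n


def compare_to_reference(ens: NetworkEnsemble, ref: TrophicNetwork) -> ComparisonResult:
    """Directed exact matching of predicted vs reference links."""
    if ref.n_links == 0:
        raise ValueError("reference network has no links")
    mats, R, n = _aligned_matrices(ens, ref)
    ref_links = R.astype(bool)
    L_ref = int(ref_links.sum())

    union = np.zeros_like(ref_links)
    recalls, overs, accs = [], [], []
    for M in mats:
        pred = M.astype(bool)
        union |= pred
        hits = int((pred & ref_links).sum())
        recalls.append(hits / L_ref)
        L_pred = int(pred.sum())
        overs.append(((pred & ~ref_links).sum() / L_pred) if L_pred else 0.0)
        accs.append(float((pred == ref_links).mean()))
    recall_union = float((union & ref_links).sum() / L_ref)
    return ComparisonResult(
        recall_union=recall_union,
        recall_mean=float(np.mean(recalls)),
        underestimated=1.0 - recall_union,
        overestimated=float(np.mean(overs)),
        accuracy_mean=float(np.mean(accs)),
    )


def random_network(N: int, C: float, rng: np.random.Generator) -> TrophicNetwork:
    """Erdos-Renyi style baseline: each off-diagonal cell is a link with
    probability C; no self-links."""
    if N < 2:
        raise ValueError(f"need N >= 2, got {N}")
    if not 0 <= C <= 1:
        raise ValueError(f"C must be in [0, 1], got {C}")
    T = (rng.uniform(size=(N, N)) < C).astype(np.int8)
    np.fill_diagonal(T, 0)
    return TrophicNetwork(index=[f"node_{i:04d}" for i in range(N)], matrix=T)
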