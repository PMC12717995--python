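"""ASAP-style species partitioning of a distance matrix.

Hierarchical (single-linkage) agglomeration over the pairwise distances
proposes one candidate partition per distinct merge height, from
all-singletons down to a single cluster.  Each candidate is scored by two
ranks — the probability of panmixia and the relative width of the barcode
gap it exhibits — and the final score is the mean of the two ranks; lower
is better.

The panmixia probability is estimated by a seeded Monte-Carlo coalescent:
for a group formed by a merge, the deepest internal split is tested by
simulating the maximum pairwise distance of an equally sized sample from a
single panmictic population whose diversity θ is estimated from the
subgroups being joined.  A candidate partition's probability is the product
of the probabilities of the merges that would destroy it (the merges at the
next height): a very low product means its groups cannot be merged any
further without violating panmixia, which is the signature of a good
species partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core_io import Config, Partition
from .distmat import DistanceMatrix

__all__ = [
    "AsapCandidate",
    "GapDescriptor",
    "candidate_partitions",
    "gap_descriptor",
    "panmixia_probability",
    "asap_rank",
]

#: guards the relative-width division when the partition has no intra pairs
EPSILON = 1e-6


class GapError(ValueError):
    """Raised when a partition exhibits no barcode gap (single cluster)."""


@dataclass(frozen=True)
class GapDescriptor:
    """Barcode gap of one partition.

    d_low    max intra-group distance
    d_high   min inter-group distance
    location distance where the gap opens (= d_low), as a fraction
    width    relative width (d_high − d_low) / max(d_low, ε)
    """

    d_low: float
    d_high: float
    location: float
    width: float


@dataclass(frozen=True)
class AsapCandidate:
    partition: Partition
    threshold: float
    p_panmixia: float
    gap_width: float
    rank_p: int
    rank_w: int
    asap_score: float


def _partition_at(
    dm: DistanceMatrix, Z: np.ndarray, height: float, label: str
) -> Partition:
    flat = fcluster(Z, t=height, criterion="distance")
    clusters: dict[str, set] = {}
    for sid, c in zip(dm.ids, flat):
        clusters.setdefault(f"C{c}", set()).add(sid)
    return Partition(
        method="ASAP",
        label=label,
        clusters={k: frozenset(v) for k, v in clusters.items()},
        threshold=height,
    )


def _singleton_partition(dm: DistanceMatrix) -> Partition:
    return Partition(
        method="ASAP",
        label="all_singletons",
        clusters={f"C{i+1}": frozenset([sid]) for i, sid in enumerate(dm.ids)},
        threshold=0.0,
    )


def _merge_heights(dm: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    condensed = squareform(dm.d, checks=False)
    Z = linkage(condensed, method="single")
    heights = np.unique(Z[:, 2])
    return Z, heights


def candidate_partitions(dm: DistanceMatrix) -> list[Partition]:
    """Nested chain of single-linkage partitions, finest to coarsest.

    The first candidate is the all-singleton partition; every distinct
    merge height then contributes one candidate, the last being the
    one-cluster partition at the maximum height.
    """
    if len(dm) < 2:
        raise ValueError("need at least 2 sequences")
    Z, heights = _merge_heights(dm)
    out = [_singleton_partition(dm)]
    for h in heights:
        out.append(_partition_at(dm, Z, float(h), f"SL@{h:.6g}"))
    return out


def gap_descriptor(part: Partition, dm: DistanceMatrix) -> GapDescriptor:
    """Barcode gap of a partition: intra ceiling vs inter floor.

    The all-singleton partition has d_low = 0 and an ε-capped sentinel
    width.  A one-cluster partition has no inter pairs and raises.
    """
    if part.n_clusters < 2:
        raise GapError("one-cluster partition has no barcode gap")
    index = {sid: i for i, sid in enumerate(dm.ids)}
    labels = np.empty(len(dm.ids), dtype=int)
    for k, members in enumerate(part.clusters.values()):
        for m in members:
            labels[index[m]] = k
    iu, ju = np.triu_indices(len(dm.ids), k=1)
    same = labels[iu] == labels[ju]
    vals = dm.d[iu, ju]
    d_low = float(vals[same].max()) if same.any() else 0.0
    d_high = float(vals[~same].min())
    width = (d_high - d_low) / max(d_low, EPSILON)
    return GapDescriptor(d_low=d_low, d_high=d_high, location=d_low, width=width)


def _simulate_tmrca(n: int, reps: int, rng: np.random.Generator) -> np.ndarray:
    """Kingman coalescent times to the MRCA for a sample of size n.

    T_MRCA = Σ_{k=2..n} T_k with T_k ~ Exp(rate = k(k−1)/2), in units where
    the expected pairwise coalescence time is 1.
    """
    ks = np.arange(2, n + 1)
    rates = ks * (ks - 1) / 2.0
    waits = rng.exponential(1.0, size=(reps, len(ks))) / rates
    return waits.sum(axis=1)


def panmixia_probability(
    group_ids: list[str],
    dm: DistanceMatrix,
    reps: int = 1000,
    seed: int | np.random.Generator = 0,
    theta_fallback: float = 0.0,
) -> float:
    """Probability that a group's deepest split is consistent with panmixia.

    The group's single-linkage root splits it into two subgroups; θ is the
    mean pairwise distance *within* those subgroups.  When the subgroups
    carry no internal pairs θ cannot be calibrated and the probability is
    defined as 1 (panmixia cannot be rejected without a rate).  The
    observed maximum pairwise distance is compared against the maxima of
    ``reps`` coalescent samples of the same size: under panmixia the
    maximum pairwise distance is θ·T_MRCA.  Singletons and zero-diversity
    groups return 1.0.
    """
    n = len(group_ids)
    if n <= 1:
        return 1.0
    if reps < 100:
        warnings.warn(f"reps={reps} < 100 gives a coarse probability", stacklevel=2)
    sub = dm.submatrix(list(group_ids))
    iu, ju = np.triu_indices(n, k=1)
    pairs = sub.d[iu, ju]
    obs_max = float(pairs.max())
    if obs_max == 0.0:
        return 1.0
    theta = _deepest_split_theta(sub)
    if theta == 0.0:
        # the subgroups being joined carry no internal diversity; fall back
        # to the caller-supplied rate (e.g. dataset-wide within-group mean),
        # else the test has no power and panmixia cannot be rejected
        theta = theta_fallback
    if theta == 0.0:
        return 1.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tmrca = _simulate_tmrca(n, reps, rng)
    return float(np.mean(theta * tmrca >= obs_max))


def _within_cluster_mean(dm: DistanceMatrix, part: Partition) -> float:
    """Mean pairwise distance over all within-cluster pairs of a partition."""
    index = {sid: i for i, sid in enumerate(dm.ids)}
    total, count = 0.0, 0
    for members in part.clusters.values():
        if len(members) < 2:
            continue
        idx = np.array(sorted(index[m] for m in members))
        block = dm.d[np.ix_(idx, idx)]
        iu, ju = np.triu_indices(len(idx), k=1)
        total += float(block[iu, ju].sum())
        count += len(iu)
    return total / count if count else 0.0


def _deepest_split_theta(sub: DistanceMatrix) -> float:
    """Mean pairwise distance within the two children of the root merge."""
    n = len(sub)
    if n == 2:
        return 0.0
    Z = linkage(squareform(sub.d, checks=False), method="single")
    root_height = Z[-1, 2]
    flat = fcluster(Z, t=root_height * (1 - 1e-12), criterion="distance")
    total, count = 0.0, 0
    for c in np.unique(flat):
        idx = np.where(flat == c)[0]
        if len(idx) > 1:
            block = sub.d[np.ix_(idx, idx)]
            iu, ju = np.triu_indices(len(idx), k=1)
            total += float(block[iu, ju].sum())
            count += len(iu)
    return total / count if count else 0.0


def asap_rank(
    dm: DistanceMatrix, cfg: Config | None = None, reps: int | None = None
) -> list[AsapCandidate]:
    """Score and rank the single-linkage candidate partitions.

    For each candidate (the one-cluster root excluded — it has no gap) the
    panmixia probability is the product of the per-merge probabilities of
    the groups formed at the next distinct merge height, floored at machine
    epsilon.  rank_p is the competition rank of that probability ascending
    (an improbable further merge supports the partition); rank_w ranks the
    relative gap width descending.  asap_score = (rank_p + rank_w)/2; ties
    are broken by larger width then fewer clusters.  The best
    ``cfg.asap_top_k`` candidates are returned.
    """
    cfg = cfg or Config()
    reps = reps if reps is not None else cfg.panmixia_reps
    if len(dm) < 3:
        raise ValueError("need at least 3 sequences to rank partitions")
    Z, heights = _merge_heights(dm)
    rng = np.random.default_rng(cfg.rng_seed)

    # per-merge panmixia probability, keyed by the distinct merge height at
    # which the group appears; evaluated on the groups of the partition at
    # that height that were not yet present at the previous height
    parts = [_singleton_partition(dm)] + [
        _partition_at(dm, Z, float(h), f"SL@{h:.6g}") for h in heights
    ]
    merge_p: list[float] = []  # product of per-merge probabilities per height
    for level in range(1, len(parts)):
        prev = parts[level - 1]
        prev_sets = set(prev.clusters.values())
        global_theta = _within_cluster_mean(dm, prev)
        prod = 1.0
        for members in parts[level].clusters.values():
            if members not in prev_sets:
                prod *= panmixia_probability(
                    sorted(members), dm, reps=reps, seed=rng,
                    theta_fallback=global_theta,
                )
        merge_p.append(max(prod, float(np.finfo(float).eps)))

    # candidates: every partition except the one-cluster root
    cands = []
    for level, part in enumerate(parts[:-1]):
        gap = gap_descriptor(part, dm)
        # probability of the merges that destroy this partition
        p_next = merge_p[level]
        cands.append((part, float(part.threshold or 0.0), p_next, gap.width))

    ps = np.array([c[2] for c in cands])
    ws = np.array([c[3] for c in cands])
    rank_p = _competition_rank(ps, ascending=True)
    rank_w = _competition_rank(ws, ascending=False)
    scored = []
    for (part, thr, p, w), rp, rw in zip(cands, rank_p, rank_w):
        score = (int(rp) + int(rw)) / 2.0
        scored.append(
            AsapCandidate(
                partition=Partition(
                    method="ASAP",
                    label=part.label,
                    clusters=part.clusters,
                    threshold=part.threshold,
                    score=score,
                ),
                threshold=thr,
                p_panmixia=p,
                gap_width=w,
                rank_p=int(rp),
                rank_w=int(rw),
                asap_score=score,
            )
        )
    scored.sort(key=lambda c: (c.asap_score, -c.gap_width, c.partition.n_clusters))
    return scored[: cfg.asap_top_k]


def _competition_rank(values: np.ndarray, ascending: bool) -> np.ndarray:
    """1224-style competition ranking; equal values share the lowest rank."""
    v = values if ascending else -values
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v), dtype=int)
    rank = 1
    prev = None
    for pos, idx in enumerate(order):
        if prev is None or v[idx] != prev:
            rank = pos + 1
            prev = v[idx]
        ranks[idx] = rank
    return ranks
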