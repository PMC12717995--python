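"""Large-scale integrative taxonomy: congruence flags, specimen selection,
and morphology-driven reconciliation of molecular clusters.

The reverse workflow delimits molecular clusters first and validates them
morphologically afterwards.  The engine takes a baseline partition (the
candidate with the fewest clusters), flags clusters that are potentially
incongruent (PI) with morphology — unstable across candidate partitions
and/or with a high maximum intraspecific p-distance — selects a minimal
set of specimens per cluster for slide mounting, and reconciles the
molecular clusters with the resulting morphological labels into a final
delimitation with per-cluster status.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import Config, MorphoLabel, Partition, SpecimenRecord
from .distmat import DistanceMatrix, round_percent

__all__ = [
    "PIAssessment",
    "SelectionPlan",
    "Delimitation",
    "choose_baseline",
    "stability_flags",
    "assess_pi",
    "select_specimens",
    "reconcile",
    "report",
]


@dataclass(frozen=True)
class PIAssessment:
    """Stability and distance flags for one baseline cluster (percent units)."""

    cluster_id: str
    stable: bool
    max_intra_p: float
    mean_intra_p: float
    pi: bool
    pi_reason: str  # none | distance_only | unstable_only | both


@dataclass(frozen=True)
class SelectionPlan:
    """Specimens chosen from one cluster for morphological validation."""

    cluster_id: str
    chosen_specimens: tuple[str, ...]
    roles: dict  # specimen_id -> divergent_haplotype | dominant_haplotype | female_supplement
    males_only: bool = False


@dataclass(frozen=True)
class Delimitation:
    """Final clusters with status and species labels.

    status per cluster: congruent | split | lumped | unresolved.  Split
    clusters trace to a finer candidate partition via source_partition;
    lumped clusters merge ≥2 clusters sharing a confirmed label.
    """

    clusters: dict  # cluster_id -> frozenset of specimen_ids
    status: dict  # cluster_id -> status string
    species_label: dict  # cluster_id -> str ("" when unidentified)
    source_partition: dict  # cluster_id -> label of the partition it came from
    baseline_ancestor: dict = field(default_factory=dict)  # cluster_id -> baseline cluster_id

    def __post_init__(self) -> None:
        if set(self.status) != set(self.clusters):
            raise ValueError("status must cover every final cluster")
        seen: set = set()
        for members in self.clusters.values():
            if seen & members:
                raise ValueError("final clusters overlap")
            seen |= members

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def choose_baseline(candidates: list[Partition]) -> Partition:
    """The candidate with the fewest clusters; ties go to the lowest score."""
    if not candidates:
        raise ValueError("no candidate partitions")
    return min(
        candidates,
        key=lambda p: (p.n_clusters, p.score if p.score is not None else np.inf),
    )


def stability_flags(
    baseline: Partition, others: list[Partition]
) -> dict[str, bool]:
    """A cluster is stable iff the identical specimen set is a cluster in
    every other partition."""
    universe = baseline.specimen_ids
    for other in others:
        if other.specimen_ids != universe:
            raise ValueError(
                f"partition {other.label!r} covers a different specimen set"
            )
    other_sets = [set(p.clusters.values()) for p in others]
    return {
        cid: all(members in s for s in other_sets)
        for cid, members in baseline.clusters.items()
    }


def _intra_stats(dm: DistanceMatrix, members: frozenset) -> tuple[float, float]:
    ids = sorted(members)
    if len(ids) < 2:
        return 0.0, 0.0
    sub = dm.submatrix(ids).d
    iu, ju = np.triu_indices(len(ids), k=1)
    vals = sub[iu, ju]
    return round_percent(float(vals.mean())), round_percent(float(vals.max()))


def assess_pi(
    baseline: Partition,
    others: list[Partition],
    dm: DistanceMatrix,
    cfg: Config | None = None,
) -> list[PIAssessment]:
    """Flag potentially incongruent clusters: unstable and/or max intra
    p-distance above cfg.pi_pdist_threshold."""
    cfg = cfg or Config()
    stable = stability_flags(baseline, others)
    threshold_pct = cfg.pi_pdist_threshold * 100.0
    out = []
    for cid in sorted(baseline.clusters, key=_natural_key):
        members = baseline.clusters[cid]
        mean_p, max_p = _intra_stats(dm, members)
        high = max_p > threshold_pct
        unstable = not stable[cid]
        if high and unstable:
            reason = "both"
        elif high:
            reason = "distance_only"
        elif unstable:
            reason = "unstable_only"
        else:
            reason = "none"
        out.append(
            PIAssessment(
                cluster_id=cid,
                stable=stable[cid],
                max_intra_p=max_p,
                mean_intra_p=mean_p,
                pi=high or unstable,
                pi_reason=reason,
            )
        )
    return out


def select_specimens(
    cluster: frozenset,
    dm: DistanceMatrix,
    haplotype_map: dict[str, str],
    pi: bool,
    specimens: list[SpecimenRecord],
    cfg: Config | None = None,
    cluster_id: str = "",
) -> SelectionPlan:
    """Choose specimens for slide mounting.

    1. the haplotype pair with the maximum p-distance (ties: the pair
       containing the lexicographically smallest specimen ids); monomorphic
       or singleton clusters contribute their single haplotype;
    2. PI clusters additionally cover every haplotype carried by more than
       cfg.dominant_haplotype_fraction of the cluster's specimens;
    3. per chosen haplotype, up to two females (males only if the haplotype
       has none);
    4. a males-only chosen haplotype triggers a female supplement from the
       nearest haplotype possessing females, if any exists in the cluster.
    """
    if not cluster:
        raise ValueError("empty cluster")
    cfg = cfg or Config()
    by_spec = {s.specimen_id: s for s in specimens}
    # haplotype -> sorted member specimens
    haps: dict[str, list[str]] = {}
    for sid in sorted(cluster):
        haps.setdefault(haplotype_map[sid], []).append(sid)
    hap_ids = sorted(haps)

    chosen_haps: dict[str, str] = {}  # haplotype -> role
    if len(hap_ids) == 1:
        chosen_haps[hap_ids[0]] = "divergent_haplotype"
    else:
        best = None
        for i, ha in enumerate(hap_ids):
            for hb in hap_ids[i + 1 :]:
                d = dm.between(haps[ha][0], haps[hb][0])
                tie_key = tuple(sorted([haps[ha][0], haps[hb][0]]))
                if best is None or (-d, tie_key) < best[0]:
                    best = ((-d, tie_key), (ha, hb))
        for h in best[1]:
            chosen_haps[h] = "divergent_haplotype"
    if pi:
        n_total = len(cluster)
        for h in hap_ids:
            if len(haps[h]) / n_total > cfg.dominant_haplotype_fraction:
                chosen_haps.setdefault(h, "dominant_haplotype")

    chosen: list[str] = []
    roles: dict[str, str] = {}

    def _pick(members: list[str], role: str) -> bool:
        """Pick up to two females (fallback: males); returns female found."""
        females = [m for m in members if by_spec[m].sex == "female"]
        pool = females[:2] if females else members[:2]
        for m in pool:
            if m not in roles:
                chosen.append(m)
                roles[m] = role
        return bool(females)

    male_only_haps = []
    for h in sorted(chosen_haps):
        if not _pick(haps[h], chosen_haps[h]):
            male_only_haps.append(h)

    for h in male_only_haps:
        # nearest haplotype (min p-distance) with females
        cands = []
        for other in hap_ids:
            if other == h:
                continue
            females = [m for m in haps[other] if by_spec[m].sex == "female"]
            if females:
                d = dm.between(haps[h][0], haps[other][0])
                cands.append((d, other, females))
        if cands:
            _, _, females = min(cands, key=lambda t: (t[0], t[1]))
            for m in females[:2]:
                if m not in roles:
                    chosen.append(m)
                    roles[m] = "female_supplement"

    males_only = all(by_spec[m].sex != "female" for m in chosen)
    return SelectionPlan(
        cluster_id=cluster_id,
        chosen_specimens=tuple(chosen),
        roles=roles,
        males_only=males_only,
    )


def _effective_label(label: MorphoLabel) -> str | None:
    """Homogeneity key; None for uninformative labels.

    A near-match is a distinct morphospecies string from the species it
    approaches.
    """
    if label.confidence == "unidentified":
        return None
    if label.confidence == "near":
        return f"nr. {label.morphospecies}"
    return label.morphospecies


def reconcile(
    candidates: list[Partition],
    baseline: Partition,
    morpho: list[MorphoLabel],
    dm: DistanceMatrix,
    cfg: Config | None = None,
    specimens: list[SpecimenRecord] | None = None,
    assessments: list[PIAssessment] | None = None,
) -> Delimitation:
    """Reconcile molecular clusters with morphological labels.

    Per baseline cluster: all validated specimens sharing one morphospecies
    → congruent; conflicting labels → the ranked candidates are searched
    for the first sub-partition of the cluster whose sub-clusters are each
    morpho-homogeneous (→ split, sub-clusters inherit the validated
    labels); no candidate resolves the conflict → unresolved, kept whole.
    Finally, clusters sharing an identical confirmed label are merged
    (lumped), within genus-hint groups when hints exist.
    """
    cfg = cfg or Config()
    known = baseline.specimen_ids
    labels: dict[str, str] = {}
    for m in morpho:
        if m.specimen_id not in known:
            raise KeyError(f"morphology label for unknown specimen {m.specimen_id!r}")
        eff = _effective_label(m)
        if eff is not None:
            labels[m.specimen_id] = eff
    genus_of = {s.specimen_id: s.genus_hint for s in specimens or []}
    confirmed = {
        m.specimen_id for m in morpho if m.confidence == "confirmed"
    }

    finer = [c for c in candidates if c.label != baseline.label]

    clusters: dict[str, frozenset] = {}
    status: dict[str, str] = {}
    species: dict[str, str] = {}
    source: dict[str, str] = {}
    ancestor: dict[str, str] = {}
    confirmed_label: dict[str, bool] = {}

    for cid in sorted(baseline.clusters, key=_natural_key):
        members = baseline.clusters[cid]
        seen = {labels[s] for s in members if s in labels}
        if len(seen) <= 1:
            clusters[cid] = members
            status[cid] = "congruent"
            species[cid] = next(iter(seen), "")
            source[cid] = baseline.label
            ancestor[cid] = cid
            confirmed_label[cid] = any(s in confirmed for s in members if s in labels)
            continue
        # conflict: look for a finer candidate resolving it
        resolved = False
        for cand in finer:
            subs = [
                members & cmembers
                for cmembers in cand.clusters.values()
                if members & cmembers
            ]
            if len(subs) < 2:
                continue
            ok = True
            for sub in subs:
                sub_seen = {labels[s] for s in sub if s in labels}
                if len(sub_seen) > 1:
                    ok = False
                    break
            if ok:
                for j, sub in enumerate(
                    sorted(subs, key=lambda s: min(s)), start=1
                ):
                    sub_id = f"{cid}.{j}"
                    clusters[sub_id] = frozenset(sub)
                    status[sub_id] = "split"
                    sub_seen = {labels[s] for s in sub if s in labels}
                    species[sub_id] = next(iter(sub_seen), "")
                    source[sub_id] = cand.label
                    ancestor[sub_id] = cid
                    confirmed_label[sub_id] = any(
                        s in confirmed for s in sub if s in labels
                    )
                resolved = True
                break
        if not resolved:
            clusters[cid] = members
            status[cid] = "unresolved"
            species[cid] = ""
            source[cid] = baseline.label
            ancestor[cid] = cid
            confirmed_label[cid] = False

    # lump step: merge clusters sharing an identical confirmed species label,
    # within genus-hint groups when hints exist
    by_key: dict[tuple, list[str]] = {}
    for cid, label in species.items():
        if not label or not confirmed_label[cid]:
            continue
        genus = ""
        if genus_of:
            genera = {genus_of.get(s, "") for s in clusters[cid]}
            genus = next(iter(genera)) if len(genera) == 1 else ""
        by_key.setdefault((genus, label), []).append(cid)
    for (genus, label), cids in sorted(by_key.items()):
        if len(cids) < 2:
            continue
        cids = sorted(cids, key=_natural_key)
        target = cids[0]
        merged = frozenset().union(*(clusters[c] for c in cids))
        for c in cids[1:]:
            del clusters[c], status[c], species[c], source[c]
            ancestor.pop(c, None)
        clusters[target] = merged
        status[target] = "lumped"
        species[target] = label

    return Delimitation(
        clusters=clusters,
        status=status,
        species_label=species,
        source_partition=source,
        baseline_ancestor=ancestor,
    )


def report(
    delim: Delimitation,
    dm: DistanceMatrix,
    specimens: list[SpecimenRecord] | None = None,
    assessments: list[PIAssessment] | None = None,
) -> pd.DataFrame:
    """Per final cluster: label, N, ancestor stability, intra p stats.

    Distances are reported in percent to 2 decimals, matching the style of
    a species-identification table.
    """
    stable_of = {a.cluster_id: a.stable for a in assessments or []}
    rows = []
    for cid in sorted(delim.clusters, key=_natural_key):
        members = delim.clusters[cid]
        mean_p, max_p = _intra_stats(dm, members)
        anc = delim.baseline_ancestor.get(cid, cid)
        rows.append(
            {
                "cluster": cid,
                "species": delim.species_label.get(cid, ""),
                "n": len(members),
                "stable": stable_of.get(anc, None),
                "mean_p_dist": mean_p,
                "max_p_dist": max_p,
                "status": delim.status[cid],
                "source_partition": delim.source_partition.get(cid, ""),
            }
        )
    return pd.DataFrame(rows)


def _natural_key(s: str):
    import re

    return [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", str(s))]
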