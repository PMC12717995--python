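"""Pairwise genetic distances and per-cluster distance summaries.

Two models are supported: uncorrected p-distance (mismatches over compared
sites) and its Jukes–Cantor correction.  Sites where either sequence holds a
gap or an ambiguity code are excluded pair-by-pair (pairwise deletion, the
TaxI2 convention); a complete-deletion switch exists for comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import Alignment, Partition

__all__ = [
    "DistanceMatrix",
    "ClusterDistanceSummary",
    "p_distance",
    "jc_distance",
    "distance_matrix",
    "cluster_summaries",
    "round_percent",
]

JC_SATURATION = 0.75

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class DistanceError(ValueError):
    pass


def _encode(rows: tuple[str, ...]) -> np.ndarray:
    """Rows -> int8 matrix; A,C,G,T -> 0..3, anything else -> -1 (ignored)."""
    n, L = len(rows), len(rows[0])
    out = np.full((n, L), -1, dtype=np.int8)
    lut = np.full(128, -1, dtype=np.int8)
    for b, c in _BASE_CODE.items():
        lut[ord(b)] = c
    for i, row in enumerate(rows):
        out[i] = lut[np.frombuffer(row.encode("ascii"), dtype=np.uint8)]
    return out


def p_distance(a: str, b: str) -> float:
    """Uncorrected p-distance between two aligned sequences.

    Pairwise deletion: sites with a gap or non-ACGT symbol in either
    sequence are excluded.  If no comparable site remains the distance is
    defined as 0 and a warning is emitted.
    """
    if len(a) != len(b):
        raise DistanceError(f"unequal lengths: {len(a)} vs {len(b)}")
    ea = _encode((a.upper(),))[0]
    eb = _encode((b.upper(),))[0]
    comparable = (ea >= 0) & (eb >= 0)
    n = int(comparable.sum())
    if n == 0:
        warnings.warn("no comparable sites; p-distance defined as 0", stacklevel=2)
        return 0.0
    mism = int((ea[comparable] != eb[comparable]).sum())
    return mism / n


def jc_distance(p: float) -> float:
    """Jukes–Cantor distance −(3/4)·ln(1 − 4p/3); requires p < 0.75."""
    if p < 0:
        raise DistanceError(f"negative p-distance {p}")
    if p >= JC_SATURATION:
        raise DistanceError(f"p-distance {p} at or beyond JC saturation (0.75)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances over sequence ids."""

    ids: tuple[str, ...]
    d: np.ndarray
    model: str = "p"

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise DistanceError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T):
            raise DistanceError("distance matrix not symmetric")
        if np.any(np.diag(d) != 0):
            raise DistanceError("non-zero diagonal")
        object.__setattr__(self, "d", d)

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, sequence_id: str) -> int:
        try:
            return self.ids.index(sequence_id)
        except ValueError:
            raise KeyError(sequence_id) from None

    def between(self, a: str, b: str) -> float:
        return float(self.d[self.index(a), self.index(b)])

    def submatrix(self, keep: list[str]) -> "DistanceMatrix":
        idx = np.array([self.index(s) for s in keep])
        return DistanceMatrix(tuple(keep), self.d[np.ix_(idx, idx)], self.model)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.d, index=list(self.ids), columns=list(self.ids)).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path, model: str = "p") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(str(c) for c in df.columns), df.to_numpy(dtype=float), model)


def distance_matrix(
    aln: Alignment, model: str = "p", pairwise_deletion: bool = True
) -> DistanceMatrix:
    """All-pairs distance matrix under the p or JC model.

    Vectorised over encoded bases; with ``pairwise_deletion=False`` any
    column containing a gap/ambiguity in any row is dropped for every pair
    (complete deletion).
    """
    if model not in ("p", "JC"):
        raise DistanceError(f"unknown model {model!r}")
    enc = _encode(aln.rows)
    valid = enc >= 0
    if not pairwise_deletion:
        keep = valid.all(axis=0)
        enc = enc[:, keep]
        valid = valid[:, keep]
    n = len(aln)
    d = np.zeros((n, n), dtype=float)
    degenerate = False
    for i in range(n):
        vi = valid[i]
        ei = enc[i]
        comp = vi & valid[i + 1 :]
        counts = comp.sum(axis=1)
        mism = ((ei != enc[i + 1 :]) & comp).sum(axis=1)
        with np.errstate(invalid="ignore"):
            p = np.where(counts > 0, mism / np.maximum(counts, 1), 0.0)
        if np.any(counts == 0):
            degenerate = True
        d[i, i + 1 :] = p
    if degenerate:
        warnings.warn(
            "some pairs share no comparable sites; their distance is 0",
            stacklevel=2,
        )
    d = d + d.T
    if model == "JC":
        pmax = d.max(initial=0.0)
        if pmax >= JC_SATURATION:
            raise DistanceError(f"p-distance {pmax} beyond JC saturation")
        d = -0.75 * np.log1p(-4.0 * d / 3.0)
        np.fill_diagonal(d, 0.0)
    return DistanceMatrix(tuple(aln.ids), d, model)


def round_percent(fraction: float, decimals: int = 2) -> float:
    """Fraction -> percentage, rounded half-up to ``decimals`` places."""
    scale = 10**decimals
    return math.floor(fraction * 100 * scale + 0.5) / scale


@dataclass(frozen=True)
class ClusterDistanceSummary:
    """Intra-cluster spread and nearest-neighbour separation, in percent."""

    cluster_id: str
    n: int
    mean_intra: float
    max_intra: float
    nn_cluster: str | None
    nn_dist: float | None


def cluster_summaries(
    dm: DistanceMatrix, part: Partition
) -> list[ClusterDistanceSummary]:
    """Per-cluster mean/max intra distance and nearest-neighbour distance.

    Percentages are rounded half-up to 2 decimals.  Singletons report
    mean = max = 0.  The nearest neighbour is the cluster containing the
    closest sequence outside the focal cluster.
    """
    id_index = {sid: i for i, sid in enumerate(dm.ids)}
    unknown = [s for s in part.specimen_ids if s not in id_index]
    if unknown:
        raise KeyError(f"partition ids missing from distance matrix: {unknown[:5]}")
    cluster_idx = {
        cid: np.array(sorted(id_index[s] for s in members))
        for cid, members in part.clusters.items()
    }
    out = []
    for cid in sorted(cluster_idx, key=_natural_key):
        idx = cluster_idx[cid]
        n = len(idx)
        if n > 1:
            sub = dm.d[np.ix_(idx, idx)]
            iu = np.triu_indices(n, k=1)
            intra = sub[iu]
            mean_intra = round_percent(float(intra.mean()))
            max_intra = round_percent(float(intra.max()))
        else:
            mean_intra = max_intra = 0.0
        nn_cluster, nn_dist = None, None
        best = np.inf
        for other, oidx in cluster_idx.items():
            if other == cid:
                continue
            dmin = float(dm.d[np.ix_(idx, oidx)].min())
            if dmin < best:
                best = dmin
                nn_cluster = other
        if nn_cluster is not None:
            nn_dist = round_percent(best)
        out.append(
            ClusterDistanceSummary(
                cluster_id=cid,
                n=n,
                mean_intra=mean_intra,
                max_intra=max_intra,
                nn_cluster=nn_cluster,
                nn_dist=nn_dist,
            )
        )
    return out


def _natural_key(s: str):
    import re

    return [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", s)]
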