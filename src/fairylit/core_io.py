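"""Domain types and readers/writers for sequences, metadata, partitions.

The package works on aligned COI minibarcodes (316 bp target region) plus a
specimen metadata table.  Everything downstream (distances, delimitation,
LIT congruence, haplotype networks) consumes the types defined here.

File conventions:

* alignment            — plain FASTA, all rows equal length
* specimens / labels   — TSV with a header row
* partition            — two-column TSV (specimen_id, cluster_id) plus a JSON
                         sidecar ``<path>.meta.json`` holding method /
                         threshold / score; diff-able and joins cleanly with
                         the metadata table
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alignment",
    "Config",
    "MorphoLabel",
    "Partition",
    "SpecimenRecord",
    "read_alignment",
    "write_alignment",
    "read_specimens",
    "write_specimens",
    "read_morpho_labels",
    "write_morpho_labels",
    "read_partition",
    "write_partition",
]

# Symbols allowed in aligned minibarcode rows: bases, gap, and IUPAC codes.
IUPAC_AMBIGUOUS = set("RYSWKMBDHVN")
VALID_SYMBOLS = set("ACGT-") | IUPAC_AMBIGUOUS

SEX_ALIASES: Mapping[str, str] = {
    "f": "female",
    "female": "female",
    "m": "male",
    "male": "male",
    "u": "unknown",
    "unknown": "unknown",
    "": "unknown",
}


class FairylitError(Exception):
    """Base class for all package errors."""


class AlignmentError(FairylitError):
    """Ragged rows, invalid symbols or duplicate sequence ids."""


class PartitionError(FairylitError):
    """Overlapping / non-covering clusters or malformed partition files."""


class MetadataError(FairylitError):
    """Malformed specimen or morphology tables."""


@dataclass(frozen=True)
class SpecimenRecord:
    """One wasp: identity, sex, collection site and its sequence."""

    specimen_id: str
    sex: str = "unknown"
    genus_hint: str = ""
    site_id: str = ""
    sequence_id: str = ""

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise MetadataError("specimen_id must be non-empty")
        if self.sex not in ("female", "male", "unknown"):
            raise MetadataError(f"invalid sex {self.sex!r}")
        if not self.sequence_id:
            # default: sequence named after the specimen
            object.__setattr__(self, "sequence_id", self.specimen_id)


@dataclass(frozen=True)
class Alignment:
    """Equal-length aligned nucleotide rows keyed by sequence id.

    Ambiguity codes are preserved on read; they are handled at distance
    time (pairwise deletion), never normalised away here.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in count")
        if len(self.ids) == 0:
            raise AlignmentError("alignment must contain at least one row")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if list(self.ids).count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment, row lengths {sorted(lengths)}")
        if self.length == 0:
            raise AlignmentError("alignment length must be > 0")
        for sid, row in zip(self.ids, self.rows):
            bad = set(row.upper()) - VALID_SYMBOLS
            if bad:
                raise AlignmentError(f"invalid symbols {sorted(bad)} in {sid!r}")
        object.__setattr__(self, "rows", tuple(r.upper() for r in self.rows))

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def __len__(self) -> int:
        return len(self.ids)

    def sequence(self, sequence_id: str) -> str:
        try:
            return self.rows[self.ids.index(sequence_id)]
        except ValueError:
            raise KeyError(sequence_id) from None

    def subset(self, keep: Sequence[str]) -> "Alignment":
        index = {sid: i for i, sid in enumerate(self.ids)}
        missing = [s for s in keep if s not in index]
        if missing:
            raise KeyError(f"unknown sequence ids: {missing}")
        return Alignment(tuple(keep), tuple(self.rows[index[s]] for s in keep))


@dataclass(frozen=True)
class Partition:
    """Assignment of specimens to disjoint, covering clusters.

    ``clusters`` maps cluster id -> frozenset of specimen ids.  Invariants
    (disjoint, covering, no empty cluster) are enforced on construction —
    every code path that builds a Partition goes through here.
    """

    method: str
    label: str
    clusters: Mapping[str, frozenset]
    threshold: float | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("ASAP", "RESL", "manual"):
            raise PartitionError(f"unknown method {self.method!r}")
        clusters = {str(k): frozenset(v) for k, v in self.clusters.items()}
        if any(len(c) == 0 for c in clusters.values()):
            raise PartitionError("empty cluster")
        counts: dict[str, int] = {}
        for members in clusters.values():
            for m in members:
                counts[m] = counts.get(m, 0) + 1
        dupes = sorted(m for m, c in counts.items() if c > 1)
        if dupes:
            raise PartitionError(f"specimens in more than one cluster: {dupes[:5]}")
        object.__setattr__(self, "clusters", clusters)

    @property
    def specimen_ids(self) -> frozenset:
        return frozenset().union(*self.clusters.values())

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def cluster_of(self, specimen_id: str) -> str:
        for cid, members in self.clusters.items():
            if specimen_id in members:
                return cid
        raise KeyError(specimen_id)

    def assignment(self) -> dict[str, str]:
        """specimen_id -> cluster_id map."""
        out: dict[str, str] = {}
        for cid, members in self.clusters.items():
            for m in members:
                out[m] = cid
        return out

    def relabelled(self, label: str) -> "Partition":
        return replace(self, label=label)


@dataclass(frozen=True)
class MorphoLabel:
    """A morphological determination for one validated specimen."""

    specimen_id: str
    morphospecies: str
    confidence: str = "confirmed"

    def __post_init__(self) -> None:
        if self.confidence not in ("confirmed", "near", "unidentified"):
            raise MetadataError(f"invalid confidence {self.confidence!r}")


@dataclass(frozen=True)
class Config:
    """Analysis thresholds; defaults follow the published protocol.

    resl_threshold               single-linkage pre-clustering distance (2.2%)
    pi_pdist_threshold           max intra-cluster p-distance flagging a
                                 potentially incongruent cluster (1.5%)
    dominant_haplotype_fraction  haplotype frequency above which a haplotype
                                 must be validated in a PI cluster (20%)
    asap_top_k                   number of best-scoring candidate partitions
                                 carried into the LIT comparison (3)
    distance_model               'p' (uncorrected) or 'JC' (Jukes-Cantor)
    """

    resl_threshold: float = 0.022
    pi_pdist_threshold: float = 0.015
    dominant_haplotype_fraction: float = 0.20
    asap_top_k: int = 3
    distance_model: str = "JC"
    pairwise_deletion: bool = True
    panmixia_reps: int = 1000
    mcl_inflation: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("resl_threshold", "pi_pdist_threshold", "dominant_haplotype_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.asap_top_k < 1:
            raise ValueError("asap_top_k must be >= 1")
        if self.distance_model not in ("p", "JC"):
            raise ValueError(f"distance_model must be 'p' or 'JC', got {self.distance_model!r}")

    @classmethod
    def from_json(cls, path: str | Path) -> "Config":
        data = json.loads(Path(path).read_text())
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path) -> Alignment:
    """Parse a FASTA alignment; rows must be equal length, ids unique.

    IDs are preserved verbatim (case-sensitive, no trimming beyond the
    FASTA word rule applied by the parser).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return Alignment(
        tuple(r.id for r in records),
        tuple(str(r.seq) for r in records),
    )


def write_alignment(aln: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(aln.ids, aln.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_specimens(path: str | Path) -> list[SpecimenRecord]:
    """Read the specimen metadata TSV.

    Required column: ``specimen_id``.  Optional: ``sex`` (F/M/U aliases are
    normalised), ``genus_hint``, ``site_id``, ``sequence_id``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "specimen_id" not in df.columns:
        raise MetadataError(f"missing required column 'specimen_id' in {path}")
    if df["specimen_id"].duplicated().any():
        dupes = df.loc[df["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise MetadataError(f"duplicated specimen_id: {dupes[:5]}")
    out = []
    for _, row in df.iterrows():
        raw_sex = str(row.get("sex", "")).strip().lower()
        if raw_sex not in SEX_ALIASES:
            raise MetadataError(f"unrecognised sex value {row.get('sex')!r}")
        out.append(
            SpecimenRecord(
                specimen_id=row["specimen_id"],
                sex=SEX_ALIASES[raw_sex],
                genus_hint=str(row.get("genus_hint", "")),
                site_id=str(row.get("site_id", "")),
                sequence_id=str(row.get("sequence_id", "")) or row["specimen_id"],
            )
        )
    return out


def write_specimens(specimens: Iterable[SpecimenRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "specimen_id": s.specimen_id,
                "sex": s.sex,
                "genus_hint": s.genus_hint,
                "site_id": s.site_id,
                "sequence_id": s.sequence_id,
            }
            for s in specimens
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_morpho_labels(path: str | Path) -> list[MorphoLabel]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("specimen_id", "morphospecies"):
        if col not in df.columns:
            raise MetadataError(f"missing required column {col!r} in {path}")
    if df["specimen_id"].duplicated().any():
        raise MetadataError("more than one morphology label for a specimen")
    return [
        MorphoLabel(
            specimen_id=row["specimen_id"],
            morphospecies=row["morphospecies"],
            confidence=str(row.get("confidence", "confirmed")) or "confirmed",
        )
        for _, row in df.iterrows()
    ]


def write_morpho_labels(labels: Iterable[MorphoLabel], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "specimen_id": l.specimen_id,
                "morphospecies": l.morphospecies,
                "confidence": l.confidence,
            }
            for l in labels
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_partition(part: Partition, path: str | Path) -> None:
    """Two-column TSV (specimen_id, cluster_id) + JSON metadata sidecar."""
    path = Path(path)
    assignment = part.assignment()
    df = pd.DataFrame(
        sorted(assignment.items()), columns=["specimen_id", "cluster_id"]
    )
    df.to_csv(path, sep="\t", index=False)
    meta = {
        "method": part.method,
        "label": part.label,
        "threshold": part.threshold,
        "score": part.score,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2) + "\n")


def read_partition(path: str | Path) -> Partition:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("specimen_id", "cluster_id"):
        if col not in df.columns:
            raise PartitionError(f"missing column {col!r} in {path}")
    if df["specimen_id"].duplicated().any():
        raise PartitionError("specimen assigned to more than one cluster")
    clusters: dict[str, set] = {}
    for _, row in df.iterrows():
        clusters.setdefault(row["cluster_id"], set()).add(row["specimen_id"])
    meta_path = _sidecar(path)
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return Partition(
        method=meta.get("method", "manual"),
        label=meta.get("label", path.stem),
        clusters={k: frozenset(v) for k, v in clusters.items()},
        threshold=meta.get("threshold"),
        score=meta.get("score"),
    )
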