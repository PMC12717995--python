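"""From tagged paired-end amplicon reads to one consensus minibarcode per
specimen.

The wet-lab construct is: 1–4 heterogeneity-spacer bases, a 5-bp specimen
tag (12 forward × 8 reverse = 96 combinations), the degenerate COI primer
(BF1 forward, C_LepFolR reverse), then the 316-bp insert.  The pipeline
demultiplexes with exact tag matching, strips primers (≤5 mismatches),
quality-trims at Q20, drops reads under 250 bp, merges mates by overlap
(higher quality wins at mismatches), clusters merged reads at 98%
identity, takes the majority-rule consensus of the largest cluster, and
screens it for NUMT signatures (internal stop codons or frameshifts under
the invertebrate mitochondrial code).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace

from Bio.Seq import Seq

__all__ = [
    "FastqRead",
    "TagScheme",
    "ConsensusCall",
    "demultiplex",
    "trim",
    "merge_pairs",
    "call_consensus",
    "screen_orf",
    "process_bin",
    "call_barcodes",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

PRIMER_F = "ACWGGWTGRACWGTNTAYCC"          # BF1
PRIMER_R = "TAAACTTCWGGRTGWCCAAAAAATCA"    # C_LepFolR

# 5-bp specimen tags; fixed arbitrary sets with pairwise Hamming distance
# ≥ 2, so one sequencing error can never convert one tag into another.
FORWARD_TAGS = (
    "ACACG", "AGTCA", "ATCGT", "CATGA", "CGATC", "CTAGG",
    "GACTT", "GCGAA", "GTACC", "TAGCC", "TCTAG", "TGCAT",
)
REVERSE_TAGS = (
    "AAGGC", "ACCTA", "CAACT", "CGGAG", "GATAC", "GGTCT", "TCAGA", "TTGCG",
)

MITO_TABLE = 5  # invertebrate mitochondrial genetic code


@dataclass(frozen=True)
class FastqRead:
    """One read: sequence plus per-base Phred qualities."""

    read_id: str
    seq: str
    qual: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "FastqRead":
        return FastqRead(
            self.read_id,
            str(Seq(self.seq).reverse_complement()),
            tuple(reversed(self.qual)),
        )

    def to_fastq(self) -> str:
        quals = "".join(chr(q + 33) for q in self.qual)
        return f"@{self.read_id}\n{self.seq}\n+\n{quals}\n"


def parse_fastq(path) -> list[FastqRead]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            FastqRead(
                rec.id,
                str(rec.seq).upper(),
                tuple(rec.letter_annotations["phred_quality"]),
            )
        )
    return out


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(r.to_fastq())


@dataclass(frozen=True)
class TagScheme:
    """Fusion-primer layout: spacers, tags and degenerate COI primers."""

    forward_tags: tuple[str, ...] = FORWARD_TAGS
    reverse_tags: tuple[str, ...] = REVERSE_TAGS
    spacer_range: tuple[int, int] = (1, 4)
    primer_f: str = PRIMER_F
    primer_r: str = PRIMER_R
    target_len: int = 316
    tag_len: int = 5

    def __post_init__(self) -> None:
        tags = self.forward_tags + self.reverse_tags
        if any(len(t) != self.tag_len for t in tags):
            raise ValueError(f"tags must be {self.tag_len} bases")
        if len(set(self.forward_tags)) != len(self.forward_tags) or len(
            set(self.reverse_tags)
        ) != len(self.reverse_tags):
            raise ValueError("tags must be unique")

    @property
    def combinations(self) -> list[tuple[str, str]]:
        return [(f, r) for f in self.forward_tags for r in self.reverse_tags]


@dataclass(frozen=True)
class ConsensusCall:
    """One candidate barcode for a specimen bin."""

    specimen_bin: tuple[str, str]
    consensus: str
    depth: int
    status: str  # accepted | low_coverage | pseudogene | off_target | ambiguous_multi


def primer_mismatches(primer: str, seq: str) -> int:
    """Mismatch count of a degenerate primer against an equal-length window."""
    return sum(
        1 for p, s in zip(primer, seq) if s not in IUPAC.get(p, p)
    )


def _find_tag(read: FastqRead, tags, scheme: TagScheme, primer: str) -> str | None:
    """Exact tag match after skipping 1–4 spacer bases.

    The downstream primer must also roughly match (≤5 mismatches over ≥5
    bases) so that a chance 5-mer at the wrong offset cannot mis-assign
    the read.
    """
    lo, hi = scheme.spacer_range
    for off in range(lo, hi + 1):
        cand = read.seq[off : off + scheme.tag_len]
        if cand in tags:
            window = read.seq[off + scheme.tag_len : off + scheme.tag_len + len(primer)]
            if len(window) >= 5 and primer_mismatches(primer[: len(window)], window) <= 5:
                return cand
    return None


def demultiplex(
    read_pairs: list[tuple[FastqRead, FastqRead]], scheme: TagScheme
) -> dict:
    """Bin read pairs by (forward tag, reverse tag); no mismatches allowed.

    Unassignable pairs land in the ``None`` discard bin.
    """
    bins: dict = {}
    for r1, r2 in read_pairs:
        f = _find_tag(r1, scheme.forward_tags, scheme, scheme.primer_f)
        r = _find_tag(r2, scheme.reverse_tags, scheme, scheme.primer_r)
        key = (f, r) if f is not None and r is not None else None
        bins.setdefault(key, []).append((r1, r2))
    return bins


def trim(
    read: FastqRead,
    scheme: TagScheme,
    primer: str | None = None,
    min_len: int = 250,
    min_quality: int = 20,
    window: int = 4,
) -> FastqRead | None:
    """Strip the spacer/tag/primer prefix and quality-trim the 3' end.

    The primer is located anywhere in the first ~15 bases allowing five
    mismatches and a minimum overlap of five; everything through its end
    is removed.  The 3' end is trimmed with a sliding-minimum window
    (width 4) at Q20.  Reads shorter than ``min_len`` after trimming are
    dropped (returns None).
    """
    primer = primer or scheme.primer_f
    start = None
    lo, hi = scheme.spacer_range
    search_to = hi + scheme.tag_len + 3
    for pos in range(0, min(search_to, len(read.seq))):
        window_seq = read.seq[pos : pos + len(primer)]
        if len(window_seq) < 5:
            break
        if primer_mismatches(primer[: len(window_seq)], window_seq) <= 5:
            start = pos + len(window_seq)
            break
    seq = read.seq[start:] if start is not None else read.seq
    qual = list(read.qual[start:] if start is not None else read.qual)

    while len(seq) >= window and min(qual[-window:]) < min_quality:
        seq = seq[:-1]
        qual.pop()
    if len(seq) < min_len:
        return None
    return FastqRead(read.read_id, seq, tuple(qual))


def merge_pairs(
    r1: FastqRead, r2: FastqRead, min_overlap: int = 20, max_mismatch_rate: float = 0.1
) -> FastqRead | None:
    """Overlap-merge a pair; the mate is reverse-complemented first.

    The overlap maximising matches (with mismatch rate ≤ 10%) is used;
    mismatching positions resolve to the higher-quality base.  Pairs with
    no admissible overlap are dropped (None).
    """
    rc = r2.reverse_complement()
    best = None
    for ov in range(min(len(r1), len(rc)), min_overlap - 1, -1):
        a = r1.seq[-ov:]
        b = rc.seq[:ov]
        mism = sum(1 for x, y in zip(a, b) if x != y)
        if mism / ov <= max_mismatch_rate:
            score = ov - 2 * mism
            if best is None or score > best[0]:
                best = (score, ov, mism)
    if best is None:
        return None
    _, ov, _ = best
    head_seq = r1.seq[:-ov]
    head_qual = list(r1.qual[:-ov])
    mid_seq = []
    mid_qual = []
    for i in range(ov):
        qa = r1.qual[len(r1) - ov + i]
        qb = rc.qual[i]
        ca = r1.seq[len(r1) - ov + i]
        cb = rc.seq[i]
        if ca == cb:
            mid_seq.append(ca)
            mid_qual.append(max(qa, qb))
        elif qa >= qb:
            mid_seq.append(ca)
            mid_qual.append(qa)
        else:
            mid_seq.append(cb)
            mid_qual.append(qb)
    tail_seq = rc.seq[ov:]
    tail_qual = list(rc.qual[ov:])
    return FastqRead(
        r1.read_id,
        head_seq + "".join(mid_seq) + tail_seq,
        tuple(head_qual + mid_qual + tail_qual),
    )


def _identity(a: str, b: str, min_overlap: int) -> float:
    ov = min(len(a), len(b))
    if ov < min_overlap:
        return 0.0
    matches = sum(1 for x, y in zip(a[:ov], b[:ov]) if x == y)
    return matches / ov


def call_consensus(
    merged: list[FastqRead],
    specimen_bin: tuple[str, str] = ("", ""),
    min_depth: int = 10,
    identity: float = 0.98,
    min_overlap: int = 250,
    reference: str | None = None,
    reference_identity: float = 0.80,
) -> list[ConsensusCall]:
    """Greedy centroid clustering at 98% identity + majority-rule consensus.

    Unique sequences are visited abundance-first; each joins the first
    centroid it matches at ≥ ``identity`` over ≥ ``min_overlap`` aligned
    bases, else founds a new cluster.  The cluster with the most reads
    yields the bin's main call; additional on-target clusters are flagged
    ``ambiguous_multi`` (heteroplasmy / cross-contamination candidates).
    Calls under ``min_depth`` reads are ``low_coverage``.  When a
    reference profile is given, clusters matching it at < 80% identity are
    ``off_target``.
    """
    if not merged:
        return []
    uniq = Counter(r.seq for r in merged)
    ordered = sorted(uniq.items(), key=lambda kv: (-kv[1], kv[0]))
    centroids: list[str] = []
    members: list[list[tuple[str, int]]] = []
    for seq, count in ordered:
        for ci, cseq in enumerate(centroids):
            if _identity(seq, cseq, min_overlap) >= identity:
                members[ci].append((seq, count))
                break
        else:
            centroids.append(seq)
            members.append([(seq, count)])

    clusters = sorted(
        zip(centroids, members),
        key=lambda cm: (-sum(c for _, c in cm[1]), cm[0]),
    )
    calls = []
    for rank, (cseq, mem) in enumerate(clusters):
        depth = sum(c for _, c in mem)
        cons = _majority_consensus(mem, len(cseq))
        if reference is not None and _identity(cons, reference, 1) < reference_identity:
            status = "off_target"
        elif rank > 0:
            status = "ambiguous_multi"
        elif depth < min_depth:
            status = "low_coverage"
        else:
            status = "accepted"
        calls.append(
            ConsensusCall(
                specimen_bin=specimen_bin, consensus=cons, depth=depth, status=status
            )
        )
    return calls


def _majority_consensus(members: list[tuple[str, int]], length: int) -> str:
    out = []
    for i in range(length):
        votes: Counter = Counter()
        for seq, count in members:
            if i < len(seq):
                votes[seq[i]] += count
        base, _ = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        out.append(base)
    return "".join(out)


def screen_orf(call: ConsensusCall, target_len: int = 316) -> ConsensusCall:
    """Flag NUMT-like consensi: internal stops or frameshifted lengths.

    The reading frame is the one of the three minimising internal stops
    under the invertebrate mitochondrial code (the region's frame is not
    encoded in the amplicon itself).  A length deviating from the target
    by a non-multiple of three indicates an indel (frameshift).
    """
    if call.status not in ("accepted", "low_coverage"):
        return call
    if (len(call.consensus) - target_len) % 3 != 0:
        return replace(call, status="pseudogene")
    if _min_internal_stops(call.consensus) > 0:
        return replace(call, status="pseudogene")
    return call


def _min_internal_stops(seq: str) -> int:
    best = None
    for frame in range(3):
        sub = seq[frame:]
        sub = sub[: len(sub) - len(sub) % 3]
        aa = str(Seq(sub).translate(table=MITO_TABLE))
        stops = aa[:-1].count("*")  # a trailing stop is not internal
        best = stops if best is None else min(best, stops)
    return best or 0


def process_bin(
    pairs: list[tuple[FastqRead, FastqRead]],
    scheme: TagScheme,
    specimen_bin: tuple[str, str] = ("", ""),
    min_depth: int = 10,
    reference: str | None = None,
) -> tuple[list[ConsensusCall], dict]:
    """Trim, merge and call one demultiplexed bin; returns calls + audit."""
    audit = {"input": len(pairs), "trimmed_out": 0, "merge_failed": 0, "merged": 0}
    merged_reads = []
    for r1, r2 in pairs:
        t1 = trim(r1, scheme, primer=scheme.primer_f)
        t2 = trim(r2, scheme, primer=scheme.primer_r)
        if t1 is None or t2 is None:
            audit["trimmed_out"] += 1
            continue
        m = merge_pairs(t1, t2)
        if m is None:
            audit["merge_failed"] += 1
            continue
        merged_reads.append(m)
    audit["merged"] = len(merged_reads)
    calls = call_consensus(
        merged_reads,
        specimen_bin=specimen_bin,
        min_depth=min_depth,
        reference=reference,
    )
    calls = [screen_orf(c, target_len=scheme.target_len) for c in calls]
    return calls, audit


def call_barcodes(
    read_pairs: list[tuple[FastqRead, FastqRead]],
    scheme: TagScheme | None = None,
    min_depth: int = 10,
    reference: str | None = None,
) -> tuple[dict, dict]:
    """End-to-end: demultiplex then process every bin.

    Returns (calls by bin, audit by bin); the audit also reports the
    demultiplex discard count under the ``None`` key so that every input
    read pair is accounted for.
    """
    scheme = scheme or TagScheme()
    bins = demultiplex(read_pairs, scheme)
    calls: dict = {}
    audit: dict = {}
    for combo, pairs in sorted(bins.items(), key=lambda kv: (kv[0] is None, kv[0])):
        if combo is None:
            audit[None] = {"input": len(pairs), "discarded_demux": len(pairs)}
            continue
        calls[combo], audit[combo] = process_bin(
            pairs, scheme, specimen_bin=combo, min_depth=min_depth, reference=reference
        )
    return calls, audit
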