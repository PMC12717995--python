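"""Synthetic barcode communities and raw tagged reads with known truth.

The generator emulates the statistical structure of a temperate-forest
fairyfly megabarcoding sample: a skewed species-abundance distribution,
within-species haplotype variation bounded by a maximum intraspecific
divergence, between-species divergences inside a stated range (so a
barcode gap exists by construction in gap mode), optional cryptic
complexes with deep substructure, sexed specimens, and a morphologist
oracle with a configurable error rate and optional female-only
identifiability.  Everything is seeded; the same seed reproduces the same
community byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .core_io import Alignment, MorphoLabel, Partition, SpecimenRecord
from .barcode_caller import IUPAC, FastqRead, TagScheme

__all__ = [
    "CommunitySpec",
    "GroundTruth",
    "ReadTruth",
    "simulate_community",
    "simulate_reads",
    "morpho_oracle",
    "paper_like_spec",
]

BASES = "ACGT"
BARCODE_LEN = 316
STOP_CODONS = ("TAA", "TAG")  # invertebrate mitochondrial code


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of a synthetic barcode community.

    Defaults describe a gap-mode community: intraspecific divergence at
    most 1.5% and interspecific divergence between 4.5% and 27%, matching
    the non-cryptic regime of a typical minibarcode survey.
    """

    n_species: int = 20
    n_specimens: int = 200
    abundance_model: str = "geometric"  # or "lognormal"
    abundance_skew: float = 0.25
    intra_divergence_max: float = 0.015
    inter_divergence_range: tuple[float, float] = (0.045, 0.27)
    cryptic_complexes: tuple[tuple[int, float], ...] = ()
    sex_ratio: float = 0.5
    seed: int = 0
    length: int = BARCODE_LEN

    def __post_init__(self) -> None:
        if self.n_specimens < self.n_species:
            raise ValueError("need at least one specimen per species")
        lo, hi = self.inter_divergence_range
        if not 0 < lo < hi:
            raise ValueError("invalid inter-divergence range")
        if lo <= self.intra_divergence_max and not self.cryptic_complexes:
            raise ValueError(
                "gap mode requires inter range min > intra max"
            )
        for idx, depth in self.cryptic_complexes:
            if not 0 <= idx < self.n_species:
                raise ValueError(f"cryptic complex index {idx} out of range")
            if not 0 < depth <= 0.11:
                raise ValueError(f"substructure depth {depth} outside (0, 0.11]")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows: true species, haplotypes and sexes."""

    species_of: dict  # specimen_id -> species label
    haplotype_of: dict  # specimen_id -> haplotype key
    sex_of: dict  # specimen_id -> female | male

    def true_partition(self) -> Partition:
        clusters: dict[str, set] = {}
        for sid, sp in self.species_of.items():
            clusters.setdefault(sp, set()).add(sid)
        return Partition(
            method="manual",
            label="truth",
            clusters={k: frozenset(v) for k, v in clusters.items()},
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "species_of": self.species_of,
                    "haplotype_of": self.haplotype_of,
                    "sex_of": self.sex_of,
                },
                fh,
                indent=2,
            )


def _random_coding_sequence(length: int, rng: np.random.Generator) -> str:
    """Random sequence with no stop codon in frame 0."""
    n_codons, rem = divmod(length, 3)
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(list(BASES), size=3))
        if c not in STOP_CODONS:
            codons.append(c)
    tail = "".join(rng.choice(list(BASES), size=rem))
    return "".join(codons) + tail


def _mutate(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Apply substitutions at distinct sites, never creating an in-frame stop."""
    s = list(seq)
    sites = rng.choice(len(s), size=min(n_subs, len(s)), replace=False)
    for site in sites:
        original = s[site]
        for _ in range(20):
            new = BASES[rng.integers(4)]
            if new == original:
                continue
            s[site] = new
            codon_start = (site // 3) * 3
            codon = "".join(s[codon_start : codon_start + 3])
            if len(codon) < 3 or codon not in STOP_CODONS:
                break
            s[site] = original
    return "".join(s)


def _p_dist(a: str, b: str) -> float:
    return sum(1 for x, y in zip(a, b) if x != y) / len(a)


def _abundances(spec: CommunitySpec, rng: np.random.Generator) -> np.ndarray:
    k = spec.n_species
    if spec.abundance_model == "geometric":
        weights = (1.0 - spec.abundance_skew) ** np.arange(k)
    elif spec.abundance_model == "lognormal":
        weights = rng.lognormal(mean=0.0, sigma=max(spec.abundance_skew, 1e-6) * 6, size=k)
    else:
        raise ValueError(f"unknown abundance model {spec.abundance_model!r}")
    weights = weights / weights.sum()
    counts = np.ones(k, dtype=int)
    extra = rng.multinomial(spec.n_specimens - k, weights)
    return counts + extra


def simulate_community(
    spec: CommunitySpec,
) -> tuple[Alignment, list[SpecimenRecord], GroundTruth]:
    """Generate an aligned barcode community with full ground truth.

    Species founders are placed by rejection sampling so that every
    founder pair sits inside the interspecific divergence range (at most
    10,000 proposals per founder).  Haplotypes mutate the founder within
    the intraspecific bound; cryptic complexes add a second subclade at
    the stated depth.  Abundances follow the configured rank-abundance
    model with every species kept at ≥ 1 specimen.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    lo, hi = spec.inter_divergence_range
    root = _random_coding_sequence(L, rng)

    founders: list[str] = []
    k_lo = max(1, int(np.ceil(lo * L * 0.55)))
    k_hi = max(k_lo + 1, int(hi * L * 0.5))
    for _ in range(spec.n_species):
        for attempt in range(10_000):
            k = int(rng.integers(k_lo, k_hi + 1))
            cand = _mutate(root, k, rng)
            if all(lo <= _p_dist(cand, f) <= hi for f in founders):
                founders.append(cand)
                break
        else:
            raise RuntimeError(
                "could not place species founders inside the divergence "
                "range after 10,000 attempts; widen inter_divergence_range"
            )

    cryptic = dict(spec.cryptic_complexes)
    counts = _abundances(spec, rng)
    max_intra_subs = max(0, int(spec.intra_divergence_max * L // 2))

    ids: list[str] = []
    rows: list[str] = []
    species_of: dict = {}
    haplotype_of: dict = {}
    sex_of: dict = {}
    specimens: list[SpecimenRecord] = []
    spec_counter = 0

    for si in range(spec.n_species):
        label = f"species_{si+1:02d}"
        n = int(counts[si])
        subclades = [founders[si]]
        if si in cryptic:
            depth_subs = max(1, int(round(cryptic[si] * L)))
            subclades.append(_mutate(founders[si], depth_subs, rng))
        # subclade membership first, then a haplotype pool whose richness
        # scales with subclade abundance (large clusters carry many more
        # haplotypes than small ones)
        subclade_of = [j % len(subclades) for j in range(n)]
        pools: list[list[str]] = []
        for sc, sc_founder in enumerate(subclades):
            n_sub = sum(1 for x in subclade_of if x == sc)
            if max_intra_subs == 0:
                n_h = 1
            else:
                n_h = max(1, min(n_sub, 1 + int(rng.poisson(2.6 * np.sqrt(n_sub)))))
            pool = [sc_founder]
            for _ in range(n_h - 1):
                k = int(rng.integers(1, max_intra_subs + 1))
                pool.append(_mutate(sc_founder, k, rng))
            pools.append(pool)
        for j in range(n):
            spec_counter += 1
            sid = f"SP{spec_counter:04d}"
            sc = subclade_of[j]
            hap = pools[sc][int(rng.integers(len(pools[sc])))]
            sex = "female" if rng.random() < spec.sex_ratio else "male"
            ids.append(sid)
            rows.append(hap)
            species_of[sid] = label
            haplotype_of[sid] = hap
            sex_of[sid] = sex
            specimens.append(
                SpecimenRecord(
                    specimen_id=sid,
                    sex=sex,
                    genus_hint=f"genus_{si % 6 + 1}",
                    site_id=f"site_{int(rng.integers(1, 11))}",
                    sequence_id=sid,
                )
            )

    aln = Alignment(tuple(ids), tuple(rows))
    truth = GroundTruth(
        species_of=species_of, haplotype_of=haplotype_of, sex_of=sex_of
    )
    return aln, specimens, truth


def morpho_oracle(
    truth: GroundTruth,
    error_rate: float = 0.0,
    seed: int = 0,
    specimen_ids: list[str] | None = None,
    sex_limited: bool = False,
) -> list[MorphoLabel]:
    """Stand-in for slide-mounted identification.

    Returns the true species label with probability 1 − error_rate (errors
    draw a different species uniformly).  In sex-limited mode males come
    back unidentifiable, mirroring keys that address females only.
    """
    rng = np.random.default_rng(seed)
    all_species = sorted(set(truth.species_of.values()))
    wanted = specimen_ids if specimen_ids is not None else sorted(truth.species_of)
    out = []
    for sid in wanted:
        if sid not in truth.species_of:
            raise KeyError(f"unknown specimen {sid!r}")
        if sex_limited and truth.sex_of[sid] == "male":
            out.append(MorphoLabel(sid, "", confidence="unidentified"))
            continue
        label = truth.species_of[sid]
        if error_rate > 0 and rng.random() < error_rate and len(all_species) > 1:
            others = [s for s in all_species if s != label]
            label = others[int(rng.integers(len(others)))]
        out.append(MorphoLabel(sid, label, confidence="confirmed"))
    return out


# ---------------------------------------------------------------------------
# raw tagged reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadTruth:
    """Per-bin planted truth for the read simulator."""

    bin_of: dict  # specimen_id -> (forward_tag, reverse_tag)
    barcode_of: dict  # specimen_id -> planted barcode string
    pseudogene: frozenset  # specimens whose amplicon is a planted NUMT
    contaminated: frozenset  # specimens with planted off-target reads
    heteroplasmic: frozenset  # specimens with a second mitochondrial variant


def _resolve_primer(primer: str, rng: np.random.Generator) -> str:
    return "".join(
        b if b in BASES else IUPAC[b][int(rng.integers(len(IUPAC[b])))]
        for b in primer
    )


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    s = list(seq)
    hits = np.where(rng.random(len(s)) < error_rate)[0]
    for i in hits:
        s[i] = BASES[(BASES.index(s[i]) + 1 + int(rng.integers(3))) % 4] if s[i] in BASES else s[i]
    return "".join(s)


def _make_numt(barcode: str, rng: np.random.Generator) -> str:
    """Degraded nuclear copy: one-base deletion plus an in-frame stop."""
    s = list(barcode)
    del s[int(rng.integers(10, len(s) - 10))]
    pos = (int(rng.integers(5, len(s) // 3 - 5))) * 3
    s[pos : pos + 3] = list(STOP_CODONS[int(rng.integers(2))])
    return "".join(s)


def _shuffled_codon_contaminant(barcode: str, rng: np.random.Generator) -> str:
    codons = [barcode[i : i + 3] for i in range(0, len(barcode) - 2, 3)]
    order = rng.permutation(len(codons))
    tail = barcode[len(codons) * 3 :]
    return "".join(codons[i] for i in order) + tail


def simulate_reads(
    aln: Alignment,
    truth: GroundTruth,
    depth_model: int = 20,
    error_rate: float = 0.0,
    contaminant_rate: float = 0.0,
    pseudogene_rate: float = 0.0,
    heteroplasmy_rate: float = 0.0,
    scheme: TagScheme | None = None,
    seed: int = 0,
    read_len: int = 300,
    base_quality: int = 36,
) -> tuple[list[tuple[FastqRead, FastqRead]], ReadTruth]:
    """Paired tagged reads for up to 96 specimens (one plate).

    Each specimen gets one tag combination; reads carry the full
    spacer+tag+primer construct on both mates.  Optional planted
    artefacts: NUMT amplicons (pseudogene_rate), shuffled-codon off-target
    reads (contaminant_rate) and a second divergent mitochondrial variant
    (heteroplasmy_rate).
    """
    scheme = scheme or TagScheme()
    rng = np.random.default_rng(seed)
    combos = scheme.combinations
    if len(aln) > len(combos):
        raise ValueError(
            f"{len(aln)} specimens exceed the {len(combos)} tag combinations "
            "of one plate; split the run"
        )
    bin_of: dict = {}
    barcode_of: dict = {}
    pseudo, contam, hetero = set(), set(), set()
    pairs: list[tuple[FastqRead, FastqRead]] = []

    for idx, sid in enumerate(aln.ids):
        combo = combos[idx]
        bin_of[sid] = combo
        barcode = aln.sequence(sid).replace("-", "")
        if pseudogene_rate > 0 and rng.random() < pseudogene_rate:
            amplicon = _make_numt(barcode, rng)
            pseudo.add(sid)
        else:
            amplicon = barcode
        barcode_of[sid] = amplicon

        variants = [(amplicon, 1.0)]
        if heteroplasmy_rate > 0 and rng.random() < heteroplasmy_rate:
            second = _mutate(amplicon, max(13, int(0.04 * len(amplicon))), rng)
            variants = [(amplicon, 0.7), (second, 0.3)]
            hetero.add(sid)
        has_contaminant = contaminant_rate > 0 and rng.random() < contaminant_rate
        if has_contaminant:
            contam.add(sid)
            contaminant = _shuffled_codon_contaminant(barcode, rng)

        depth = int(depth_model)
        n_contam = max(2, depth // 3) if has_contaminant else 0
        for ri in range(depth + n_contam):
            if ri < depth:
                r = rng.random()
                insert = variants[0][0] if r < variants[0][1] or len(variants) == 1 else variants[1][0]
            else:
                insert = contaminant
            pairs.append(
                _make_pair(
                    f"{sid}_r{ri}", insert, combo, scheme, rng,
                    read_len, base_quality, error_rate,
                )
            )
    return pairs, ReadTruth(
        bin_of=bin_of,
        barcode_of=barcode_of,
        pseudogene=frozenset(pseudo),
        contaminated=frozenset(contam),
        heteroplasmic=frozenset(hetero),
    )


def _make_pair(
    read_id: str,
    insert: str,
    combo: tuple[str, str],
    scheme: TagScheme,
    rng: np.random.Generator,
    read_len: int,
    base_quality: int,
    error_rate: float,
) -> tuple[FastqRead, FastqRead]:
    from Bio.Seq import Seq

    ftag, rtag = combo
    lo, hi = scheme.spacer_range
    sp1 = "".join(rng.choice(list(BASES), size=int(rng.integers(lo, hi + 1))))
    sp2 = "".join(rng.choice(list(BASES), size=int(rng.integers(lo, hi + 1))))
    fwd_construct = sp1 + ftag + _resolve_primer(scheme.primer_f, rng) + insert
    rev_construct = (
        sp2 + rtag + _resolve_primer(scheme.primer_r, rng)
        + str(Seq(insert).reverse_complement())
    )
    s1 = _apply_errors(fwd_construct[:read_len], error_rate, rng)
    s2 = _apply_errors(rev_construct[:read_len], error_rate, rng)
    q1 = tuple([base_quality] * len(s1))
    q2 = tuple([base_quality] * len(s2))
    return FastqRead(f"{read_id}/1", s1, q1), FastqRead(f"{read_id}/2", s2, q2)


def paper_like_spec(seed: int = 0, scale: float = 1.0) -> CommunitySpec:
    """A community approximating the structure of a large mymarid survey:
    2098 specimens across ~45 species, one ~930-specimen species carrying a
    deep (~10.7%) cryptic complex and one mid-sized complex, heavily skewed
    abundances.  ``scale`` shrinks the specimen count proportionally for
    quick runs while keeping the structure."""
    return CommunitySpec(
        n_species=45,
        n_specimens=max(45, int(round(2098 * scale))),
        abundance_model="geometric",
        abundance_skew=0.45,
        intra_divergence_max=0.012,
        inter_divergence_range=(0.045, 0.27),
        cryptic_complexes=((0, 0.107), (2, 0.08)),
        sex_ratio=0.5,
        seed=seed,
    )
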