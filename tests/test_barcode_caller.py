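"""Amplicon pipeline: demultiplexing, trimming, merging, consensus and
pseudogene screening on constructed reads and simulator output."""

import numpy as np
from Bio.Seq import Seq

from fairylit import (
    ConsensusCall,
    FastqRead,
    TagScheme,
    call_barcodes,
    call_consensus,
    demultiplex,
    merge_pairs,
    screen_orf,
    trim,
)
from fairylit.barcode_caller import primer_mismatches
from fairylit.synthetic_data import _random_coding_sequence

SCHEME = TagScheme()
RNG = np.random.default_rng(99)
BARCODE = _random_coding_sequence(316, RNG)


def read(seq, q=36, rid="r"):
    return FastqRead(rid, seq, tuple([q] * len(seq)))


def concrete(primer, rng=None):
    rng = rng or np.random.default_rng(0)
    from fairylit.barcode_caller import IUPAC

    return "".join(
        b if b in "ACGT" else IUPAC[b][rng.integers(len(IUPAC[b]))] for b in primer
    )


def tagged_pair(insert, ftag, rtag, spacer1="AT", spacer2="C", read_len=300):
    r1 = read((spacer1 + ftag + concrete(SCHEME.primer_f) + insert)[:read_len], rid="p/1")
    rc = str(Seq(insert).reverse_complement())
    r2 = read((spacer2 + rtag + concrete(SCHEME.primer_r) + rc)[:read_len], rid="p/2")
    return r1, r2


class TestDemultiplex:
    def test_exact_tag_at_spacer_offset(self):
        pair = tagged_pair(BARCODE, SCHEME.forward_tags[0], SCHEME.reverse_tags[0])
        bins = demultiplex([pair], SCHEME)
        assert (SCHEME.forward_tags[0], SCHEME.reverse_tags[0]) in bins

    def test_one_tag_mismatch_discarded(self):
        tag = SCHEME.forward_tags[0]
        bad = ("T" if tag[0] != "T" else "G") + tag[1:]
        r1 = read("AT" + bad + concrete(SCHEME.primer_f) + BARCODE[:100])
        r2 = tagged_pair(BARCODE, tag, SCHEME.reverse_tags[0])[1]
        bins = demultiplex([(r1, r2)], SCHEME)
        assert list(bins) == [None]

    def test_96_combinations_no_leakage(self):
        pairs = []
        expected = {}
        for i, combo in enumerate(SCHEME.combinations):
            p = tagged_pair(BARCODE, *combo)
            pairs.append(p)
            expected[combo] = p
        bins = demultiplex(pairs, SCHEME)
        assert None not in bins
        assert len(bins) == 96
        for combo, members in bins.items():
            assert members == [expected[combo]]


class TestTrim:
    def test_exact_primer_removed(self):
        r = read(concrete(SCHEME.primer_f) + BARCODE)
        out = trim(r, SCHEME)
        assert out.seq == BARCODE

    def test_low_quality_tail_removed(self):
        seq = BARCODE
        quals = [36] * (len(seq) - 20) + [2] * 20
        out = trim(FastqRead("r", seq, tuple(quals)), SCHEME)
        assert out is not None
        assert len(out.seq) == len(seq) - 20

    def test_short_read_dropped(self):
        out = trim(read(BARCODE[:240]), SCHEME)
        assert out is None

    def test_spacer_tag_primer_prefix_removed(self):
        r = read("ATG" + SCHEME.forward_tags[2] + concrete(SCHEME.primer_f) + BARCODE)
        out = trim(r, SCHEME)
        assert out.seq == BARCODE


class TestMergePairs:
    def test_perfect_overlap_reconstructs_amplicon(self):
        r1 = read(BARCODE[:300], rid="a/1")
        r2 = read(str(Seq(BARCODE[50:]).reverse_complement()), rid="a/2")
        merged = merge_pairs(r1, r2)
        assert merged is not None
        assert merged.seq == BARCODE

    def test_non_overlapping_pair_dropped(self):
        r1 = read(BARCODE[:100])
        r2 = read(str(Seq(_random_coding_sequence(100, np.random.default_rng(5))).reverse_complement()))
        assert merge_pairs(r1, r2) is None

    def test_higher_quality_base_wins_in_overlap(self):
        a = BARCODE[:150]
        b = BARCODE[50:150]
        # plant a disagreement at overlap position: r1 low quality there
        pos = 100  # inside r1, position 50 of the overlap region
        wrong = "A" if a[pos] != "A" else "C"
        r1_seq = a[:pos] + wrong + a[pos + 1 :]
        q1 = [10 if i == pos else 36 for i in range(len(a))]
        r1 = FastqRead("m/1", r1_seq, tuple(q1))
        r2 = read(str(Seq(b).reverse_complement()))
        merged = merge_pairs(r1, r2)
        assert merged.seq[pos] == a[pos]  # r2's high-quality base won


class TestCallConsensus:
    def test_identical_reads_accepted(self):
        calls = call_consensus([read(BARCODE, rid=f"r{i}") for i in range(20)])
        assert len(calls) == 1
        assert calls[0].status == "accepted"
        assert calls[0].depth == 20
        assert calls[0].consensus == BARCODE

    def test_low_coverage_below_ten(self):
        calls = call_consensus([read(BARCODE, rid=f"r{i}") for i in range(8)])
        assert calls[0].status == "low_coverage"
        assert calls[0].depth == 8

    def test_contaminant_forms_second_cluster(self):
        rng = np.random.default_rng(1)
        contaminant = list(BARCODE)
        for pos in rng.choice(len(contaminant), size=32, replace=False):
            contaminant[pos] = "ACGT"[rng.integers(4)]
        contaminant = "".join(contaminant)
        reads = [read(BARCODE, rid=f"t{i}") for i in range(15)] + [
            read(contaminant, rid=f"c{i}") for i in range(6)
        ]
        calls = call_consensus(reads)
        assert len(calls) == 2
        assert calls[0].depth == 15 and calls[0].status == "accepted"
        assert calls[0].consensus == BARCODE
        assert calls[1].status == "ambiguous_multi"

    def test_sequencing_noise_averaged_out(self):
        rng = np.random.default_rng(2)
        reads = []
        for i in range(30):
            s = list(BARCODE)
            for pos in rng.choice(len(s), size=2, replace=False):
                s[pos] = "ACGT"[rng.integers(4)]
            reads.append(read("".join(s), rid=f"n{i}"))
        calls = call_consensus(reads)
        assert calls[0].consensus == BARCODE


class TestScreenOrf:
    def test_clean_barcode_accepted(self):
        call = ConsensusCall(("f", "r"), BARCODE, 20, "accepted")
        assert screen_orf(call).status == "accepted"

    def test_internal_stop_flagged(self):
        s = list(BARCODE)
        s[150:153] = "TAA"  # mid-frame stop (frame 0 is the coding frame)
        # also break the other frames so no alternative frame rescues it
        s[100:103] = "TAA"
        s[200:203] = "TAG"
        call = ConsensusCall(("f", "r"), "".join(s), 20, "accepted")
        out = screen_orf(call)
        assert out.status == "pseudogene"

    def test_frameshift_flagged(self):
        deleted = BARCODE[:100] + BARCODE[101:]  # 1-base deletion, length 315
        call = ConsensusCall(("f", "r"), deleted, 20, "accepted")
        assert screen_orf(call).status == "pseudogene"


class TestEndToEnd:
    def test_simulated_plate_full_recovery(self):
        """Error-free 20x reads over 24 bins: every planted barcode is
        recovered exactly; read conservation holds."""
        from fairylit import CommunitySpec, simulate_community, simulate_reads

        spec = CommunitySpec(
            n_species=8, n_specimens=24, intra_divergence_max=0.01,
            inter_divergence_range=(0.05, 0.25), seed=21,
        )
        aln, _, truth = simulate_community(spec)
        pairs, rt = simulate_reads(aln, truth, depth_model=20, seed=21)
        calls, audit = call_barcodes(pairs)
        assert len(calls) == 24
        bin_to_spec = {v: k for k, v in rt.bin_of.items()}
        for combo, cl in calls.items():
            sid = bin_to_spec[combo]
            assert cl[0].status == "accepted"
            assert cl[0].consensus == rt.barcode_of[sid]
        accounted = sum(a.get("input", 0) for a in audit.values())
        assert accounted == len(pairs)

    def test_pseudogene_and_low_coverage_gates(self):
        from fairylit import CommunitySpec, simulate_community, simulate_reads

        spec = CommunitySpec(
            n_species=6, n_specimens=18, intra_divergence_max=0.01,
            inter_divergence_range=(0.05, 0.25), seed=5,
        )
        aln, _, truth = simulate_community(spec)
        pairs, rt = simulate_reads(
            aln, truth, depth_model=20, pseudogene_rate=0.3, seed=5
        )
        # drop one bin's reads below 10x
        starved = aln.ids[0]
        combo = rt.bin_of[starved]
        kept, count = [], 0
        for r1, r2 in pairs:
            if r1.read_id.startswith(starved + "_"):
                count += 1
                if count > 8:
                    continue
            kept.append((r1, r2))
        calls, _ = call_barcodes(kept)
        bin_to_spec = {v: k for k, v in rt.bin_of.items()}
        for bin_combo, cl in calls.items():
            sid = bin_to_spec[bin_combo]
            if sid == starved and sid not in rt.pseudogene:
                assert cl[0].status == "low_coverage"
            elif sid in rt.pseudogene:
                assert cl[0].status == "pseudogene"
            else:
                assert cl[0].status == "accepted"


def test_primer_mismatch_counting_degenerate():
    assert primer_mismatches("ACWGG", "ACTGG") == 0  # W matches A/T
    assert primer_mismatches("ACWGG", "ACCGG") == 1  # W does not match C
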