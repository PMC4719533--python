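"""Six-frame ORF scanning and SNP placement."""

import io
import re

import numpy as np
import pytest

from poolvar.alignment_io import QualSequence
from poolvar.caller import VariantCall
from poolvar.errors import PoolvarError
from poolvar.orfs import (
    FRAME_ORDER,
    STOP_CODONS,
    find_orfs,
    place_snps,
    reverse_complement,
    write_orf_fasta,
)


def brute_force_orfs(seq, min_len, mode="stop-to-stop"):
    """Codon-by-codon scan of all six frames, independent of the scanner."""
    seq = seq.upper()
    n = len(seq)
    out = []
    for frame in FRAME_ORDER:
        s = seq if frame > 0 else reverse_complement(seq)
        off = abs(frame) - 1
        codons = [s[p:p + 3] for p in range(off, n - 2, 3)]
        run = []
        for idx, codon in enumerate(codons + ["TAA"]):
            if codon in STOP_CODONS:
                if run:
                    start = off + 3 * run[0]
                    end = off + 3 * (run[-1] + 1)
                    if mode == "atg-to-stop":
                        atgs = [i for i in run if codons[i] == "ATG"]
                        start = off + 3 * atgs[0] if atgs else None
                    if start is not None and end - start >= min_len:
                        if frame > 0:
                            out.append((frame, start, end))
                        else:
                            out.append((frame, n - end, n - start))
                run = []
            else:
                run.append(idx)
    return sorted(out)


class TestFindOrfs:
    def test_hand_translated_example(self):
        assert sorted(find_orfs("ATGAAATAA", min_len=6)) == brute_force_orfs(
            "ATGAAATAA", 6
        )
        assert (1, 0, 6) in find_orfs("ATGAAATAA", min_len=6)

    def test_stop_free_frame_is_one_orf(self):
        seq = "AAA" * 40  # no stops anywhere
        orfs = [o for o in find_orfs(seq, min_len=30) if o[0] == 1]
        assert orfs == [(1, 0, 120)]

    def test_invalid_min_len_rejected(self):
        with pytest.raises(PoolvarError):
            find_orfs("ATGAAATAA", min_len=5)

    @pytest.mark.parametrize("mode", ["stop-to-stop", "atg-to-stop"])
    def test_matches_brute_force_scan(self, mode):
        rng = np.random.default_rng(5)
        for _ in range(60):
            n = int(rng.integers(300, 901))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            got = sorted(find_orfs(seq, min_len=90, mode=mode))
            assert got == brute_force_orfs(seq, 90, mode)

    def test_reported_orfs_are_stop_free(self):
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGT"), size=600))
        for frame, s, e in find_orfs(seq, min_len=90):
            sub = seq[s:e] if frame > 0 else reverse_complement(seq[s:e])
            codons = {sub[i:i + 3] for i in range(0, len(sub), 3)}
            assert not codons & STOP_CODONS

    def test_strand_symmetry(self):
        """Reverse-complementing maps frame +k ORFs to -k with mirrored
        coordinates."""
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        fwd = set(find_orfs(seq, min_len=90))
        rev = set(find_orfs(reverse_complement(seq), min_len=90))
        n = len(seq)
        mirrored = {(-f, n - e, n - s) for f, s, e in rev}
        assert fwd == mirrored


def _call(contig, pos, major="A", minor="T"):
    return VariantCall(contig, pos, major, minor, 14, 6, 75.0, 72.0, 20)


def _contig(cid, seq):
    return QualSequence(cid, seq, [40] * len(seq))


class TestPlaceSnps:
    def test_offset_arithmetic_consistent(self):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), size=600))
        contig = _contig("c1", seq)
        anns, no_orf = place_snps(
            [_call("c1", p, major=seq[p]) for p in (100, 300, 500)],
            [contig], min_len=30,
        )
        for a in anns:
            length = a.orf_end - a.orf_start
            assert a.left_flank + a.right_flank + 1 == length
            assert a.codon_position == a.snp_offset % 3 + 1
            assert a.orf_start <= a.call.position < a.orf_end
            assert len(a.orf_seq) == length

    def test_snp_without_orf_goes_to_no_orf_list(self):
        # stop codons land in every frame of both strands: no ORF anywhere
        seq = "ATTAATTAACTA" * 25
        assert find_orfs(seq, min_len=90) == []
        anns, no_orf = place_snps([_call("c1", 100, major="A", minor="G")],
                                  [_contig("c1", seq)], min_len=90)
        assert anns == [] and len(no_orf) == 1

    def test_longer_orf_wins(self):
        # frame +1 stop-free across the whole sequence; frame +2 broken up
        seq = "AAA" * 100
        anns, _ = place_snps([_call("c1", 150, major="A")],
                             [_contig("c1", seq)], min_len=30)
        (a,) = anns
        best_len = max(
            e - s for f, s, e in find_orfs(seq, min_len=30)
            if s <= 150 < e
        )
        assert a.orf_end - a.orf_start == best_len

    def test_major_allele_substituted(self):
        # the contig consensus carries the minor base; placement should
        # scan with the major allele instead
        seq = "ATG" + "AAA" * 30 + "TAA"
        contig = _contig("c1", seq)
        anns, _ = place_snps([_call("c1", 10, major="C", minor=seq[10])],
                             [contig], min_len=30)
        (a,) = anns
        expected = "C" if a.frame > 0 else "G"  # complement on - strand
        assert a.orf_seq[a.snp_offset] == expected


class TestWriteOrfFasta:
    def test_title_convention_and_round_trip(self):
        seq = "AAA" * 40
        contig = _contig("c1", seq)
        anns, _ = place_snps(
            [_call("c1", 10, major="A"), _call("c1", 50, major="A")],
            [contig], min_len=30,
        )
        buf = io.StringIO()
        write_orf_fasta(anns, buf)
        titles = re.findall(r">(\S+) frame:([+-]\d) SNP:(\d+):(\w)/(\w)",
                            buf.getvalue())
        assert len(titles) == len(anns)
        for (name, frame, off1, major, minor), a in zip(titles, anns):
            assert name.startswith("c1_ORF")
            assert int(frame) == a.frame
            assert int(off1) == a.snp_offset + 1
            assert (major, minor) == (a.call.major_base, a.call.minor_base)

    def test_empty_annotation_list(self):
        buf = io.StringIO()
        write_orf_fasta([], buf)
        assert buf.getvalue() == ""
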