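"""Sequence model, motif scanning, type IIS cut geometry, digestion."""

import numpy as np
import pytest

from ggclone.dna import (
    BSAI,
    SWAI,
    Annotation,
    NucleotideSequence,
    digest,
    ligate,
    revcomp,
    reverse_complement,
    scan_sites,
    translate,
)
from ggclone.errors import EntangledCutError, FrameError, ValidationError

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def naive_revcomp(s):
    return "".join(COMP[b] for b in reversed(s))


def random_bases(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestReverseComplement:
    def test_palindrome_is_fixed_point(self):
        assert revcomp("ATTTAAAT") == "ATTTAAAT"

    def test_involution(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = random_bases(rng, int(rng.integers(1, 200)))
            assert revcomp(revcomp(s)) == s

    def test_matches_naive_oracle_on_1kb(self):
        s = random_bases(np.random.default_rng(1), 1000)
        assert revcomp(s) == naive_revcomp(s)

    def test_rejects_non_acgt_with_position(self):
        with pytest.raises(ValidationError, match="position 2"):
            reverse_complement(NucleotideSequence("AANT"))

    def test_preserves_topology_and_mirrors_annotations(self):
        seq = NucleotideSequence("ACGTACGT", "circular", [Annotation("x", 1, 3)])
        rc = reverse_complement(seq)
        assert rc.is_circular
        (a,) = rc.annotations
        assert (a.start, a.end, a.strand) == (5, 7, -1)


class TestScanSites:
    def test_empty_sequence(self):
        assert scan_sites(NucleotideSequence(""), BSAI) == []

    def test_finds_both_strands(self):
        seq = NucleotideSequence("AAGGTCTCAAA" + "TTGAGACCTT")
        sites = scan_sites(seq, BSAI)
        assert [(s.position, s.strand) for s in sites] == [(2, 1), (13, -1)]

    def test_plus_strand_cut_geometry(self):
        # GGTCTC N1 + 4-nt 5' overhang: recognition at 2 -> cuts at 9/13
        seq = NucleotideSequence("AAGGTCTCA" + "TTTT" + "CCCC")
        (s,) = scan_sites(seq, BSAI)
        assert (s.top_cut, s.bottom_cut) == (9, 13)
        assert seq.bases[s.top_cut : s.bottom_cut] == "TTTT"

    def test_minus_strand_cut_geometry_mirrored(self):
        seq = NucleotideSequence("CCCC" + "TTTT" + "A" + "GAGACC" + "AA")
        (s,) = scan_sites(seq, BSAI)
        assert s.strand == -1
        assert (s.top_cut, s.bottom_cut) == (4, 8)
        assert seq.bases[s.top_cut : s.bottom_cut] == "TTTT"

    def test_circular_origin_spanning_site(self):
        # recognition split across the origin: ...GGT | CTC...
        bases = "CTC" + "A" * 30 + "GGT"
        circ = NucleotideSequence(bases, "circular")
        sites = scan_sites(circ, BSAI)
        assert len(sites) == 1 and sites[0].position == 33 and sites[0].strand == 1
        assert scan_sites(NucleotideSequence(bases, "linear"), BSAI) == []

    def test_matches_naive_sliding_window_oracle(self):
        rng = np.random.default_rng(2)
        s = random_bases(rng, 10_000)
        seq = NucleotideSequence(s)
        for enzyme in (BSAI, SWAI):
            got = {(c.position, c.strand) for c in scan_sites(seq, enzyme)}
            k = len(enzyme.recognition)
            fwd = {(i, 1) for i in range(len(s) - k + 1) if s[i : i + k] == enzyme.recognition}
            rev = {
                (i, -1)
                for i in range(len(s) - k + 1)
                if naive_revcomp(s[i : i + k]) == enzyme.recognition
            }
            if enzyme.is_palindromic:
                rev = set()  # palindromes reported once, plus strand
            assert got == fwd | rev

    def test_rotation_invariance_up_to_shift(self):
        rng = np.random.default_rng(3)
        bases = random_bases(rng, 300) + "GGTCTC" + random_bases(rng, 300)
        circ = NucleotideSequence(bases, "circular")
        base_positions = {s.position for s in scan_sites(circ, BSAI)}
        n = len(bases)
        for off in rng.integers(0, n, size=10):
            rotated = circ.rotated(int(off))
            got = {(s.position + int(off)) % n for s in scan_sites(rotated, BSAI)}
            assert got == base_positions


class TestDigest:
    def test_uncut_circle_returned_intact(self):
        circ = NucleotideSequence("ACGT" * 20, "circular")
        (frag,) = digest(circ, BSAI)
        assert frag.uncut and frag.core.bases == circ.bases

    def test_two_inward_sites_release_expected_overhangs(self):
        # hand-built donor-style circle: recognitions stay on the vector
        insert = "CATCATCATCATCATCAT"
        bases = (
            "GGTCTC" + "A" + "AATG" + insert + "GCTT" + "T" + "GAGACC" + "GCCACCGCAATT"
        )
        circ = NucleotideSequence(bases, "circular")
        frags = digest(circ, BSAI)
        assert len(frags) == 2
        by_left = {f.left_overhang: f for f in frags}
        part = by_left["AATG"]
        assert part.right_overhang == "GCTT"
        assert part.core.bases == "AATG" + insert + "GCTT"
        vector = by_left["GCTT"]
        assert vector.right_overhang == "AATG"
        assert "GGTCTC" in vector.core.bases and "GAGACC" in vector.core.bases

    def test_blunt_enzyme_gives_empty_overhangs(self):
        seq = NucleotideSequence("CCC" + "ATTTAAAT" + "GGG")
        frags = digest(seq, SWAI)
        assert len(frags) == 2
        assert all(f.left_overhang == "" and f.right_overhang == "" for f in frags)
        assert frags[0].core.bases == "CCCATTT" and frags[1].core.bases == "AAATGGG"

    def test_linear_n_sites_yield_n_plus_one_fragments(self):
        seq = NucleotideSequence("AA" + "ATTTAAAT" + "CC" + "ATTTAAAT" + "GG")
        assert len(digest(seq, SWAI)) == 3

    def test_roundtrip_reconstructs_parent(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            chunks = []
            n_sites = int(rng.integers(2, 5))
            for _ in range(n_sites):
                filler = random_bases(rng, int(rng.integers(30, 80)))
                chunks.append("GGTCTC" + "A" + random_bases(rng, 4) + filler)
            parent = NucleotideSequence("".join(chunks), "circular")
            try:
                frags = digest(parent, BSAI)
            except EntangledCutError:
                continue  # random filler planted an overlapping site
            if len(frags) != n_sites:
                continue  # random filler created extra sites; skip
            rebuilt = ligate(frags, circular=True)
            # same circle up to rotation
            assert len(rebuilt.bases) == len(parent.bases)
            assert rebuilt.bases in parent.bases + parent.bases

    def test_base_conservation(self, registry):
        bb = registry.backbones["pGGYL1"].sequence
        frags = digest(bb, BSAI)
        total = sum(len(f.core.bases) - len(f.left_overhang) for f in frags)
        assert total == len(bb.bases)

    def test_entangled_cut_windows_raise(self):
        # opposing sites whose 4-nt windows overlap: + window [7,11),
        # - window [5,9)
        seq = NucleotideSequence("GGTCTC" + "AAAA" + "GAGACC" + "TT", "linear")
        with pytest.raises(EntangledCutError):
            digest(seq, BSAI)

    def test_cut_pair_is_religatable(self):
        seq = NucleotideSequence("CC" + "GGTCTC" + "A" + "TGCA" + "TTTTTT")
        left, right = digest(seq, BSAI)
        assert left.right_overhang == right.left_overhang
        assert ligate([left, right], circular=False).bases == seq.bases


class TestTranslate:
    def test_standard_code_examples(self):
        assert translate("ATGGGT") == "MG"
        assert translate("TAA") == "*"

    def test_frame_error(self):
        with pytest.raises(FrameError):
            translate("ATGG")

    def test_matches_codon_table_oracle(self):
        # independent oracle: the standard code as the canonical 64-char
        # amino-acid string in TCAG codon order
        aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
        order = {b: i for i, b in enumerate("TCAG")}

        def lookup(codon):
            return aas[16 * order[codon[0]] + 4 * order[codon[1]] + order[codon[2]]]

        rng = np.random.default_rng(5)
        s = random_bases(rng, 300)
        expected = "".join(lookup(s[i : i + 3]) for i in range(0, 300, 3))
        assert translate(s) == expected
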