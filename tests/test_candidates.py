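import numpy as np
import pytest

from guideset.candidates import (
    BindingSite,
    CandidateSgRNA,
    PamPattern,
    build_binding_map,
    enumerate_candidates,
    filter_excluded,
    find_pam_sites,
    iupac_match,
)
from guideset.genome_io import reverse_complement

from .conftest import random_seq
from .oracles import hamming, naive_binding_map, naive_candidates, naive_pam_sites

NGG = PamPattern("NGG")


class TestIupacMatch:
    @pytest.mark.parametrize(
        "code,base,expected",
        [
            ("N", "A", True), ("N", "T", True), ("G", "G", True),
            ("G", "A", False), ("R", "A", True), ("R", "C", False),
            ("N", "N", False),  # genomic N never matches, even pattern N
            ("A", "N", False),
        ],
    )
    def test_semantics(self, code, base, expected):
        assert iupac_match(code, base) is expected

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError):
            iupac_match("X", "A")
        with pytest.raises(ValueError):
            PamPattern("NGX")


class TestFindPamSites:
    def test_too_short_sequence_yields_nothing(self):
        assert find_pam_sites("ACG", NGG, 2) == []

    def test_both_strand_layouts(self):
        # forward site at 2 (spacer TA, PAM AGG); reverse at 7 (CCT = rc AGG)
        sites = find_pam_sites("TTTAAGGCCTTT", NGG, 2)
        assert sites == [(2, "+"), (7, "-")]

    @pytest.mark.parametrize("pam", ["NGG", "NG", "TTTN"])
    @pytest.mark.parametrize("spacer_len", [4, 20])
    def test_matches_naive_scanner(self, rng, pam, spacer_len):
        for _ in range(20):
            seq = random_seq(rng, int(rng.integers(30, 400)))
            got = find_pam_sites(seq, PamPattern(pam), spacer_len)
            assert got == naive_pam_sites(seq, pam, spacer_len)

    def test_strand_symmetry(self, rng):
        """Enumerating revcomp(seq) mirrors the enumeration of seq."""
        pam, L = PamPattern("NGG"), 6
        for _ in range(20):
            seq = random_seq(rng, 200)
            fwd = set(find_pam_sites(seq, pam, L))
            rc = find_pam_sites(reverse_complement(seq), pam, L)
            site_len = L + len(pam)
            mirrored = {
                (len(seq) - (pos + site_len), "-" if strand == "+" else "+")
                for pos, strand in rc
            }
            assert fwd == mirrored

    def test_n_disqualifies_pam(self):
        assert find_pam_sites("AANGG", NGG, 2) == []


class TestEnumerateCandidates:
    def test_identical_spacers_group(self):
        unit = "GATTACAGATTACAGATTAC" + "TGG"
        seq = ("C" * 30).join([unit, unit, unit])
        cands = enumerate_candidates(seq, NGG, 20)
        by = {c.spacer: c for c in cands}
        assert len(by["GATTACAGATTACAGATTAC"].exact_loci) == 3

    def test_all_n_sequence_yields_nothing(self):
        assert enumerate_candidates("N" * 100, NGG, 20) == []

    def test_distinct_spacer_count_matches_naive(self, rng):
        for _ in range(10):
            seq = random_seq(rng, 2000)
            cands = enumerate_candidates(seq, NGG, 20)
            naive = naive_candidates(seq, "NGG", 20)
            assert {c.spacer for c in cands} == set(naive)
            for c in cands:
                assert sorted(c.exact_loci) == sorted(naive[c.spacer])


class TestFilterExcluded:
    def _cands(self, *spacers):
        return [CandidateSgRNA(s, [(0, "+")]) for s in spacers]

    def test_removes_u6_terminator_spacers(self):
        cands = self._cands("GTTTTACCGGTACGTACGTA", "GATTACAGATTACAGATTAC")
        kept = filter_excluded(cands, ["TTTT"])
        assert [c.spacer for c in kept] == ["GATTACAGATTACAGATTAC"]

    def test_case_study_exclusions(self):
        cands = self._cands(
            "CCAAAACCGGTACGTACGTA",  # AAAA
            "GTTTTACCGGTACGTACGTA",  # TTTT
            "GATTACAGATTACAGATTAC",
        )
        kept = filter_excluded(cands, ["AAAA", "TTTT"])
        assert [c.spacer for c in kept] == ["GATTACAGATTACAGATTAC"]

    def test_empty_exclusion_is_identity_and_idempotent(self):
        cands = self._cands("GTTTTACCGGTACGTACGTA", "GATTACAGATTACAGATTAC")
        assert filter_excluded(cands, []) == cands
        once = filter_excluded(cands, ["TTTT"])
        assert filter_excluded(once, ["TTTT"]) == once

    def test_exclusions_load_from_plain_or_yaml_file(self, tmp_path):
        from guideset.candidates import load_excluded

        plain = tmp_path / "exclude.txt"
        plain.write_text("# U6 terminator\nTTTT\naaaa\n")
        assert load_excluded(plain) == ["TTTT", "AAAA"]
        yml = tmp_path / "exclude.yaml"
        yml.write_text("[TTTT, AAAA]\n")
        assert load_excluded(yml) == ["TTTT", "AAAA"]


class TestBuildBindingMap:
    def test_zero_mismatch_map_equals_exact_loci(self, rng):
        seq = random_seq(rng, 1500)
        cands = enumerate_candidates(seq, NGG, 20)
        bmap = build_binding_map(cands, seq, NGG, 0)
        for c in cands:
            got = sorted((s.start, s.strand) for s in bmap[c.spacer])
            assert got == sorted(c.exact_loci)
            assert all(s.mismatches == 0 for s in bmap[c.spacer])

    def test_planted_two_mismatch_site_found(self):
        proto = "GATTACAGATTACAGATTAC"
        variant = "GATCACAGATTACAGATTAG"  # differs at positions 3 and 19
        assert hamming(proto, variant) == 2
        seq = proto + "TGG" + "C" * 40 + variant + "AGG"
        cands = enumerate_candidates(seq, NGG, 20)
        bmap = build_binding_map(cands, seq, NGG, 3)
        sites = {s.start: s for s in bmap[proto]}
        assert sites[63].mismatches == 2

    def test_full_map_matches_naive_all_pairs(self, rng):
        for _ in range(5):
            seq = random_seq(rng, 800)
            cands = enumerate_candidates(seq, NGG, 20)
            bmap = build_binding_map(cands, seq, NGG, 3)
            naive = naive_binding_map([c.spacer for c in cands], seq, "NGG", 3, 20)
            for c in cands:
                got = sorted((s.start, s.strand, s.mismatches) for s in bmap[c.spacer])
                assert got == sorted(naive[c.spacer])

    def test_recorded_mismatches_equal_recomputed_hamming(self, rng):
        seq = random_seq(rng, 1000)
        cands = enumerate_candidates(seq, NGG, 20)
        bmap = build_binding_map(cands, seq, NGG, 2)
        for spacer, sites in bmap.items():
            for s in sites:
                assert s.mismatches == hamming(spacer, s.spacer_seq)
                assert PamPattern("NGG").matches(s.pam_seq)

    def test_offset_shifts_coordinates(self):
        seq = "GATTACAGATTACAGATTAC" + "TGG"
        cands = enumerate_candidates(seq, NGG, 20)
        bmap = build_binding_map(cands, seq, NGG, 0, chrom="chr9", offset=100)
        (site,) = bmap["GATTACAGATTACAGATTAC"]
        assert (site.chrom, site.start) == ("chr9", 100)
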