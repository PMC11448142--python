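"""Binding engine: IUPAC semantics, reverse complement, and the
qualification rules (match length, mismatch cap, 3'-anchor), all checked
against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ampliscope.binding import (
    BindingSite,
    SearchParams,
    base_compatible,
    best_site,
    find_binding_sites,
    min_mismatch,
    reverse_complement,
)
from ampliscope.refdb import Primer

from _oracles import IUPAC, brute_force_sites, compat, revcomp
from conftest import random_dna, random_iupac

CODES = sorted(IUPAC)


def test_base_compatible_matches_set_intersection_exhaustively():
    for a in CODES:
        for b in CODES:
            assert base_compatible(a, b) == compat(a, b), (a, b)


def test_base_compatible_rejects_non_iupac():
    with pytest.raises(ValueError, match="X"):
        base_compatible("X", "A")


@pytest.mark.parametrize(
    "seq,expected", [("ACGT", "ACGT"), ("RRN", "NYY"), ("", "")]
)
def test_reverse_complement_examples(seq, expected):
    assert reverse_complement(seq) == expected


@given(st.text(alphabet=CODES, min_size=0, max_size=80))
@settings(max_examples=200, derandomize=True)
def test_reverse_complement_is_an_involution(seq):
    assert reverse_complement(reverse_complement(seq)) == seq
    assert len(reverse_complement(seq)) == len(seq)


def test_reverse_complement_rejects_non_iupac():
    with pytest.raises(ValueError, match="position 2"):
        reverse_complement("AC-GT")


def test_exact_forward_site():
    primer = "TTGACGCATGCATCCA"  # no internal repeat structure
    template = "G" * 40 + primer + "C" * 40
    sites = find_binding_sites(primer, template)
    assert len(sites) == 1
    s = sites[0]
    assert (s.start, s.end, s.mm_count, s.aligned_len) == (40, 56, 0, 16)
    assert s.three_prime_intact and s.strand == "+"


def test_three_prime_mismatch_suppresses_site():
    primer = "TTGACGCATGCATCCA"
    # alter the template base under the primer's terminal 3' position
    template = "G" * 40 + primer[:-1] + "G" + "C" * 40
    assert find_binding_sites(primer, template) == []
    # an internal mismatch with the same count is still reported
    template2 = "G" * 40 + primer[:5] + "A" + primer[6:] + "C" * 40
    sites = find_binding_sites(primer, template2)
    assert len(sites) == 1 and sites[0].mm_count == 1
    # 0-based 5' index 5 in a 16-mer is position 16 - 5 = 11 from the 3' end
    assert sites[0].mm_positions == (11,)


def test_reverse_primer_site_reported_in_sense_coordinates():
    p = Primer("rev", "TTGACGCATGCATCCA", "reverse")
    template = "G" * 30 + reverse_complement(p.sequence) + "C" * 20
    sites = find_binding_sites(p, template)
    assert len(sites) == 1
    s = sites[0]
    assert (s.start, s.end, s.strand, s.mm_count) == (30, 46, "-", 0)


def test_mm_positions_are_3prime_indexed_for_reverse_primers():
    p = Primer("rev", "TTGACGCATGCATCCA", "reverse")
    site = list(reverse_complement(p.sequence))
    # primer position 5 from the 3' end sits at revcomp index 4
    site[4] = "A" if site[4] != "A" else "G"
    template = "G" * 30 + "".join(site) + "C" * 20
    sites = find_binding_sites(p, template)
    assert len(sites) == 1
    assert sites[0].mm_positions == (5,)


def _engine_tuples(sites):
    return sorted(
        (s.start, s.end, s.aligned_len, s.mm_count, s.mm_positions) for s in sites
    )


@pytest.mark.parametrize("orientation", ["forward", "reverse"])
def test_engine_equals_brute_force_on_random_instances(orientation):
    rng = np.random.default_rng(42 if orientation == "forward" else 43)
    params = SearchParams()
    for _ in range(300):
        primer_seq = random_iupac(rng, int(rng.integers(12, 22)))
        template = random_dna(rng, int(rng.integers(20, 120)))
        primer = Primer("p", primer_seq, orientation)
        got = _engine_tuples(find_binding_sites(primer, template, params))
        exp = brute_force_sites(primer_seq, orientation, template)
        assert got == exp, (primer_seq, orientation, template)


def test_engine_equals_brute_force_without_overhang():
    rng = np.random.default_rng(7)
    params = SearchParams(allow_5prime_overhang=False, min_match_len=8, max_mm=4)
    for _ in range(150):
        primer_seq = random_iupac(rng, 12)
        template = random_dna(rng, int(rng.integers(8, 40)))
        got = _engine_tuples(find_binding_sites(primer_seq, template, params))
        exp = brute_force_sites(
            primer_seq, "forward", template, min_match=8, max_mm=4,
            allow_overhang=False,
        )
        assert got == exp


def test_overhang_positions_neither_match_nor_mismatch():
    primer = "AAAATTGACGCATGCATCCA"  # 20 nt, 4-nt 5' extension
    template = "TTGACGCATGCATCCA" + "C" * 30
    sites = find_binding_sites(primer, template, SearchParams(min_match_len=16))
    assert len(sites) == 1
    s = sites[0]
    assert (s.start, s.aligned_len, s.mm_count) == (0, 16, 0)


def test_strand_symmetry():
    """Sites of a forward primer on seq mirror the sites of the same primer
    declared reverse on revcomp(seq)."""
    rng = np.random.default_rng(11)
    for _ in range(50):
        pseq = random_iupac(rng, 15)
        template = random_dna(rng, 80)
        fwd = find_binding_sites(Primer("p", pseq, "forward"), template)
        rev = find_binding_sites(Primer("p", pseq, "reverse"), revcomp(template))
        L = len(template)
        mirrored = sorted(
            (L - s.end, L - s.start, s.aligned_len, s.mm_count, s.mm_positions)
            for s in rev
        )
        assert _engine_tuples(fwd) == mirrored


def test_qualifying_sites_monotone_in_max_mm():
    rng = np.random.default_rng(5)
    for _ in range(40):
        pseq = random_iupac(rng, 14)
        template = random_dna(rng, 100)
        prev: set = set()
        for mm in range(0, 5):
            cur = set(_engine_tuples(
                find_binding_sites(pseq, template, SearchParams(max_mm=mm))
            ))
            assert prev <= cur
            prev = cur


def test_sites_sorted_and_deterministic():
    rng = np.random.default_rng(3)
    pseq = random_iupac(rng, 12)
    template = random_dna(rng, 500)
    params = SearchParams(max_mm=4, min_match_len=8)
    a = find_binding_sites(pseq, template, params)
    b = find_binding_sites(pseq, template, params)
    assert a == b
    assert [s.start for s in a] == sorted(s.start for s in a)


def test_max_sites_per_template_caps_output():
    template = "ACGTACGTACGT" * 10
    params = SearchParams(max_mm=0, max_sites_per_template=3)
    sites = find_binding_sites("ACGTACGTACGT", template, params)
    assert len(sites) == 3


def test_primer_longer_than_template_returns_empty_not_error():
    assert find_binding_sites("ACGTACGTACGTACGT", "ACGT") == []


def test_best_site_prefers_fewest_mismatches_then_longest_then_leftmost():
    def mk(start, alen, mm):
        return BindingSite("r", "p", "+", start, start + alen, alen, mm,
                           tuple(range(3, 3 + mm)), True)

    sites = [mk(10, 15, 2), mk(50, 15, 0), mk(5, 15, 1)]
    assert best_site(sites).mm_count == 0
    assert best_site([]) is None
    # random lists equal the argmin oracle
    rng = np.random.default_rng(9)
    for _ in range(100):
        sites = [
            mk(int(rng.integers(0, 50)), int(rng.integers(11, 20)), int(rng.integers(0, 4)))
            for _ in range(int(rng.integers(1, 8)))
        ]
        expected = min(sites, key=lambda s: (s.mm_count, -s.aligned_len, s.start))
        assert best_site(sites) == expected


def test_min_mismatch_values(planted_db, panel):
    primers, _ = panel
    db, truth, _ = planted_db
    # a sequence with a planted 2-MM site reports exactly 2
    for rid, sites in truth.sites.items():
        for site in sites:
            if site["primer"] == "mixA_377F" and site["mm_count"] == 2:
                rec = db.get(rid)
                assert min_mismatch(primers["mixA_377F"], rec) == 2
                return
    raise AssertionError("no 2-MM plant found in fixture")


def test_min_mismatch_none_when_no_site():
    assert min_mismatch("TTGACGCATGCATCCA", "A" * 100) is None


def test_search_params_validation():
    with pytest.raises(ValueError):
        SearchParams(min_match_len=1, min_3prime_consecutive=2)
    with pytest.raises(ValueError):
        SearchParams(max_mm=-1)
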