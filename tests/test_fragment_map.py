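"""Digestion, fragment-map construction and mappability annotation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fourc.fragment_map import (
    IUPAC_CODES,
    ChromFragments,
    EnzymeConfigError,
    EnzymeSpec,
    FragmentMap,
    LibraryDesign,
    annotate_mappability,
    build_fragment_map,
    digest,
    read_fragments_tsv,
    write_fragments_tsv,
)

HINDIII = EnzymeSpec("HindIII", "AAGCTT", 1)
NLAIII = EnzymeSpec("NlaIII", "CATG", 4)


def naive_digest(seq: str, enzyme: EnzymeSpec) -> list[int]:
    """Position-by-position IUPAC matcher: the independent digestion oracle."""
    from fourc.fragment_map import _reverse_complement

    seq = seq.upper()
    sites = [(enzyme.recognition, enzyme.cut_offset)]
    if not enzyme.is_palindromic:
        sites.append(
            (_reverse_complement(enzyme.recognition),
             len(enzyme.recognition) - enzyme.cut_offset)
        )
    hits = set()
    for site, offset in sites:
        k = len(site)
        for i in range(len(seq) - k + 1):
            if all(seq[i + j] in IUPAC_CODES[site[j]] for j in range(k)):
                hits.add(i + offset)
    return sorted(hits)


class TestDigest:
    @pytest.mark.parametrize(
        "seq,enzyme,expected",
        [
            ("GGAAGCTTCCAAGCTTGG", HINDIII, [3, 11]),
            ("GGGGGGGG", HINDIII, []),
            ("AACATGTT", NLAIII, [6]),
        ],
    )
    def test_known_cut_positions(self, seq, enzyme, expected):
        assert digest(seq, enzyme) == expected

    def test_overlapping_sites_all_reported(self):
        # CATGCATG: CATG at 0 and 4 -> cuts at 4 and 8
        assert digest("CATGCATG", NLAIII) == [4, 8]

    def test_n_bases_never_match(self):
        assert digest("AANATGTT", NLAIII) == []
        assert digest("N" * 50, EnzymeSpec("anyN", "NNNN", 2)) == []

    def test_degenerate_site_honored(self):
        # ApoI R^AATTY matches both AAATTC and GAATTT
        apoi = EnzymeSpec("ApoI", "RAATTY", 1)
        assert digest("AAATTC", apoi) == [1]
        assert digest("GAATTT", apoi) == [1]
        assert digest("CAATTC", apoi) == []

    def test_non_palindromic_matched_on_both_strands(self):
        # BspMI ACCTGC (cuts downstream; offset within site for this test)
        enz = EnzymeSpec("asym", "ACCTGC", 2)
        fwd = digest("TTACCTGCTT", enz)
        rc = digest("TTGCAGGTTT", enz)  # reverse complement context
        assert fwd == [4]
        assert rc == naive_digest("TTGCAGGTTT", enz)
        assert rc  # the bottom-strand site is found

    def test_invalid_iupac_rejected(self):
        with pytest.raises(EnzymeConfigError):
            EnzymeSpec("bad", "AXGCTT", 1)
        with pytest.raises(EnzymeConfigError):
            EnzymeSpec("short", "ACG", 1)
        with pytest.raises(EnzymeConfigError):
            EnzymeSpec("offset", "AAGCTT", 7)

    def test_agrees_with_naive_matcher_on_random_sequences(self):
        """Digestion oracle: exact agreement on 1000 random 1-kb sequences."""
        rng = np.random.default_rng(7)
        enzymes = [HINDIII, NLAIII, EnzymeSpec("ApoI", "RAATTY", 1),
                   EnzymeSpec("asym", "ACCTGC", 4)]
        bases = np.array(list("ACGTN"))
        # mostly ACGT with occasional N runs
        probs = np.array([0.24, 0.24, 0.24, 0.24, 0.04])
        for trial in range(1000):
            seq = "".join(rng.choice(bases, size=1000, p=probs))
            enz = enzymes[trial % len(enzymes)]
            assert digest(seq, enz) == naive_digest(seq, enz)


class TestBuildFragmentMap:
    def test_cut_positions_become_fragment_bounds(self):
        fmap = build_fragment_map({"chr1": "GGAAGCTTCCAAGCTTGG"}, HINDIII)
        cf = fmap.chroms["chr1"]
        assert cf.starts.tolist() == [0, 3, 11]
        assert cf.ends.tolist() == [3, 11, 18]

    def test_no_cuts_single_fragment(self):
        fmap = build_fragment_map({"chr1": "GGGGGGGG"}, HINDIII)
        cf = fmap.chroms["chr1"]
        assert cf.starts.tolist() == [0] and cf.ends.tolist() == [8]

    def test_cut_at_zero_suppresses_empty_leading_fragment(self):
        # NlaIII cut at offset 4 of a site starting at 0 gives cut 4; use an
        # enzyme cutting at offset 0 to create a cut at position 0.
        enz = EnzymeSpec("cut0", "CATG", 0)
        fmap = build_fragment_map({"chr1": "CATGCATG"}, enz)
        cf = fmap.chroms["chr1"]
        # cuts at 0 and 4: the empty leading interval is suppressed
        assert cf.starts.tolist() == [0, 4]
        assert cf.ends.tolist() == [4, 8]

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            build_fragment_map({}, HINDIII)

    def test_tiling_invariant_on_random_genomes(self, rng):
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGT"), size=2000))
            fmap = build_fragment_map({"c": seq}, NLAIII)
            cf = fmap.chroms["c"]
            assert cf.starts[0] == 0
            assert cf.ends[-1] == 2000
            assert np.array_equal(cf.ends[:-1], cf.starts[1:])
            assert int((cf.ends - cf.starts).sum()) == 2000


def _design(size_min=200, size_max=650, primer=50, min_map=20):
    return LibraryDesign(
        primary_enzyme=HINDIII,
        secondary_enzyme=NLAIII,
        read_length=100,
        primer_length=primer,
        size_min=size_min,
        size_max=size_max,
        min_map_length=min_map,
    )


def _single_fragment_map(length: int) -> FragmentMap:
    m = np.ones(1, dtype=bool)
    fmap = FragmentMap(
        {"c": ChromFragments(np.array([0]), np.array([length]), m, m.copy(), m.copy())}
    )
    fmap.validate()
    return fmap


class TestMappability:
    def test_blind_fragment_unmappable(self):
        # no internal NlaIII site
        fmap = _single_fragment_map(1000)
        ann = annotate_mappability(fmap, {"c": "A" * 1000}, _design())
        assert not ann.chroms["c"].mappable[0]

    def test_end_distance_and_size_selection_rule(self):
        # secondary cut at 300 in a 1000-bp fragment: 5' d=300 -> amplicon
        # 350 in [200, 650] -> capturable; 3' d=700 -> 750 > 650 -> not.
        seq = "A" * 296 + "CATG" + "A" * 700  # NlaIII cut at 296+4 = 300
        fmap = _single_fragment_map(1000)
        ann = annotate_mappability(fmap, {"c": seq}, _design())
        cf = ann.chroms["c"]
        assert bool(cf.end5[0]) and not bool(cf.end3[0])
        assert bool(cf.mappable[0])

    def test_both_ends_below_size_selection(self):
        # cut at 50 from each boundary of a 100-bp fragment: d+primer < 200
        seq = "A" * 46 + "CATG" + "A" * 50
        fmap = _single_fragment_map(100)
        ann = annotate_mappability(fmap, {"c": seq}, _design())
        assert not ann.chroms["c"].mappable[0]

    def test_short_fragments_unmappable(self):
        seq = "CATGCATGCC"
        fmap = _single_fragment_map(10)
        ann = annotate_mappability(fmap, {"c": seq}, _design(min_map=20))
        assert not ann.chroms["c"].mappable[0]

    def test_brute_force_end_enumeration(self, rng):
        """Each end's flag equals a brute-force scan over internal cuts."""
        design = _design()
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=3000))
            fmap = build_fragment_map({"c": seq}, HINDIII)
            ann = annotate_mappability(fmap, {"c": seq}, design)
            cuts = digest(seq, NLAIII)
            cf = ann.chroms["c"]
            for i in range(cf.n):
                s, e = int(cf.starts[i]), int(cf.ends[i])
                internal = [c for c in cuts if s < c < e]
                if not internal or e - s < design.min_map_length:
                    exp5 = exp3 = False
                else:
                    d5, d3 = internal[0] - s, e - internal[-1]
                    exp5 = (d5 >= design.min_map_length
                            and design.size_min <= d5 + design.primer_length <= design.size_max)
                    exp3 = (d3 >= design.min_map_length
                            and design.size_min <= d3 + design.primer_length <= design.size_max)
                assert bool(cf.end5[i]) == exp5 and bool(cf.end3[i]) == exp3
                assert bool(cf.mappable[i]) == (exp5 or exp3)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        size_min=st.integers(50, 400),
        widen_lo=st.integers(0, 49),
        widen_hi=st.integers(0, 400),
        seed=st.integers(0, 10_000),
    )
    def test_widening_size_selection_is_monotone(self, size_min, widen_lo, widen_hi, seed):
        """Widening [size_min, size_max] never makes a mappable fragment unmappable."""
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=1500))
        fmap = build_fragment_map({"c": seq}, HINDIII)
        size_max = size_min + 200
        narrow = annotate_mappability(fmap, {"c": seq}, _design(size_min, size_max))
        wide = annotate_mappability(
            fmap, {"c": seq}, _design(size_min - widen_lo, size_max + widen_hi)
        )
        lost = narrow.chroms["c"].mappable & ~wide.chroms["c"].mappable
        assert not lost.any()


def test_fragment_tsv_round_trip(tmp_path, rng):
    seq = "".join(rng.choice(list("ACGT"), size=3000))
    fmap = build_fragment_map({"c": seq}, HINDIII)
    ann = annotate_mappability(fmap, {"c": seq}, _design())
    path = tmp_path / "frags.tsv"
    write_fragments_tsv(ann, path)
    back = read_fragments_tsv(path)
    for chrom in ann.chroms:
        a, b = ann.chroms[chrom], back.chroms[chrom]
        assert np.array_equal(a.starts, b.starts)
        assert np.array_equal(a.ends, b.ends)
        assert np.array_equal(a.mappable, b.mappable)
        assert np.array_equal(a.end5, b.end5)
        assert np.array_equal(a.end3, b.end3)
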