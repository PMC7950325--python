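"""Cross-link candidate enumeration, precursor/fragment matching, scoring."""
import numpy as np
import pytest

from oxlink.chem import (
    CARBAMIDOMETHYL,
    PROTON,
    CrosslinkedPair,
    Peptide,
    crosslink_mass,
    mz_from_mass,
    peptide_mass,
)
from oxlink.digest import DigestSpec, digest, modified_forms
from oxlink.xlsearch import (
    Ms2Spectrum,
    enumerate_candidates,
    estimate_fdr,
    filter_matches,
    fragment_ions,
    linear_fragment_ions,
    make_decoy_peptides,
    match_precursor,
    score_match,
    search_spectra,
)


def pep(seq, start=1, mods=()):
    return Peptide("P", start, start + len(seq) - 1, seq, mods=tuple(mods))


def cam_all(seq, ):
    return tuple((i + 1, CARBAMIDOMETHYL) for i, r in enumerate(seq) if r == "C")


class TestEnumerateCandidates:
    def test_single_eligible_pair(self):
        cands = enumerate_candidates([pep("AYK"), pep("GWR", start=10)], ["YW"])
        assert len(cands) == 1
        (c,) = cands
        assert {c.alpha.sequence, c.beta.sequence} == {"AYK", "GWR"}

    def test_two_tyrosines_give_two_candidates(self):
        cands = enumerate_candidates([pep("AYYK"), pep("GYR", start=10)], ["YY"])
        links = {(c.link_alpha_pos, c.link_beta_pos) for c in cands}
        assert len(cands) == 2
        assert links == {(2, 2), (3, 2)}

    def test_table_pair_among_fixture_candidates(self, fixture_protein):
        peps = digest(fixture_protein.sequence, DigestSpec(), fixture_protein.protein_id)
        forms = [f for p in peps for f in modified_forms(p, [CARBAMIDOMETHYL], 0)]
        cands = enumerate_candidates(forms, ["YY"])
        seq_pairs = {frozenset((c.alpha.sequence, c.beta.sequence)) for c in cands}
        assert frozenset(("TFYSCTTEGR", "YSFCTDHTVLVQTR")) in seq_pairs

    def test_modified_link_sites_are_excluded(self):
        from oxlink.chem import NITRATION

        nitrated = pep("AYK", mods=((2, NITRATION),))
        assert enumerate_candidates([nitrated, pep("GYR", start=10)], ["YY"]) == []

    def test_brute_force_oracle_equivalence(self):
        """Exhaustive pairing of all digest products of a toy chain
        reproduces the candidate set exactly."""
        seq = "MKAYLRGGWPTKDDYYKAAWRTTK"
        peps = digest(seq, DigestSpec(min_length=3, max_length=30), "T")
        cands = enumerate_candidates(peps, ["YY", "WW", "YW"])
        got = {
            (c.link_type,)
            + tuple(
                sorted(
                    (
                        (c.alpha.start, c.alpha.end, c.link_alpha_pos),
                        (c.beta.start, c.beta.end, c.link_beta_pos),
                    )
                )
            )
            for c in cands
        }
        expected = set()
        rules = {"YY": ("Y", "Y"), "WW": ("W", "W"), "YW": ("Y", "W")}
        for i, a in enumerate(peps):
            for b in peps[i + 1 :]:
                for rule, (ra, rb) in rules.items():
                    for la, ca in enumerate(a.sequence, 1):
                        for lb, cb in enumerate(b.sequence, 1):
                            if a is b and la == lb:
                                continue
                            if {(ca, cb), (cb, ca)} & {(ra, rb)}:
                                key = (rule,) + tuple(
                                    sorted(((a.start, a.end, la), (b.start, b.end, lb)))
                                )
                                if (ca, cb) == (ra, rb) or (ca, cb) == (rb, ra):
                                    expected.add(key)
        assert got == expected


class TestMatchPrecursor:
    def make_pair(self):
        alpha = pep("YSFCTDHTVLVQTR", mods=cam_all("YSFCTDHTVLVQTR"))
        beta = pep("TFYSCTTEGR", start=30, mods=cam_all("TFYSCTTEGR"))
        return CrosslinkedPair(alpha, beta, 1, 3, "YY")

    def test_sub_ppm_match(self):
        pair = self.make_pair()
        mz = mz_from_mass(2944.312, 5)
        (hit,) = match_precursor((mz, 5), [pair], tol_ppm=10)
        assert abs(hit.ppm_error) < 1.0

    def test_distant_mass_rejected(self):
        pair = self.make_pair()
        assert match_precursor((mz_from_mass(2944.50, 5), 5), [pair], 10) == []

    def test_six_ppm_match(self):
        a_seq = "VEYELSEEGDEPQYLDLPSTATSVNIPDLLPGR"
        from oxlink.chem import NITRATION

        alpha = pep(a_seq)
        beta = pep("WCHDNGVNYK", start=50, mods=cam_all("WCHDNGVNYK") + ((9, NITRATION),))
        pair = CrosslinkedPair(alpha, beta, 3, 1, "YW")
        (hit,) = match_precursor((mz_from_mass(4980.235, 5), 5), [pair], 10)
        assert abs(hit.ppm_error) == pytest.approx(6.4, abs=0.2)


class TestFragmentIons:
    def test_ladder_complementarity(self):
        p = pep("TFYSCTTEGR", mods=cam_all("TFYSCTTEGR"))
        ions = dict(linear_fragment_ions(p, ("b", "y"), 1))
        n = len(p.sequence)
        for i in range(1, n):
            b = ions[f"b{i}+1"] - PROTON
            y = ions[f"y{n - i}+1"] - PROTON
            assert b + y == pytest.approx(peptide_mass(p), abs=1e-9)

    def test_b2_of_gr(self):
        ions = dict(linear_fragment_ions(pep("GRK")))
        assert ions["b2+1"] == pytest.approx(214.12985, abs=2e-5)

    def test_link_retaining_b1_carries_partner(self):
        alpha = pep("YSFCTDHTVLVQTR", mods=cam_all("YSFCTDHTVLVQTR"))
        beta = pep("TFYSCTTEGR", start=30, mods=cam_all("TFYSCTTEGR"))
        pair = CrosslinkedPair(alpha, beta, 1, 3, "YY")
        ions = {f.name: f for f in fragment_ions(pair, ("b", "y"), 1)}
        b1 = ions["alpha.b1+1"]
        assert b1.retains_link
        assert b1.mz - PROTON == pytest.approx(1381.561, abs=2e-3)

    def test_heavy_label_shifts_y_ions_only(self):
        light = pep("GGYAGK")
        heavy = pep("GGYAGK", mods=()).with_label(2)
        li = dict(linear_fragment_ions(light))
        hi = dict(linear_fragment_ions(heavy))
        assert hi["y2+1"] - li["y2+1"] == pytest.approx(2 * 2.004246, abs=1e-6)
        assert hi["b2+1"] == pytest.approx(li["b2+1"], abs=1e-9)


class TestScore:
    def make_pair(self):
        return CrosslinkedPair(pep("AYAGK"), pep("GYGR", start=20), 2, 2, "YY")

    def spectrum_from(self, frags, ids=None):
        peaks = tuple((f.mz, 100.0) for f in frags)
        return Ms2Spectrum("s", 500.0, 3, peaks)

    def test_perfect_match_scores_100(self):
        frags = fragment_ions(self.make_pair(), ("b", "y"), 1)
        score, matched = score_match(self.spectrum_from(frags), frags, 0.02)
        assert score == pytest.approx(100.0)
        assert len(matched) == len(frags)

    def test_empty_or_disjoint_spectrum_scores_0(self):
        frags = fragment_ions(self.make_pair(), ("b", "y"), 1)
        empty = Ms2Spectrum("e", 500.0, 3, ())
        assert score_match(empty, frags, 0.02)[0] == 0.0
        off = Ms2Spectrum("o", 500.0, 3, tuple((f.mz + 5.0, 10.0) for f in frags))
        assert score_match(off, frags, 0.02)[0] == 0.0

    def test_plain_only_match_scores_one_third_with_equal_counts(self):
        frags = fragment_ions(self.make_pair(), ("b", "y"), 1)
        plain = [f for f in frags if not f.retains_link]
        retain = [f for f in frags if f.retains_link]
        assert len(plain) == len(retain)  # symmetric link positions
        score, _ = score_match(self.spectrum_from(plain), frags, 0.02)
        assert score == pytest.approx(100.0 / 3.0, abs=0.05)

    def test_intensity_scaling_invariance(self):
        frags = fragment_ions(self.make_pair(), ("b", "y"), 1)
        peaks = tuple((f.mz, 7.0) for f in frags[::2])
        s1 = Ms2Spectrum("a", 500.0, 3, peaks)
        s2 = Ms2Spectrum("b", 500.0, 3, tuple((m, i * 1234.5) for m, i in peaks))
        assert score_match(s1, frags, 0.02)[0] == score_match(s2, frags, 0.02)[0]


class TestFilterAndDecoys:
    def make_match(self, score=60.0, intensity=5000.0, replicate="rep1", decoy=False):
        from oxlink.xlsearch import XlMatch

        pair = CrosslinkedPair(pep("AYAGK"), pep("GYGR", start=20), 2, 2, "YY")
        return XlMatch(pair, 900.0, 0.5, (), score, decoy=decoy,
                       precursor_intensity=intensity, replicate=replicate)

    def test_score_boundary(self):
        assert filter_matches([self.make_match(score=49.9)]) == []
        assert filter_matches([self.make_match(score=50.0)]) == []  # strictly above
        assert len(filter_matches([self.make_match(score=50.1)])) == 1

    def test_intensity_floor(self):
        assert filter_matches([self.make_match(intensity=1999.9)]) == []
        assert len(filter_matches([self.make_match(intensity=2000.0)])) == 1

    def test_replicate_requirement(self):
        one = [self.make_match(replicate="rep1")]
        assert filter_matches(one, require_replicates=2) == []
        two = [self.make_match(replicate="rep1"), self.make_match(replicate="rep2")]
        assert len(filter_matches(two, require_replicates=2)) == 2

    def test_decoy_construction_fixes_cterm(self):
        decoys = make_decoy_peptides([pep("AYDGK"), pep("TWGAC")])
        assert [d.sequence for d in decoys] == ["GDYAK", "CAGWT"]
        assert all(d.protein_id.startswith("DECOY_") for d in decoys)

    def test_fdr_estimate(self):
        matches = [self.make_match(score=80) for _ in range(19)] + [
            self.make_match(score=80, decoy=True)
        ]
        assert estimate_fdr(matches, 50) == pytest.approx(1 / 19)
        assert estimate_fdr([], 50) == 0.0
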