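"""Relative site occupancy, coverage statistics, condition comparison."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oxlink.chem import MET_OXIDATION, NITRATION, Peptide
from oxlink.quant import (
    PeptideQuantRecord,
    class_percentages,
    compare_conditions,
    coverage_stats,
    residue_census,
    rso,
    rso_table,
    summarize,
)


def rec(seq, start, area, mods=(), condition="A", replicate=1):
    p = Peptide("P", start, start + len(seq) - 1, seq, mods=tuple(mods))
    return PeptideQuantRecord(p, area, condition, replicate)


class TestRso:
    def test_equal_split(self):
        records = [
            rec("AYAGK", 1, 1e6, mods=((2, NITRATION),)),
            rec("AYAGK", 1, 1e6),
        ]
        occ = rso(records, "P", 2, "nitration")
        assert occ.rso_percent == pytest.approx(50.0)

    def test_no_modified_forms(self):
        occ = rso([rec("AYAGK", 1, 5e5)], "P", 2, "nitration")
        assert occ.rso_percent == 0.0
        assert not occ.low_confidence

    def test_pooling_overlapping_species(self):
        records = [
            rec("AYAGK", 1, 30, mods=((2, NITRATION),)),
            rec("AYAGKR", 1, 20, mods=((2, NITRATION),)),
            rec("AYAGK", 1, 50),
        ]
        assert rso(records, "P", 2, "nitration").rso_percent == pytest.approx(50.0)

    def test_uncovered_site_is_not_identified(self):
        assert rso([rec("AYAGK", 1, 10)], "P", 99, "nitration") is None

    def test_modified_only_flags_low_confidence(self):
        occ = rso([rec("AYAGK", 1, 10, mods=((2, NITRATION),))], "P", 2, "nitration")
        assert occ.rso_percent == pytest.approx(100.0)
        assert occ.low_confidence

    def test_met_oxidized_forms_stay_in_denominator(self):
        records = [
            rec("AYMGK", 1, 40, mods=((2, NITRATION),)),
            rec("AYMGK", 1, 30, mods=((3, MET_OXIDATION),)),
            rec("AYMGK", 1, 30),
        ]
        assert rso(records, "P", 2, "nitration").rso_percent == pytest.approx(40.0)

    @settings(max_examples=40, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.1, max_value=1e6), min_size=1, max_size=6),
        st.lists(st.floats(min_value=0.1, max_value=1e6), min_size=1, max_size=6),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_scaling_invariance(self, mod_areas, unmod_areas, scale):
        def build(factor):
            recs = [
                rec("AYAGK", 1, a * factor, mods=((2, NITRATION),)) for a in mod_areas
            ] + [rec("AYAGK", 1, a * factor) for a in unmod_areas]
            return rso(recs, "P", 2, "nitration").rso_percent

        assert build(1.0) == pytest.approx(build(scale), rel=1e-9)

    @settings(max_examples=30, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_oracle(self, data):
        seqs = [("AYAGKR", 1), ("YAGKRM", 2), ("GKRMAY", 4)]
        records = []
        for seq, start in seqs:
            n_forms = data.draw(st.integers(1, 3))
            for _ in range(n_forms):
                modded = data.draw(st.booleans())
                area = data.draw(st.floats(min_value=0.0, max_value=1e6))
                ypos = seq.index("Y") + 1
                mods = ((ypos, NITRATION),) if modded else ()
                records.append(rec(seq, start, area, mods=mods))
        site = 2  # residue number of the shared Tyr
        occ = rso(records, "P", site, "nitration")
        covering = [r for r in records if r.peptide.covers(site)]
        num = sum(
            r.ms1_area
            for r in covering
            if any(m.name == "nitration" for m in r.peptide.modifications_at(site))
        )
        den = sum(r.ms1_area for r in covering)
        if den == 0:
            assert occ.rso_percent == 0.0
        else:
            assert occ.rso_percent == pytest.approx(100.0 * num / den, rel=1e-9)


class TestRsoTable:
    def test_replicates_averaged_at_rso_level(self):
        records = [
            rec("AYAGK", 1, 10, mods=((2, NITRATION),), replicate=1),
            rec("AYAGK", 1, 90, replicate=1),  # 10%
            rec("AYAGK", 1, 30, mods=((2, NITRATION),), replicate=2),
            rec("AYAGK", 1, 70, replicate=2),  # 30%
        ]
        tbl = rso_table(records, NITRATION)
        row = tbl[tbl.residue_number == 2].iloc[0]
        assert row.rso_percent == pytest.approx(20.0)  # mean of 10 and 30, not pooled 20/200
        assert row.n_replicates == 2
        assert row.rso_sd == pytest.approx(np.std([10, 30], ddof=1))


class TestCoverage:
    def test_table_style_percentages(self):
        cls = class_percentages(8, 25, 6)
        assert cls["pct_of_total"] == pytest.approx(20.5, abs=0.05)
        assert cls["pct_of_identified"] == pytest.approx(24.2, abs=0.05)
        assert class_percentages(0, 33, 6)["pct_identified_of_total"] == pytest.approx(
            84.6, abs=0.05
        )

    def test_counts_from_peptides(self):
        seq = "AYAGKWMDDR"
        peptides = [
            Peptide("P", 1, 5, "AYAGK", mods=((2, NITRATION),)),
        ]
        stats = coverage_stats(peptides, seq)
        assert stats["sequence_coverage_percent"] == pytest.approx(50.0)
        y = stats["residue_classes"]["Y"]
        assert (y["modified"], y["not_modified"], y["not_identified"]) == (1, 0, 0)
        w = stats["residue_classes"]["W"]
        assert (w["modified"], w["not_modified"], w["not_identified"]) == (0, 0, 1)

    def test_glyco_exclusion_raises_coverage(self):
        seq = "AYAGKWMDDR"
        peptides = [Peptide("P", 1, 5, "AYAGK")]
        stats = coverage_stats(peptides, seq, glyco_exclusion_sites=[6, 7, 8, 9, 10])
        assert stats["sequence_coverage_excluding_glyco_percent"] == pytest.approx(100.0)

    def test_no_peptides(self):
        stats = coverage_stats([], "AYAGK")
        assert stats["sequence_coverage_percent"] == 0.0
        assert stats["residue_classes"]["Y"]["not_identified"] == 1

    def test_residue_census(self):
        counts = residue_census("AYYAWM")
        assert counts == {"A": 2, "Y": 2, "W": 1, "M": 1}


RSO_COLUMNS = ["protein_id", "residue_number", "residue", "modification", "rso_percent"]


def make_rso_frame(rows):
    return pd.DataFrame(
        [("P", rn, "Y", "nitration", v) for rn, v in rows], columns=RSO_COLUMNS
    )


class TestCompareConditions:
    def test_sign_convention(self):
        a = make_rso_frame([(10, 10.0)])
        b = make_rso_frame([(10, 25.0)])
        out = compare_conditions(a, b)
        assert out.delta.iloc[0] == pytest.approx(-15.0)

    def test_assumed_zero_for_missing_site(self):
        a = make_rso_frame([])
        b = make_rso_frame([(590, 39.0)])
        out = compare_conditions(a, b)
        row = out.iloc[0]
        assert row.delta == pytest.approx(-39.0)
        assert row.assumed_zero_a and not row.assumed_zero_b

    def test_identical_tables_give_zero(self):
        a = make_rso_frame([(1, 12.0), (5, 3.0)])
        assert (compare_conditions(a, a).delta == 0).all()

    def test_antisymmetry(self):
        a = make_rso_frame([(1, 12.0), (5, 3.0)])
        b = make_rso_frame([(1, 2.0), (9, 8.0)])
        ab = compare_conditions(a, b).set_index("residue_number").delta
        ba = compare_conditions(b, a).set_index("residue_number").delta
        assert ((ab + ba).abs() < 1e-12).all()


class TestSummarize:
    def test_mean_over_modified_sites_only(self):
        tbl = make_rso_frame([(1, 10.0), (2, 20.0), (3, 30.0), (4, 0.0)])
        out = summarize(tbl)
        assert out["mean_rso_of_modified"] == pytest.approx(20.0)
        assert out["n_modified_sites"] == 3

    def test_all_zero_reports_absent_mean(self):
        tbl = make_rso_frame([(1, 0.0)])
        assert summarize(tbl)["mean_rso_of_modified"] is None

    def test_change_threshold_flags(self):
        a = make_rso_frame([(1, 22.0), (2, 5.0)])
        b = make_rso_frame([(1, 10.0), (2, 10.0)])
        deltas = compare_conditions(a, b)  # +12 and -5
        out = summarize(a, deltas, min_change_percent=10)
        assert len(out["flagged_sites"]) == 1
        assert out["flagged_sites"][0][1] == 1
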