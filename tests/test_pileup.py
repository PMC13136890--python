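"""Total variation arithmetic, error breakdown, deltas, and the BAM adapter."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poremod import (
    PileupRow,
    PileupTable,
    ValidationError,
    breakdown,
    error_delta,
    pileup_from_alignments,
    total_variation,
)

# (ref_base, a, c, g, u, del, ins, expected TV %)
TV_CASES = [
    ("A", 100, 0, 0, 0, 0, 0, 0.0),
    ("A", 0, 0, 0, 0, 50, 0, 100.0),
    ("A", 70, 0, 10, 0, 15, 5, 30.0),
    ("U", 0, 0, 0, 90, 0, 0, 0.0),
    ("U", 0, 10, 0, 90, 0, 0, 10.0),
    ("C", 0, 50, 0, 0, 0, 50, 50.0),
    ("G", 0, 0, 80, 0, 0, 20, 20.0),
    ("G", 5, 5, 80, 5, 0, 5, 20.0),
    ("A", 50, 50, 0, 0, 0, 0, 50.0),
    ("A", 1, 0, 0, 0, 0, 0, 0.0),
    ("A", 0, 1, 0, 0, 0, 0, 100.0),
    ("C", 25, 25, 25, 25, 0, 0, 75.0),
    ("U", 10, 10, 10, 60, 10, 0, 40.0),
    ("G", 0, 0, 1, 0, 1, 0, 50.0),
    ("A", 3, 0, 0, 0, 1, 0, 25.0),
    ("A", 60, 0, 0, 0, 0, 40, 40.0),
    ("C", 0, 30, 0, 0, 30, 40, 70.0),
    ("U", 0, 0, 0, 7, 2, 1, 30.0),
    ("G", 2, 2, 90, 2, 2, 2, 10.0),
    ("A", 80, 5, 5, 5, 4, 1, 20.0),
    ("U", 0, 0, 0, 0, 10, 0, 100.0),
    ("A", 99, 1, 0, 0, 0, 0, 1.0),
]


@pytest.mark.parametrize("ref,a,c,g,u,dele,ins,expected", TV_CASES)
def test_total_variation_hand_computed(ref, a, c, g, u, dele, ins, expected):
    row = PileupRow(1, ref, a, c, g, u, dele, ins)
    assert total_variation(row) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("ref,a,c,g,u,dele,ins,expected", TV_CASES)
def test_breakdown_components_sum_to_total(ref, a, c, g, u, dele, ins, expected):
    row = PileupRow(1, ref, a, c, g, u, dele, ins)
    bd = breakdown(row)
    total = (bd.mismatch_A + bd.mismatch_C + bd.mismatch_G + bd.mismatch_U
             + bd.deletion_pct + bd.insertion_pct)
    assert total == pytest.approx(bd.total_variation_pct, abs=1e-9)
    assert bd.total_variation_pct == pytest.approx(expected, abs=1e-9)


def test_breakdown_direct_arithmetic():
    bd = breakdown(PileupRow(1, "A", 70, 0, 10, 0, 15, 5))
    assert bd.mismatch_G == pytest.approx(10.0)
    assert bd.deletion_pct == pytest.approx(15.0)
    assert bd.insertion_pct == pytest.approx(5.0)
    assert bd.total_variation_pct == pytest.approx(30.0)
    ref_u = breakdown(PileupRow(2, "U", 0, 10, 0, 90, 0, 0))
    assert ref_u.mismatch_C == pytest.approx(10.0)
    assert ref_u.mismatch_U == 0.0
    assert ref_u.total_variation_pct == pytest.approx(10.0)


def test_zero_denominator_is_undefined_not_zero():
    row = PileupRow(9, "A")
    assert math.isnan(total_variation(row))
    table = PileupTable(pd.DataFrame({
        "position": [1, 2], "ref_base": ["A", "C"],
        "A": [10, 0], "C": [0, 0], "G": [0, 0], "U": [0, 0],
        "del": [0, 0], "ins": [0, 0],
    }))
    tv = table.total_variation()
    assert tv.loc[1] == 0.0
    assert math.isnan(tv.loc[2])


@given(
    ref=st.sampled_from("ACGU"),
    counts=st.tuples(*[st.integers(0, 10_000)] * 6),
)
@settings(max_examples=200, derandomize=True)
def test_total_variation_bounds_and_sum_rule(ref, counts):
    a, c, g, u, dele, ins = counts
    row = PileupRow(1, ref, a, c, g, u, dele, ins)
    tv = total_variation(row)
    bd = breakdown(row)
    if a + c + g + u + dele + ins == 0:
        assert math.isnan(tv)
    else:
        assert 0.0 <= tv <= 100.0
        parts = (bd.mismatch_A + bd.mismatch_C + bd.mismatch_G + bd.mismatch_U
                 + bd.deletion_pct + bd.insertion_pct)
        assert parts == pytest.approx(tv, abs=1e-9)


class TestErrorDelta:
    @staticmethod
    def _table(tv_counts, start=1):
        rows = []
        for i, (a, dele) in enumerate(tv_counts):
            rows.append({"position": start + i, "ref_base": "A", "A": a, "C": 0,
                         "G": 0, "U": 0, "del": dele, "ins": 0})
        return PileupTable(pd.DataFrame(rows))

    def test_identity_gives_zero(self):
        t = self._table([(95, 5), (80, 20)])
        delta = error_delta(t, t)
        assert np.allclose(delta["delta_pct"], 0.0)

    def test_arithmetic(self):
        ctl = self._table([(95, 5)])
        mod = self._table([(75, 25)])
        delta = error_delta(mod, ctl)
        assert delta["delta_pct"].iloc[0] == pytest.approx(20.0)

    def test_undefined_propagates(self):
        ctl = self._table([(0, 0), (90, 10)])
        mod = self._table([(50, 50), (90, 10)])
        delta = error_delta(mod, ctl)
        assert math.isnan(delta["delta_pct"].iloc[0])
        assert not delta["defined"].iloc[0]
        assert delta["defined"].iloc[1]

    def test_disjoint_ranges_rejected(self):
        a = self._table([(10, 0)], start=1)
        b = self._table([(10, 0)], start=100)
        with pytest.raises(ValidationError):
            error_delta(a, b)


def test_table_normalizes_dna_alphabet():
    table = PileupTable(pd.DataFrame({
        "position": [1], "ref_base": ["T"], "A": [0], "C": [0], "G": [0],
        "U": [9], "del": [1], "ins": [0],
    }))
    assert table.df["ref_base"].iloc[0] == "U"
    assert table.total_variation().iloc[0] == pytest.approx(10.0)


def test_csv_round_trip(tmp_path, default_bundle):
    path = tmp_path / "pileup.csv"
    default_bundle.pileup_modified.to_csv(path)
    again = PileupTable.read_csv(path)
    assert again == default_bundle.pileup_modified


def test_modified_sites_have_higher_total_variation(default_bundle):
    """Deletion-dominant elevation at sites should dominate the background."""
    tv = default_bundle.pileup_modified.total_variation()
    sites = list(default_bundle.truth.positions)
    med_sites = tv.loc[sites].median()
    med_background = tv.drop(sites).median()
    assert med_sites > med_background


# --- alignment adapter ----------------------------------------------------

REF_DNA = "ACGTACGTACGTACGTACGT"  # 20 nt


def _write_sam(path, reads):
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": "ref", "LN": len(REF_DNA)}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for name, flag, start0, mapq, cigar, seq in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = name
            a.flag = flag
            a.reference_id = 0
            a.reference_start = start0
            a.mapping_quality = mapq
            a.cigarstring = cigar
            a.query_sequence = seq
            out.write(a)


def test_perfect_reads_give_zero_variation(tmp_path):
    sam = tmp_path / "perfect.sam"
    _write_sam(sam, [(f"r{i}", 0, 0, 60, "20M", REF_DNA) for i in range(3)])
    table = pileup_from_alignments(sam, {"ref": REF_DNA})
    tv = table.total_variation()
    assert (table.depth() == 3).all()
    assert np.allclose(tv.to_numpy(), 0.0)


def test_deletion_and_insertion_counting(tmp_path):
    sam = tmp_path / "indel.sam"
    reads = [(f"r{i}", 0, 0, 60, "20M", REF_DNA) for i in range(4)]
    # deletion of reference position 5 (1-based)
    reads.append(("rdel", 0, 0, 60, "4M1D15M", REF_DNA[:4] + REF_DNA[5:]))
    # insertion after reference position 5
    reads.append(("rins", 0, 0, 60, "5M1I15M", REF_DNA[:5] + "A" + REF_DNA[5:]))
    _write_sam(sam, reads)
    table = pileup_from_alignments(sam, {"ref": REF_DNA})
    row5 = table.row(5)
    assert row5.del_calls == 1
    assert row5.ins_calls == 1
    # rdel lacks position 5, rins has an extra event there:
    # TV(5) = (0 mism + 1 del + 1 ins) / (5 base calls + 1 del + 1 ins)
    assert total_variation(row5) == pytest.approx(100 * 2 / 7)
    assert table.row(4).del_calls == 0
    assert table.row(6).ins_calls == 0


def test_mapq_and_secondary_filters(tmp_path):
    sam = tmp_path / "filtered.sam"
    mutated = "G" + REF_DNA[1:]
    _write_sam(sam, [
        ("good", 0, 0, 60, "20M", REF_DNA),
        ("lowq", 0, 0, 10, "20M", mutated),
        ("secondary", 256, 0, 60, "20M", mutated),
    ])
    table = pileup_from_alignments(sam, {"ref": REF_DNA}, min_mapq=20)
    assert (table.depth() == 1).all()
    assert np.allclose(table.total_variation().to_numpy(), 0.0)


def test_bam_without_index_is_io_error(tmp_path):
    import pysam

    bam = tmp_path / "noindex.bam"
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": "ref", "LN": len(REF_DNA)}]}
    with pysam.AlignmentFile(str(bam), "wb", header=header) as out:
        a = pysam.AlignedSegment(out.header)
        a.query_name = "r0"
        a.flag = 0
        a.reference_id = 0
        a.reference_start = 0
        a.mapping_quality = 60
        a.cigarstring = "20M"
        a.query_sequence = REF_DNA
        out.write(a)
    with pytest.raises(OSError):
        pileup_from_alignments(bam, {"ref": REF_DNA})
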