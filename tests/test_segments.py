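import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleoibd.segments import (
    IBDMatrix,
    IBDSegment,
    SegmentFormatError,
    SegmentValidationError,
    build_matrix,
    filter_segments,
    merge_adjacent_states,
    read_segments,
    summarize_pairs,
    write_segments,
)


def seg(a="X", b="Y", chrom=1, start=0.0, end=20.0, n_snps=6000, state="IBD1"):
    return IBDSegment(
        id_a=a, id_b=b, chrom=chrom, start_cM=start, end_cM=end,
        length_cM=end - start, n_snps=n_snps, state=state,
    )


class TestIBDSegment:
    def test_pair_canonicalized(self):
        s = IBDSegment("Z", "A", 1, 0.0, 10.0, 10.0, 3000)
        assert s.pair == ("A", "Z")

    def test_rejects_end_before_start(self):
        with pytest.raises(SegmentValidationError):
            IBDSegment("A", "B", 1, 10.0, 5.0, -5.0, 100)

    def test_rejects_length_mismatch(self):
        with pytest.raises(SegmentValidationError):
            IBDSegment("A", "B", 1, 0.0, 10.0, 12.0, 100)

    def test_rejects_self_pair(self):
        with pytest.raises(SegmentValidationError):
            IBDSegment("A", "A", 1, 0.0, 10.0, 10.0, 100)

    def test_rejects_bad_state(self):
        with pytest.raises(SegmentValidationError):
            seg(state="IBD3")


class TestReadWrite:
    def test_three_row_file(self, tmp_path):
        path = tmp_path / "seg.tsv"
        path.write_text(
            "iid1\tiid2\tch\tstart_cM\tend_cM\tlength_cM\tn_snps\tstate\n"
            "B\tA\t1\t0.0\t15.0\t15.0\t4000\tIBD1\n"
            "A\tC\t2\t5.0\t25.0\t20.0\t5000\tIBD2\n"
            "C\tB\t3\t1.0\t14.0\t13.0\t3000\tIBD1\n"
        )
        segs = read_segments(path)
        assert len(segs) == 3
        assert segs[0].pair == ("A", "B")  # normalized

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "seg.tsv"
        path.write_text("iid1\tiid2\tch\tstart_cM\tend_cM\tn_snps\nA\tB\t1\t0\t10\t100\n")
        with pytest.raises(SegmentFormatError, match="length_cM"):
            read_segments(path)

    def test_bad_row_cites_index(self, tmp_path):
        path = tmp_path / "seg.tsv"
        path.write_text(
            "iid1\tiid2\tch\tstart_cM\tend_cM\tlength_cM\tn_snps\tstate\n"
            "A\tB\t1\t0.0\t15.0\t15.0\t4000\tIBD1\n"
            "A\tC\t2\t25.0\t5.0\t-20.0\t5000\tIBD1\n"
        )
        with pytest.raises(SegmentValidationError, match="row 2"):
            read_segments(path)

    def test_round_trip(self, tmp_path, rng):
        segs = [
            seg("A", "B", chrom=int(c), start=float(s), end=float(s) + float(l))
            for c, s, l in zip(
                rng.integers(1, 23, 20), rng.uniform(0, 50, 20), rng.uniform(1, 40, 20)
            )
        ]
        path = tmp_path / "rt.tsv"
        write_segments(segs, path)
        back = read_segments(path)
        assert sorted(back, key=lambda s: (s.chrom, s.start_cM)) == sorted(
            segs, key=lambda s: (s.chrom, s.start_cM)
        )


class TestMerge:
    def test_adjacent_ibd1_ibd2_merge(self):
        s1 = seg(start=10.0, end=30.0, state="IBD1")
        s2 = seg(start=30.0, end=45.0, state="IBD2")
        merged = merge_adjacent_states([s1, s2])
        assert len(merged) == 1
        m = merged[0]
        assert (m.start_cM, m.end_cM) == (10.0, 45.0)
        assert m.length_cM == pytest.approx(35.0)
        assert m.state == "IBD1"
        assert m.n_snps == s1.n_snps + s2.n_snps

    def test_all_ibd2_stays_ibd2(self):
        merged = merge_adjacent_states(
            [seg(start=0, end=10, state="IBD2"), seg(start=10, end=20, state="IBD2")]
        )
        assert merged[0].state == "IBD2"

    def test_different_chromosomes_untouched(self):
        segs = [seg(chrom=1), seg(chrom=2)]
        assert sorted(merge_adjacent_states(segs), key=lambda s: s.chrom) == segs

    def test_gap_respected(self):
        segs = [seg(start=0, end=10), seg(start=15, end=25)]
        assert len(merge_adjacent_states(segs, gap_tol_cM=0.0)) == 2
        assert len(merge_adjacent_states(segs, gap_tol_cM=5.0)) == 1

    def test_overlap_merges_with_warning(self):
        segs = [seg(start=0, end=12), seg(start=8, end=20)]
        with pytest.warns(UserWarning, match="overlap"):
            merged = merge_adjacent_states(segs)
        assert len(merged) == 1
        assert (merged[0].start_cM, merged[0].end_cM) == (0.0, 20.0)

    def test_fragmentation_reconstruction_oracle(self, rng):
        # shatter a known span into abutting pieces; merge must recover it
        for _ in range(100):
            lo, hi = 5.0, 5.0 + float(rng.uniform(20, 80))
            k = int(rng.integers(2, 8))
            cuts = np.sort(rng.uniform(lo, hi, size=k - 1))
            bounds = [lo, *cuts.tolist(), hi]
            pieces = [
                seg(start=a, end=b, state=("IBD2" if rng.random() < 0.3 else "IBD1"))
                for a, b in zip(bounds[:-1], bounds[1:])
            ]
            order = rng.permutation(len(pieces))
            merged = merge_adjacent_states([pieces[i] for i in order])
            assert len(merged) == 1
            assert merged[0].start_cM == pytest.approx(lo)
            assert merged[0].end_cM == pytest.approx(hi)


class TestFilter:
    def test_short_removed(self):
        assert filter_segments([seg(start=0, end=10, n_snps=9000)]) == []

    def test_boundary_12cm_retained(self):
        # inclusive threshold: exactly 12 cM at exactly 220 SNPs/cM stays
        s = seg(start=0, end=12.0, n_snps=2640)
        assert filter_segments([s]) == [s]

    def test_low_density_removed(self):
        assert filter_segments([seg(start=0, end=15, n_snps=3000)]) == []

    def test_merge_then_filter_idempotent(self, rng):
        segs = []
        for _ in range(50):
            a, b = sorted(rng.choice(list("ABCDE"), 2, replace=False))
            start = float(rng.uniform(0, 100))
            segs.append(
                seg(a, b, chrom=int(rng.integers(1, 5)), start=start,
                    end=start + float(rng.uniform(1, 40)),
                    n_snps=int(rng.integers(0, 20000)))
            )
        once = filter_segments(merge_adjacent_states(segs))
        twice = filter_segments(merge_adjacent_states(once))
        assert sorted(once, key=lambda s: (s.pair, s.chrom, s.start_cM)) == sorted(
            twice, key=lambda s: (s.pair, s.chrom, s.start_cM)
        )


class TestSummariesAndMatrix:
    def test_pair_summary(self):
        segs = [seg(start=0, end=14), seg(start=20, end=40)]
        summ = summarize_pairs(segs)[("X", "Y")]
        assert summ.sum_cM == pytest.approx(34.0)
        assert summ.max_cM == pytest.approx(20.0)
        assert summ.n_segments == 2

    def test_unknown_individual_named(self):
        summaries = summarize_pairs([seg("X", "Y")])
        with pytest.raises(KeyError, match="Y"):
            build_matrix(summaries, ["X", "Z"])

    def test_conservation_oracle(self, rng):
        ids = [f"P{k}" for k in range(8)]
        segs = []
        for _ in range(60):
            a, b = sorted(rng.choice(ids, 2, replace=False))
            start = float(rng.uniform(0, 100))
            segs.append(seg(a, b, start=start, end=start + float(rng.uniform(8, 40)),
                            n_snps=30000, chrom=int(rng.integers(1, 23))))
        retained = filter_segments(segs)
        mat = build_matrix(summarize_pairs(retained), ids)
        total = sum(s.length_cM for s in retained)
        assert mat.total_cM() == pytest.approx(total, rel=1e-12)
        # equivalently: full-matrix sum double-counts each pair
        assert mat.values.sum() == pytest.approx(2 * total, rel=1e-12)

    def test_matrix_invariants_and_possible_pairs(self, rng):
        from conftest import random_symmetric_matrix

        mat = random_symmetric_matrix(rng, 51)
        assert mat.n_possible_pairs() == 1275
        assert np.allclose(mat.values, mat.values.T)
        assert np.all(np.diag(mat.values) == 0)

    def test_matrix_rejects_asymmetry(self):
        values = np.zeros((2, 2))
        values[0, 1] = 3.0
        with pytest.raises(ValueError, match="symmetric"):
            IBDMatrix(ids=["A", "B"], values=values)

    def test_matrix_csv_round_trip(self, tmp_path, rng):
        from conftest import random_symmetric_matrix

        mat = random_symmetric_matrix(rng, 7)
        path = tmp_path / "m.csv"
        mat.write_csv(path)
        back = IBDMatrix.read_csv(path)
        assert back.ids == mat.ids
        np.testing.assert_allclose(back.values, mat.values)


@settings(max_examples=50, deadline=None)
@given(
    start=st.floats(0, 100),
    length=st.floats(0.5, 60),
    n_snps=st.integers(0, 50000),
)
def test_segment_invariants_hold(start, length, n_snps):
    s = IBDSegment("A", "B", 1, start, start + length, length, n_snps)
    assert s.end_cM > s.start_cM
    assert s.length_cM == pytest.approx(s.end_cM - s.start_cM, abs=1e-6)
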