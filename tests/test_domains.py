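"""Block decomposition, candidate enumeration, the two block statistics, and
domain extraction policies."""

import numpy as np
import pandas as pd
import pytest

from rnadomains import (
    BasePairProbabilityMatrix,
    DomainCandidate,
    ExtractionPolicy,
    decompose_blocks,
    enumerate_candidates,
    extract_domains,
    scan_report,
    score_candidate,
    write_bed,
)

from conftest import random_matrix


def naive_scores(matrix, start, end, double_count=False):
    """Brute-force double loop over every (i, j): the scoring oracle.

    Written independently of the scanner's prefix-sum arithmetic.
    """
    L = matrix.length
    size = end - start + 1
    inside = cross = 0.0
    for i in range(1, L + 1):
        for j in range(i + 1, L + 1):
            p = matrix[i, j]
            i_in = start <= i <= end
            j_in = start <= j <= end
            if i_in and j_in:
                inside += p
            elif i_in or j_in:
                cross += p
    if double_count:
        cross *= 2.0
    p_inside = inside / size**2
    p_io = 0.0 if size == L else cross / ((L - size) * size)
    return p_inside, p_io


class TestBlockDecomposition:
    @pytest.mark.parametrize(
        ("length", "block", "n_blocks", "last"),
        [
            (656, 10, 66, (651, 656)),  # short trailing block of 6 nt
            (10, 10, 1, (1, 10)),
            (7, 10, 1, (1, 7)),
            (30, 10, 3, (21, 30)),
        ],
    )
    def test_blocks(self, length, block, n_blocks, last):
        d = decompose_blocks(length, block)
        assert d.n_blocks == n_blocks
        assert d.blocks[-1] == last
        # coverage of 1..L without gaps or overlap
        flat = [p for s, e in d.blocks for p in range(s, e + 1)]
        assert flat == list(range(1, length + 1))

    @pytest.mark.parametrize(("length", "block"), [(0, 10), (10, 0), (-5, 10)])
    def test_invalid(self, length, block):
        with pytest.raises(ValueError):
            decompose_blocks(length, block)


class TestCandidateEnumeration:
    def test_count_is_triangular_for_all_b_up_to_100(self):
        for b in range(1, 101):
            d = decompose_blocks(b * 10, 10)
            assert len(enumerate_candidates(d)) == b * (b + 1) // 2

    def test_eleanor2_sized_input(self):
        assert len(enumerate_candidates(decompose_blocks(656, 10))) == 2211

    def test_single_block(self):
        (cand,) = enumerate_candidates(decompose_blocks(7, 10))
        assert (cand.start, cand.end) == (1, 7)

    def test_three_blocks_exhaustive(self):
        cands = enumerate_candidates(decompose_blocks(30, 10))
        ranges = [(c.start, c.end) for c in cands]
        assert ranges == [(1, 10), (1, 20), (1, 30), (11, 20), (11, 30), (21, 30)]


class TestScoring:
    def test_single_inside_pair(self):
        m = BasePairProbabilityMatrix(20, {(3, 8): 0.5})
        c = enumerate_candidates(decompose_blocks(20))[0]  # 1..10
        s = score_candidate(c, m)
        assert s.p_inside == pytest.approx(0.5 / 100)
        assert s.p_inside_outside == 0.0

    def test_single_cross_pair(self):
        m = BasePairProbabilityMatrix(20, {(5, 15): 0.3})
        c = enumerate_candidates(decompose_blocks(20))[0]  # 1..10
        s = score_candidate(c, m)
        assert s.p_inside == 0.0
        assert s.p_inside_outside == pytest.approx(0.3 / (10 * 10))

    def test_double_count_convention_doubles_cross_sum(self):
        m = BasePairProbabilityMatrix(20, {(5, 15): 0.3})
        c = enumerate_candidates(decompose_blocks(20))[0]
        assert score_candidate(c, m, symmetric_double_count=True).p_inside_outside == (
            pytest.approx(2 * 0.3 / 100)
        )

    def test_whole_sequence_candidate_has_zero_io(self, rng):
        m = random_matrix(rng, 40, 15)
        c = DomainCandidate(0, 3, 1, 40, 40)
        assert score_candidate(c, m).p_inside_outside == 0.0

    def test_matches_naive_double_loop(self, rng):
        """Spot-check (the 1000-draw sweep runs in the acceptance suite)."""
        for _ in range(100):
            L = int(rng.integers(11, 61))
            m = random_matrix(rng, L, int(rng.integers(1, 20)))
            cands = enumerate_candidates(decompose_blocks(L))
            c = cands[int(rng.integers(0, len(cands)))]
            s = score_candidate(c, m)
            ni, nio = naive_scores(m, c.start, c.end)
            assert abs(s.p_inside - ni) < 1e-12
            assert abs(s.p_inside_outside - nio) < 1e-12

    def test_permuting_entries_inside_d_preserves_p_inside(self, rng):
        """p_inside depends only on total probability mass within D."""
        L = 40
        base = np.zeros((L, L))
        coords = [(12, 18), (13, 19), (11, 16)]  # all inside 11..20
        vals = [0.3, 0.2, 0.1]
        for (i, j), v in zip(coords, vals):
            base[i - 1, j - 1] = v
        m1 = BasePairProbabilityMatrix(L, base.copy())
        perm = np.zeros((L, L))
        for (i, j), v in zip(coords, vals[::-1]):  # same positions, permuted masses
            perm[i - 1, j - 1] = v
        m2 = BasePairProbabilityMatrix(L, perm)
        c = DomainCandidate(1, 1, 11, 20, L)
        assert score_candidate(c, m1).p_inside == pytest.approx(
            score_candidate(c, m2).p_inside
        )

    def test_length_mismatch(self, rng):
        m = random_matrix(rng, 20, 3)
        with pytest.raises(ValueError, match="length"):
            score_candidate(DomainCandidate(0, 0, 1, 10, 30), m)


class TestExtraction:
    def test_zero_matrix_yields_nothing_under_any_policy(self):
        m = BasePairProbabilityMatrix(60, np.zeros((60, 60)))
        for mode in ("all_passing", "maximal_passing", "best_nonoverlapping"):
            assert extract_domains(m, ExtractionPolicy(report_mode=mode)) == []

    def test_planted_hairpin_exact_arithmetic(self):
        """Ten 0.9 stem entries planted on 21..50 of a 60-nt matrix."""
        mat = np.zeros((60, 60))
        for k in range(10):
            mat[20 + k, 49 - k] = 0.9  # pairs (21+k, 50-k), 1-based
        m = BasePairProbabilityMatrix(60, mat)
        doms = extract_domains(m, ExtractionPolicy(report_mode="all_passing"))
        by_range = {(c.start, c.end): s for c, s in doms}
        assert (21, 50) in by_range
        assert by_range[(21, 50)].p_inside == pytest.approx(9.0 / 900)
        assert by_range[(21, 50)].p_inside_outside == 0.0
        # candidates confined to the unpaired flanks never pass
        for c, _ in doms:
            assert not (c.end <= 20 or c.start >= 51)

    def test_maximal_passing_drops_contained_candidates(self):
        mat = np.zeros((60, 60))
        for k in range(10):
            mat[20 + k, 49 - k] = 0.9
        m = BasePairProbabilityMatrix(60, mat)
        maximal = extract_domains(m, ExtractionPolicy(report_mode="maximal_passing"))
        allp = extract_domains(m, ExtractionPolicy(report_mode="all_passing"))
        kept = {(c.start, c.end) for c, _ in maximal}
        everyone = {(c.start, c.end) for c, _ in allp}
        assert kept <= everyone
        for a, b in kept:
            for c, d in everyone:
                assert not (c <= a and b <= d and (c, d) != (a, b))

    def test_best_nonoverlapping_excludes_overlaps(self):
        mat = np.zeros((60, 60))
        for k in range(10):
            mat[20 + k, 49 - k] = 0.9
        m = BasePairProbabilityMatrix(60, mat)
        chosen = extract_domains(m, ExtractionPolicy(report_mode="best_nonoverlapping"))
        for a, (c1, _) in enumerate(chosen):
            for c2, _ in chosen[a + 1 :]:
                assert not c1.overlaps(c2)

    def test_threshold_monotonicity(self, rng):
        """Raising t_inside or lowering t_io can only shrink the result."""
        for _ in range(10):
            m = random_matrix(rng, 60, 25)
            base = ExtractionPolicy(report_mode="all_passing")
            found = {(c.start, c.end) for c, _ in extract_domains(m, base)}
            stricter_inside = ExtractionPolicy(
                threshold_inside=base.threshold_inside * 2, report_mode="all_passing"
            )
            stricter_io = ExtractionPolicy(
                threshold_io=base.threshold_io / 2, report_mode="all_passing"
            )
            assert {(c.start, c.end) for c, _ in extract_domains(m, stricter_inside)} <= found
            assert {(c.start, c.end) for c, _ in extract_domains(m, stricter_io)} <= found

    def test_deterministic(self, rng):
        m = random_matrix(rng, 80, 30)
        a = [(c.start, c.end) for c, _ in extract_domains(m)]
        b = [(c.start, c.end) for c, _ in extract_domains(m)]
        assert a == b


class TestReportAndExport:
    def test_report_has_one_row_per_candidate(self, rng):
        m = random_matrix(rng, 30, 5)
        df = scan_report(m)
        assert len(df) == 6  # B=3 blocks
        assert list(df.columns) == ["start", "end", "size", "p_inside", "p_io", "passes"]

    def test_zero_matrix_report_all_fail(self):
        df = scan_report(BasePairProbabilityMatrix(30, np.zeros((30, 30))))
        assert not df["passes"].any()

    def test_report_rows_match_score_candidate(self, rng):
        m = random_matrix(rng, 50, 20)
        df = scan_report(m)
        cands = enumerate_candidates(decompose_blocks(50))
        for row, cand in zip(df.itertuples(), cands):
            s = score_candidate(cand, m)
            assert row.p_inside == pytest.approx(s.p_inside, abs=1e-15)
            assert row.p_io == pytest.approx(s.p_inside_outside, abs=1e-15)

    def test_bed_export_is_zero_based_half_open(self, tmp_path):
        mat = np.zeros((60, 60))
        for k in range(10):
            mat[20 + k, 49 - k] = 0.9
        m = BasePairProbabilityMatrix(60, mat)
        doms = extract_domains(m, ExtractionPolicy(report_mode="maximal_passing"))
        bed = tmp_path / "d.bed"
        write_bed(doms, bed)
        rows = [line.split("\t") for line in bed.read_text().splitlines()]
        assert len(rows) == len(doms)
        for fields, (cand, score) in zip(rows, doms):
            assert int(fields[1]) == cand.start - 1
            assert int(fields[2]) == cand.end
            assert 0 <= int(fields[4]) <= 1000
            assert int(fields[4]) == int(min(score.p_inside * 1000, 1000))
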