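"""Single and structured motif extraction vs exhaustive enumeration."""

import pytest

from flasm import (FlasmError, ImplantPlan, StructuredMotifSpec,
                   box_occurrences, implant, random_sequences,
                   single_motif_extract, structured_motif_extract)

from conftest import random_string
from oracles import single_motifs_brute, structured_motifs_brute


class TestSpecNotation:
    def test_parse_paper_style_notation(self):
        spec = StructuredMotifSpec.from_notation(
            "<(80,15)[5,15](60,10)[5,20](230,20)>")
        assert spec.boxes == ((80, 15), (60, 10), (230, 20))
        assert spec.gaps == ((5, 15), (5, 20))
        assert spec.notation == "(80,15)[5,15](60,10)[5,20](230,20)"

    @pytest.mark.parametrize("bad", ["(3,0)(3,0)", "[1,2](3,0)", "(3,0)[1,2]",
                                     "(3,3)", "(3,0)[2,1](3,0)", "nonsense"])
    def test_invalid_notation_rejected(self, bad):
        with pytest.raises(FlasmError):
            StructuredMotifSpec.from_notation(bad)


class TestSingleMotifs:
    def test_shared_tetramer(self):
        recs = single_motif_extract(["AACGTT", "CACGTG", "TACGTA"], 4, 0, 3)
        assert [(r.motif, r.quorum_count) for r in recs] == [("ACGT", 3)]
        assert recs[0].source == (0, 4)
        assert recs[0].seq_hits == [1, 1, 1]

    def test_quorum_one_returns_every_distinct_factor(self):
        seqs = ["ACGTA", "GGGGG"]
        recs = single_motif_extract(seqs, 2, 0, 1)
        factors = {s[p:p + 2] for s in seqs for p in range(len(s) - 1)}
        assert {r.motif for r in recs} == factors

    @pytest.mark.parametrize("model", ["hamming", "edit"])
    def test_matches_brute_force(self, rng, model):
        for _ in range(4):
            seqs = [random_string(rng, rng.randint(10, 20)) for _ in range(4)]
            ell, k = 4, rng.randint(0, 2)
            quorum = rng.randint(1, 4)
            got = {r.motif: r.quorum_count
                   for r in single_motif_extract(seqs, ell, k, quorum, model)}
            assert got == single_motifs_brute(seqs, ell, k, quorum, model)

    def test_raising_quorum_never_adds_motifs(self, rng):
        seqs = [random_string(rng, 15) for _ in range(5)]
        prev = None
        for quorum in range(5, 0, -1):
            cur = {r.motif for r in single_motif_extract(seqs, 3, 1, quorum)}
            if prev is not None:
                assert prev <= cur
            prev = cur

    def test_raising_k_never_removes_motifs(self, rng):
        seqs = [random_string(rng, 15) for _ in range(4)]
        prev = set()
        for k in range(4):
            cur = {r.motif for r in single_motif_extract(seqs, 5, k, 3)}
            assert prev <= cur
            prev = cur

    def test_long_motif_recovery_beyond_word_size(self):
        """An implanted 120-mer (with substitutions up to half the threshold
        per copy) is recovered at matching parameters — factor lengths well
        beyond one machine word."""
        k = 8
        seqs = random_sequences(10, 500, 77)
        plan = ImplantPlan(120, tuple(range(10)), (k // 2,), seed=78)
        seqs, truth = implant(seqs, plan)
        recs = single_motif_extract(seqs, 120, k, 10, "hamming")
        reported = {r.motif for r in recs}
        assert all(tr.boxes[0] in reported for tr in truth)

    def test_errors(self):
        with pytest.raises(FlasmError):
            single_motif_extract(["ACGT"], 2, 0, 1)
        with pytest.raises(FlasmError):
            single_motif_extract(["ACGT", "ACGT"], 2, 0, 3)  # quorum > N
        with pytest.raises(FlasmError):
            single_motif_extract(["ACGT", "AC"], 3, 0, 1)    # ell too long


class TestBoxOccurrences:
    def test_exact_box(self):
        assert box_occurrences(["AAATCCC"], "AAA", 0)[0] == [(0, 2)]

    def test_one_error_occurrence(self):
        occ = box_occurrences(["ATGGCAAGT"], "AGA", 1)[0]
        assert (6, 8) in occ  # AGA vs AGT with one error

    def test_edit_start_is_minimal_distance_start(self):
        # ending at j=4, GAAA (substitution) and AAA (deletion) both reach
        # distance 1; the smallest start attaining the minimum wins
        occ = box_occurrences(["GGAAAGG"], "AAAA", 1, "edit")[0]
        assert (1, 4) in occ

    @pytest.mark.parametrize("model", ["hamming", "edit"])
    def test_matches_window_scan(self, rng, model):
        from oracles import _occ_intervals
        for _ in range(5):
            s = random_string(rng, 25)
            box = random_string(rng, 5)
            k = rng.randint(0, 2)
            assert box_occurrences([s], box, k, model)[0] == \
                _occ_intervals(box, s, k, model)


class TestStructuredMotifs:
    SPEC = StructuredMotifSpec(((3, 0), (3, 0)), ((1, 2),))

    def test_two_box_worked_example(self):
        seqs = ["AAATCCC", "AAATTCCCG", "AAACCC"]
        recs = structured_motif_extract(seqs, self.SPEC, 2)
        hit = [r for r in recs if r.boxes == ("AAA", "CCC")]
        assert len(hit) == 1
        assert hit[0].quorum_count == 2  # third sequence's gap of 0 fails
        assert hit[0].motif == "AAA[1,2]CCC"

    def test_single_box_degenerates_to_single_extraction(self, rng):
        seqs = [random_string(rng, 15) for _ in range(4)]
        spec = StructuredMotifSpec(((4, 1),), ())
        got = {r.boxes[0]: r.quorum_count
               for r in structured_motif_extract(seqs, spec, 2)}
        exp = {r.motif: r.quorum_count
               for r in single_motif_extract(seqs, 4, 1, 2)}
        assert got == exp

    @pytest.mark.parametrize("model", ["hamming", "edit"])
    def test_matches_brute_force(self, rng, model):
        for _ in range(3):
            seqs = [random_string(rng, rng.randint(12, 18), "AC") for _ in range(3)]
            spec = StructuredMotifSpec(((3, 1), (2, 0)), ((0, 2),))
            quorum = rng.randint(1, 3)
            got = {r.boxes: r.quorum_count
                   for r in structured_motif_extract(seqs, spec, quorum, model)}
            exp = structured_motifs_brute(seqs, list(spec.boxes),
                                          list(spec.gaps), quorum, model)
            assert got == exp, (seqs, quorum)

    def test_raising_quorum_never_adds(self, rng):
        seqs = [random_string(rng, 20, "AC") for _ in range(4)]
        spec = StructuredMotifSpec(((3, 1), (3, 1)), ((0, 3),))
        prev = None
        for quorum in range(4, 0, -1):
            cur = {r.boxes for r in structured_motif_extract(seqs, spec, quorum)}
            if prev is not None:
                assert prev <= cur
            prev = cur

    def test_implant_recovery(self):
        spec = StructuredMotifSpec(((12, 3), (10, 2)), ((2, 6),))
        seqs = random_sequences(6, 120, 5)
        plan = ImplantPlan(spec, (0, 1, 2, 3), (1, 1), seed=6)
        seqs, truth = implant(seqs, plan)
        recs = structured_motif_extract(seqs, spec, quorum=4)
        reported = {r.boxes for r in recs}
        assert all(tr.boxes in reported for tr in truth)
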