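import numpy as np
import pytest
from Bio.SeqUtils import MeltingTemp as BioMT

from ssrpolykit.primer_designer import (
    PrimerParams,
    candidate_ok,
    design_primers,
    extract_flanks,
    gc_content,
    melting_temperature,
)
from ssrpolykit.sequence_io import SequenceRecord
from ssrpolykit.ssr_miner import SSRLocus

PARAMS = PrimerParams()


def random_record(rng, n, seq_id="s"):
    return SequenceRecord(
        id=seq_id, residues="".join(rng.choice(list("ACGT"), size=n))
    )


class TestExtractFlanks:
    def test_full_flanks_coordinates(self):
        rng = np.random.default_rng(1)
        record = random_record(rng, 2000)
        locus = SSRLocus("s", 600, 620, "ACG", 7, "p3")
        fl = extract_flanks(record, locus, 500)
        assert fl.upstream == record.residues[99:599]
        assert fl.downstream == record.residues[620:1120]
        assert len(fl.upstream) == len(fl.downstream) == 500
        assert fl.template == record.residues[99:1120]
        assert fl.template_start == 100

    def test_left_clipping_no_padding(self):
        rng = np.random.default_rng(2)
        record = random_record(rng, 2000)
        locus = SSRLocus("s", 50, 61, "AC", 6, "p2")
        fl = extract_flanks(record, locus, 500)
        assert fl.upstream == record.residues[:49]
        assert len(fl.upstream) == 49

    def test_locus_at_record_end(self):
        record = SequenceRecord(id="s", residues="G" * 100 + "AC" * 6)
        locus = SSRLocus("s", 101, 112, "AC", 6, "p2")
        fl = extract_flanks(record, locus, 500)
        assert fl.downstream == ""

    def test_out_of_bounds_rejected(self):
        record = SequenceRecord(id="s", residues="ACGT" * 10)
        with pytest.raises(ValueError):
            extract_flanks(record, SSRLocus("s", 30, 45, "AC", 8, "p2"), 10)


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("GGAAATCGTCAAGAACGTC", 9 / 19),  # 5 G + 4 C over 19
            ("AAAA", 0.0),
            ("GCGC", 1.0),
            ("GCNN", 0.5),  # N in denominator only
        ],
    )
    def test_values(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gc_content("")


class TestMeltingTemperature:
    def test_salt_adjusted_gc_formula(self):
        # 81.5 - 21.597 + 19.421 - 31.579
        tm = melting_temperature("GGAAATCGTCAAGAACGTC", na_conc=0.05)
        assert tm == pytest.approx(47.7, abs=0.05)

    def test_wallace_rule(self):
        assert melting_temperature(
            "GGAAATCGTCAAGAACGTC", method="wallace"
        ) == pytest.approx(56.0)

    def test_wallace_agrees_with_biopython(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(15, 30))))
            assert melting_temperature(seq, method="wallace") == pytest.approx(
                BioMT.Tm_Wallace(seq)
            )

    def test_gc_monotonicity_at_fixed_length(self):
        low = melting_temperature("ATATATATATATATATATAT")
        high = melting_temperature("ATATATATATGTATATATAT")
        assert high > low

    @pytest.mark.parametrize("seq", ["ACGTNACGTACG", "ACGTACG"])
    def test_preconditions(self, seq):
        with pytest.raises(ValueError):
            melting_temperature(seq)


class TestCandidateOk:
    def test_polyx_rejected(self):
        ok, reason = candidate_ok("A" * 20, PARAMS)
        assert not ok and reason == "poly-X"

    def test_too_short_rejected(self):
        ok, reason = candidate_ok("ACGTACGTAC", PARAMS)
        assert not ok and reason == "length"

    def test_n_rejected(self):
        ok, reason = candidate_ok("ACGTACGTACGTACGTNCGT", PARAMS)
        assert not ok and reason == "contains N"

    def test_good_candidate_accepted(self):
        # 20-mer, GC 0.5, no run > 4: Tm = 81.5 - 21.597 + 20.5 - 30 = 50.4;
        # accepted under widened Tm bounds
        params = PrimerParams(tm_min=45.0, tm_opt=50.0, tm_max=55.0)
        ok, reason = candidate_ok("ACGTACGTACGTACGTACGT", params)
        assert not ok and reason == "3' self-complementarity"
        ok, reason = candidate_ok("AGGATCCTGTAACTGGTCAT", params)
        assert ok, reason


def seeded_flanked_locus(seed=3, flank=500):
    """A planted (AT)9 locus with random flanks on a 2 kb record."""
    rng = np.random.default_rng(seed)
    up = "".join(rng.choice(list("ACGT"), size=flank))
    down = "".join(rng.choice(list("ACGT"), size=flank))
    tract = "AT" * 9
    record = SequenceRecord(id="s", residues=up + tract + down)
    locus = SSRLocus("s", flank + 1, flank + len(tract), "AT", 9, "p2")
    return record, extract_flanks(record, locus, flank)


class TestDesignPrimers:
    def test_seeded_fixture_contract(self):
        _, fl = seeded_flanked_locus()
        ps = design_primers(fl, PARAMS)
        assert ps.pairs, ps.failure_reason
        tract_lo = len(fl.upstream) + 1
        tract_hi = len(fl.upstream) + len(fl.tract)
        for p in ps.pairs:
            assert PARAMS.product_min <= p.expected_product_size <= PARAMS.product_max
            # tract fully inside the product; primers fully in the flanks
            assert p.forward_end < tract_lo
            assert p.reverse_start > tract_hi
            assert p.expected_product_size == p.reverse_end - p.forward_start + 1
            assert PARAMS.tm_min <= p.tm_forward <= PARAMS.tm_max
            assert abs(p.tm_forward - p.tm_reverse) <= PARAMS.max_tm_diff

    def test_sorted_by_penalty_with_consecutive_ranks(self):
        _, fl = seeded_flanked_locus()
        ps = design_primers(fl, PARAMS)
        penalties = [p.penalty for p in ps.pairs]
        assert penalties == sorted(penalties)
        assert [p.rank for p in ps.pairs] == list(range(1, len(ps.pairs) + 1))
        assert len(ps.pairs) <= PARAMS.n_pairs

    def test_distinct_forward_positions(self):
        _, fl = seeded_flanked_locus()
        ps = design_primers(fl, PARAMS)
        starts = [p.forward_start for p in ps.pairs]
        assert len(starts) == len(set(starts))

    def test_penalty_formula_and_zero_condition(self):
        _, fl = seeded_flanked_locus()
        ps = design_primers(fl, PARAMS)
        for p in ps.pairs:
            expected = (
                abs(p.tm_forward - PARAMS.tm_opt)
                + abs(p.tm_reverse - PARAMS.tm_opt)
                + 0.5 * (abs(len(p.forward) - PARAMS.len_opt)
                         + abs(len(p.reverse) - PARAMS.len_opt))
                + abs(p.tm_forward - p.tm_reverse)
            )
            assert p.penalty == pytest.approx(expected)
            if p.penalty == 0:
                assert len(p.forward) == len(p.reverse) == PARAMS.len_opt
                assert p.tm_forward == p.tm_reverse == PARAMS.tm_opt

    def test_zero_penalty_with_idealized_tm(self):
        # with a constant-Tm model, penalty reduces to the length terms,
        # so an opt-length pair scores exactly zero
        _, fl = seeded_flanked_locus()
        ps = design_primers(fl, PARAMS, tm_function=lambda s: PARAMS.tm_opt)
        assert ps.pairs
        best = ps.pairs[0]
        assert best.penalty == 0.0
        assert len(best.forward) == len(best.reverse) == PARAMS.len_opt

    def test_unusable_flanks_fail_with_reason(self):
        record = SequenceRecord(id="s", residues="A" * 500 + "AT" * 9 + "A" * 500)
        locus = SSRLocus("s", 501, 518, "AT", 9, "p2")
        fl = extract_flanks(record, locus, 500)
        ps = design_primers(fl, PARAMS)
        assert ps.pairs == []
        assert ps.failure_reason == "no acceptable candidates"

    def test_short_flanks_fail_with_reason(self):
        record = SequenceRecord(id="s", residues="AT" * 9 + "GCGATCGATG")
        locus = SSRLocus("s", 1, 18, "AT", 9, "p2")
        fl = extract_flanks(record, locus, 500)
        ps = design_primers(fl, PARAMS)
        assert ps.pairs == []
        assert ps.failure_reason == "flank too short"

    def test_determinism(self):
        _, fl = seeded_flanked_locus()
        a = design_primers(fl, PARAMS)
        b = design_primers(fl, PARAMS)
        assert a == b
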