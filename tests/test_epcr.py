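import numpy as np
import pytest

import oracles
from ssrpolykit.datasets import HVSSR_PANEL
from ssrpolykit.epcr import EPCRParams, epcr, epcr_batch, find_matches
from ssrpolykit.sequence_io import GenotypeSet, SequenceRecord, reverse_complement

PRIMER = "ACGTACGTACGTACGTAC"
PRIMER2 = "TGCATGGACTACGGATTAGC"  # non-periodic, for mismatch-mode tests
F337, R337, SIZES337 = HVSSR_PANEL["HvSSR03-37"]


def rec(seq, seq_id="t"):
    return SequenceRecord(id=seq_id, residues=seq)


def planted_record(rng, primer, pos=100, n=1000):
    """Random record with `primer` planted once at 1-based position pos+1."""
    while True:
        bg = "".join(rng.choice(list("ACGT"), size=n))
        s = bg[:pos] + primer + bg[pos + len(primer):]
        if s.count(primer) == 1 and s.count(reverse_complement(primer)) == 0:
            return rec(s)


class TestFindMatches:
    def test_planted_exact_plus_strand(self):
        record = planted_record(np.random.default_rng(1), PRIMER)
        (m,) = find_matches(PRIMER, record)
        assert (m.start, m.end, m.strand, m.mismatches) == (101, 118, "+", 0)

    def test_reverse_complement_minus_strand_same_footprint(self):
        record = planted_record(np.random.default_rng(1), PRIMER)
        (m,) = find_matches(reverse_complement(PRIMER), record)
        assert (m.start, m.end, m.strand) == (101, 118, "-")

    def test_absent_primer(self):
        record = planted_record(np.random.default_rng(2), PRIMER)
        assert find_matches("G" * 18, record) == []

    def test_three_prime_seed_blocks_terminal_mismatch(self):
        rng = np.random.default_rng(3)
        record = planted_record(rng, PRIMER2)
        mutated = PRIMER2[:-1] + ("G" if PRIMER2[-1] != "G" else "C")
        params = EPCRParams(max_mismatch=1, three_prime_seed=5)
        assert find_matches(mutated, record, params) == []

    def test_internal_mismatch_tolerated_outside_seed(self):
        rng = np.random.default_rng(3)
        record = planted_record(rng, PRIMER2)
        mutated = ("G" if PRIMER2[0] != "G" else "C") + PRIMER2[1:]
        params = EPCRParams(max_mismatch=1, three_prime_seed=5)
        (m,) = find_matches(mutated, record, params)
        assert (m.start, m.mismatches) == (101, 1)

    def test_n_in_template_never_matches(self):
        record = rec("G" * 50 + PRIMER2[:9] + "N" + PRIMER2[10:] + "G" * 50)
        assert find_matches(PRIMER2, record) == []
        params = EPCRParams(max_mismatch=1, three_prime_seed=5)
        (m,) = find_matches(PRIMER2, record, params)
        assert m.mismatches == 1


def cassette(rng, forward, reverse, spacer):
    return forward + "".join(rng.choice(list("ACGT"), size=spacer)) + reverse_complement(reverse)


class TestEpcr:
    def test_hvssr_cassette_size(self):
        rng = np.random.default_rng(10)
        template = "G" * 0 + cassette(rng, F337, R337, 298)
        record = rec("".join(rng.choice(list("ACGT"), size=150)) + template
                     + "".join(rng.choice(list("ACGT"), size=150)))
        (hit,) = epcr((F337, R337), [record])
        assert hit.size == len(F337) + 298 + len(R337) == 337
        assert hit.orientation == "+"
        assert hit.forward_mismatches == hit.reverse_mismatches == 0

    def test_strand_symmetry_minus_orientation(self):
        rng = np.random.default_rng(10)
        template = cassette(rng, F337, R337, 298)
        record = rec(reverse_complement("A" * 100 + template + "A" * 100))
        (hit,) = epcr((F337, R337), [record])
        assert hit.size == 337
        assert hit.orientation == "-"

    def test_duplicated_cassette_two_hits(self):
        rng = np.random.default_rng(11)
        cas = cassette(rng, F337, R337, 100)
        spacer = "".join(rng.choice(list("ACGT"), size=400))
        record = rec(cas + spacer + cas)
        # cap the product size below the inter-copy distance so only the
        # two per-copy amplicons remain (copies further apart than any
        # amplifiable product, as for true paralogs)
        hits = epcr((F337, R337), [record], EPCRParams(max_product=500))
        assert len(hits) == 2
        assert all(h.size == 139 for h in hits)
        # without the cap, the cross-copy pairing amplifies as well
        assert len(epcr((F337, R337), [record])) == 3

    def test_one_primer_only_no_product(self):
        rng = np.random.default_rng(12)
        record = rec("".join(rng.choice(list("ACGT"), size=300)) + F337
                     + "".join(rng.choice(list("ACGT"), size=300)))
        assert epcr((F337, R337), [record]) == []

    def test_size_bounds_respected(self):
        rng = np.random.default_rng(13)
        cas = cassette(rng, F337, R337, 961)  # size 1000
        record = rec(cas)
        assert epcr((F337, R337), [record], EPCRParams(max_product=999)) == []
        (hit,) = epcr((F337, R337), [record], EPCRParams(max_product=1000))
        assert hit.size == 1000

    def test_strand_involution_property(self):
        rng = np.random.default_rng(14)
        cas = cassette(rng, F337, R337, 120)
        bg = "".join(rng.choice(list("ACGT"), size=800))
        seq = bg[:300] + cas + bg[300:]
        fwd_hits = epcr((F337, R337), [rec(seq)])
        revc_hits = epcr((F337, R337), [rec(reverse_complement(seq))])
        n = len(seq)
        mirrored = sorted((n - h.end + 1, n - h.start + 1) for h in revc_hits)
        assert mirrored == sorted((h.start, h.end) for h in fwd_hits)
        assert {h.orientation for h in fwd_hits} != {h.orientation for h in revc_hits}


class TestEpcrBatch:
    def genotypes(self, rng, n=3):
        out = []
        for i in range(n):
            seq = cassette(rng, F337, R337, 100 + 2 * i)
            bg = "".join(rng.choice(list("ACGT"), size=500))
            out.append(
                GenotypeSet(genotype_id=f"g{i}", records=[rec(bg + seq, f"chr_{i}")])
            )
        return out

    def test_complete_cross_product(self):
        rng = np.random.default_rng(20)
        genos = self.genotypes(rng, 3)
        pairs = [("L1", F337, R337), ("L2", "G" * 18, "C" * 18)]
        table = epcr_batch(pairs, genos)
        assert set(table.hits) == {(l, g) for l in ("L1", "L2") for g in ("g0", "g1", "g2")}
        assert all(table.hits[("L2", g)] == [] for g in ("g0", "g1", "g2"))

    def test_asymmetric_flag_for_one_primer_genotype(self):
        rng = np.random.default_rng(21)
        genos = self.genotypes(rng, 2)
        # genotype with forward site only (a null allele situation)
        bg = "".join(rng.choice(list("ACGT"), size=500))
        genos.append(GenotypeSet(genotype_id="null", records=[rec(bg + F337 + bg[:80])]))
        table = epcr_batch([("L1", F337, R337)], genos)
        assert table.hits[("L1", "null")] == []
        assert table.asymmetric[("L1", "null")] is True
        assert table.asymmetric[("L1", "g0")] is False

    def test_duplicate_locus_ids_rejected(self):
        rng = np.random.default_rng(22)
        genos = self.genotypes(rng, 1)
        with pytest.raises(ValueError):
            epcr_batch([("L1", F337, R337), ("L1", F337, R337)], genos)

    def test_zero_mismatch_mode_reports_zero_counts(self):
        rng = np.random.default_rng(23)
        genos = self.genotypes(rng, 2)
        table = epcr_batch([("L1", F337, R337)], genos)
        for cell in table.hits.values():
            for h in cell:
                assert h.forward_mismatches == 0 and h.reverse_mismatches == 0
                assert h.size == h.end - h.start + 1


class TestOracleEquivalence:
    def build_genome(self, rng, n=10_000):
        f2, r2 = "TGCATGGACTACGGATTAGC", "CCATGATCGGTTACGGATCA"
        bg = "".join(rng.choice(list("ACGT"), size=n))
        pieces = [
            bg[:2000],
            cassette(rng, F337, R337, 150),
            bg[2000:5000],
            cassette(rng, f2, r2, 300),
            bg[5000:7000],
            reverse_complement(cassette(rng, f2, r2, 210)),
            bg[7000:],
        ]
        return "".join(pieces), [(F337, R337), (f2, r2)]

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_mode(self, seed):
        rng = np.random.default_rng(40 + seed)
        seq, pairs = self.build_genome(rng)
        record = rec(seq)
        for f, r in pairs:
            got = [
                (h.start, h.end, h.size, h.orientation, h.forward_mismatches,
                 h.reverse_mismatches)
                for h in epcr((f, r), [record])
            ]
            assert got == oracles.naive_epcr(f, r, seq)

    @pytest.mark.parametrize("seed", range(3))
    def test_mismatch_mode(self, seed):
        rng = np.random.default_rng(60 + seed)
        seq, pairs = self.build_genome(rng, n=6000)
        # degrade one planted forward site by an internal substitution
        i = seq.find(F337)
        seq = seq[:i + 4] + ("A" if seq[i + 4] != "A" else "T") + seq[i + 5:]
        record = rec(seq)
        params = EPCRParams(max_mismatch=1, three_prime_seed=5)
        for f, r in pairs:
            got = [
                (h.start, h.end, h.size, h.orientation, h.forward_mismatches,
                 h.reverse_mismatches)
                for h in epcr((f, r), [record], params)
            ]
            assert got == oracles.naive_epcr(f, r, seq, max_mm=1, seed=5)
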