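"""In-silico PCR: primer binding-site search and amplicon enumeration.

A primer pair (F, R) yields an amplicon wherever F anneals on one strand
and R anneals on the opposite strand downstream of it, with the implied
product size within bounds. On the plus strand the product reads
``F ... reverse_complement(R)``; the mirror orientation (the same pair
annealing on the minus strand) is searched symmetrically and hits that
coincide in coordinates are deduplicated.

Default stringency is exact matching (``max_mismatch=0``): same-species
re-sequencing templates are expected to carry intact primer sites, and a
locus that fails to amplify is informative (a null allele or missing
sequence). For heterologous/transferability use, a mismatch budget with a
mandatory exact 3'-terminal seed is available. N never matches any base,
including N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .sequence_io import GenotypeSet, SequenceRecord, reverse_complement

__all__ = [
    "EPCRParams",
    "Match",
    "AmpliconHit",
    "AmpliconTable",
    "find_matches",
    "epcr",
    "epcr_batch",
]


@dataclass(frozen=True)
class EPCRParams:
    max_mismatch: int = 0
    three_prime_seed: int = 5
    max_product: int = 5000
    min_product: int | None = None  # None -> sum of the two primer lengths

    def __post_init__(self) -> None:
        if not (0 <= self.max_mismatch <= 3):
            raise ValueError("max_mismatch must be in 0..3")
        if self.three_prime_seed < 0:
            raise ValueError("three_prime_seed must be >= 0")
        if self.min_product is not None and self.min_product > self.max_product:
            raise ValueError("min_product must be <= max_product")


@dataclass(frozen=True)
class Match:
    """One primer footprint (1-based inclusive) on a template record.

    ``strand='+'`` means the primer sequence itself appears on the plus
    strand; ``strand='-'`` means its reverse complement does (the primer
    anneals to the plus strand and extends leftward).
    """

    seq_id: str
    start: int
    end: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class AmpliconHit:
    genotype_id: str
    seq_id: str
    start: int
    end: int
    size: int
    orientation: str  # '+' pair on plus strand, '-' mirror orientation
    forward_mismatches: int
    reverse_mismatches: int

    def __post_init__(self) -> None:
        if self.size != self.end - self.start + 1:
            raise ValueError("amplicon size != end - start + 1")


@dataclass
class AmpliconTable:
    """Complete (locus x genotype) grid of hit lists plus asymmetric flags.

    Empty hit lists are preserved so "no product" is distinct from
    "not tested"; asymmetric is True where exactly one of the two primers
    matched anywhere in that genotype.
    """

    locus_ids: list[str]
    genotype_ids: list[str]
    hits: dict[tuple[str, str], list[AmpliconHit]] = field(default_factory=dict)
    asymmetric: dict[tuple[str, str], bool] = field(default_factory=dict)

    def cell(self, locus_id: str, genotype_id: str) -> list[AmpliconHit]:
        return self.hits[(locus_id, genotype_id)]


def _exact_positions(template: str, pattern: str) -> list[int]:
    """0-based start positions of exact occurrences (empty if pattern has N)."""
    if not pattern or "N" in pattern:
        return []
    out = []
    i = template.find(pattern)
    while i != -1:
        out.append(i)
        i = template.find(pattern, i + 1)
    return out


def _mismatch_positions(
    template: str, pattern: str, max_mm: int, seed: int, seed_at_end: bool
) -> list[tuple[int, int]]:
    """(0-based start, mismatches) with <= max_mm mismatches and an exact seed.

    ``seed_at_end`` selects whether the exact-seed window sits at the right
    (plus-strand 3' end) or left (reverse-complemented footprint) of the
    pattern. N in either sequence never matches.
    """
    n, m = len(template), len(pattern)
    if m == 0 or n < m:
        return []
    tarr = np.frombuffer(template.encode(), dtype=np.uint8)
    parr = np.frombuffer(pattern.encode(), dtype=np.uint8)
    nval = ord("N")
    npos = n - m + 1
    mism = np.zeros(npos, dtype=np.int32)
    seed_mism = np.zeros(npos, dtype=np.int32)
    seed_idx = range(m - seed, m) if seed_at_end else range(0, seed)
    seed_set = set(seed_idx)
    for j in range(m):
        win = tarr[j : j + npos]
        bad = (win != parr[j]) | (win == nval) | (parr[j] == nval)
        mism += bad
        if j in seed_set:
            seed_mism += bad
    keep = np.nonzero((mism <= max_mm) & (seed_mism == 0))[0]
    return [(int(i), int(mism[i])) for i in keep]


def find_matches(
    primer: str, record: SequenceRecord, params: EPCRParams | None = None
) -> list[Match]:
    """All annealing sites of ``primer`` on both strands of ``record``.

    At most ``max_mismatch`` mismatches overall and zero mismatches within
    the 3'-terminal ``three_prime_seed`` bases. Sorted by footprint start.
    """
    params = params if params is not None else EPCRParams()
    if len(primer) < params.three_prime_seed:
        raise ValueError("primer shorter than three_prime_seed")
    s = record.residues
    rc = reverse_complement(primer)
    out: list[Match] = []
    if params.max_mismatch == 0:
        for i in _exact_positions(s, primer):
            out.append(Match(record.id, i + 1, i + len(primer), "+", 0))
        for i in _exact_positions(s, rc):
            out.append(Match(record.id, i + 1, i + len(primer), "-", 0))
    else:
        seed = params.three_prime_seed
        for i, mm in _mismatch_positions(s, primer, params.max_mismatch, seed, True):
            out.append(Match(record.id, i + 1, i + len(primer), "+", mm))
        for i, mm in _mismatch_positions(s, rc, params.max_mismatch, seed, False):
            out.append(Match(record.id, i + 1, i + len(primer), "-", mm))
    out.sort(key=lambda m: (m.start, m.strand))
    return out


def _pair_hits(
    forward: str,
    reverse: str,
    record: SequenceRecord,
    params: EPCRParams,
    genotype_id: str,
) -> tuple[list[AmpliconHit], bool, bool]:
    """Hits on one record plus whether each primer matched anywhere."""
    f_matches = find_matches(forward, record, params)
    r_matches = find_matches(reverse, record, params)
    f_plus = [m for m in f_matches if m.strand == "+"]
    f_minus = [m for m in f_matches if m.strand == "-"]
    r_plus = [m for m in r_matches if m.strand == "+"]
    r_minus = [m for m in r_matches if m.strand == "-"]

    min_product = (
        params.min_product
        if params.min_product is not None
        else len(forward) + len(reverse)
    )
    seen: set[tuple[str, int, int]] = set()
    hits: list[AmpliconHit] = []

    def emit(start, end, orientation, fm, rm):
        size = end - start + 1
        if not (min_product <= size <= params.max_product):
            return
        key = (record.id, start, end)
        if key in seen:
            return
        seen.add(key)
        hits.append(
            AmpliconHit(
                genotype_id=genotype_id,
                seq_id=record.id,
                start=start,
                end=end,
                size=size,
                orientation=orientation,
                forward_mismatches=fm,
                reverse_mismatches=rm,
            )
        )

    # plus orientation: F on plus, rc(R) downstream (R minus-strand match)
    r_minus_sorted = sorted(r_minus, key=lambda m: m.start)
    for f in f_plus:
        for r in r_minus_sorted:
            if r.start <= f.end:
                continue
            if r.end - f.start + 1 > params.max_product:
                break
            emit(f.start, r.end, "+", f.mismatches, r.mismatches)
    # mirror orientation: R on plus, rc(F) downstream (F minus-strand match)
    f_minus_sorted = sorted(f_minus, key=lambda m: m.start)
    for r in r_plus:
        for f in f_minus_sorted:
            if f.start <= r.end:
                continue
            if f.end - r.start + 1 > params.max_product:
                break
            emit(r.start, f.end, "-", f.mismatches, r.mismatches)

    hits.sort(key=lambda h: (h.seq_id, h.start, h.end))
    f_any = bool(f_matches)
    r_any = bool(r_matches)
    return hits, f_any, r_any


def epcr(
    pair,
    records: Iterable[SequenceRecord],
    params: EPCRParams | None = None,
    genotype_id: str = "",
) -> list[AmpliconHit]:
    """All amplicons of one primer pair over a set of template records.

    ``pair`` is anything with ``forward``/``reverse`` attributes, or a
    (forward, reverse) sequence of strings.
    """
    params = params if params is not None else EPCRParams()
    forward, reverse = _pair_seqs(pair)
    if not forward or not reverse:
        raise ValueError("both primer sequences must be non-empty")
    hits: list[AmpliconHit] = []
    for rec in records:
        h, _, _ = _pair_hits(forward, reverse, rec, params, genotype_id)
        hits.extend(h)
    hits.sort(key=lambda h: (h.seq_id, h.start, h.end))
    return hits


def _pair_seqs(pair) -> tuple[str, str]:
    if hasattr(pair, "forward") and hasattr(pair, "reverse"):
        return pair.forward, pair.reverse
    f, r = pair
    return f, r


def epcr_batch(
    pairs: Sequence[tuple[str, str, str]] | Mapping[str, tuple[str, str]],
    genotypes: Sequence[GenotypeSet],
    params: EPCRParams | None = None,
) -> AmpliconTable:
    """Complete amplicon table over (locus, genotype) cross product.

    ``pairs``: iterable of (locus_id, forward, reverse) or a mapping
    locus_id -> (forward, reverse). Duplicate locus_ids are an error.
    """
    params = params if params is not None else EPCRParams()
    if isinstance(pairs, Mapping):
        pair_list = [(lid, f, r) for lid, (f, r) in pairs.items()]
    else:
        pair_list = list(pairs)
    if not pair_list:
        raise ValueError("epcr_batch requires at least one primer pair")
    genotypes = list(genotypes)
    if not genotypes:
        raise ValueError("epcr_batch requires at least one genotype")
    lids = [lid for lid, _, _ in pair_list]
    if len(lids) != len(set(lids)):
        raise ValueError("duplicate locus_ids in primer pairs")

    table = AmpliconTable(locus_ids=lids, genotype_ids=[g.genotype_id for g in genotypes])
    for lid, fwd, rev in pair_list:
        for geno in genotypes:
            cell: list[AmpliconHit] = []
            f_any = r_any = False
            for rec in geno.records:
                h, fa, ra = _pair_hits(fwd, rev, rec, params, geno.genotype_id)
                cell.extend(h)
                f_any = f_any or fa
                r_any = r_any or ra
            cell.sort(key=lambda h: (h.seq_id, h.start, h.end))
            table.hits[(lid, geno.genotype_id)] = cell
            table.asymmetric[(lid, geno.genotype_id)] = f_any != r_any
    return table


def amplicon_table_frame(table: AmpliconTable):
    """Long-format TSV-ready view of an amplicon table."""
    import pandas as pd

    rows = []
    for lid in table.locus_ids:
        for gid in table.genotype_ids:
            cell = table.hits[(lid, gid)]
            asym = table.asymmetric[(lid, gid)]
            if not cell:
                rows.append(
                    {
                        "locus_id": lid,
                        "genotype_id": gid,
                        "seq_id": "",
                        "start": -1,
                        "end": -1,
                        "size": -1,
                        "orientation": "",
                        "mismatches_f": -1,
                        "mismatches_r": -1,
                        "asymmetric_flag": asym,
                    }
                )
            for h in cell:
                rows.append(
                    {
                        "locus_id": lid,
                        "genotype_id": gid,
                        "seq_id": h.seq_id,
                        "start": h.start,
                        "end": h.end,
                        "size": h.size,
                        "orientation": h.orientation,
                        "mismatches_f": h.forward_mismatches,
                        "mismatches_r": h.reverse_mismatches,
                        "asymmetric_flag": asym,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "locus_id",
            "genotype_id",
            "seq_id",
            "start",
            "end",
            "size",
            "orientation",
            "mismatches_f",
            "mismatches_r",
            "asymmetric_flag",
        ],
    )
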