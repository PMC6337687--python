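"""Locus-level calling: allele-length polymorphism, transferability and
genic (intron-junction) primer screening.

A locus is genotyped by the size of its single e-PCR product per genotype.
Classification uses only genotypes with exactly one product:

* ``POLYMORPHIC``  — >= 2 such genotypes, >= 2 distinct product sizes;
* ``MONOMORPHIC``  — >= 2 such genotypes, all sizes equal;
* ``INSUFFICIENT`` — fewer than 2 genotypes amplified cleanly;
* ``PARALOGOUS``   — any genotype yielded >= 2 products (multi-locus
  amplification confounds length genotyping, so this status takes
  precedence over all others and such loci should be discarded before
  wet-lab validation).

Genotypes with no product are reported as MISSING (possible null allele or
missing sequence) but never make a locus polymorphic on their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .epcr import AmpliconHit, AmpliconTable, EPCRParams, _pair_hits, epcr
from .sequence_io import GenotypeSet, SequenceRecord

__all__ = [
    "MISSING",
    "LocusCall",
    "PolymorphismReport",
    "TransferabilityReport",
    "GenicEvaluation",
    "call_locus",
    "detect_polymorphism",
    "evaluate_transferability",
    "evaluate_genic_primers",
]

MISSING = None

STATUSES = ("POLYMORPHIC", "MONOMORPHIC", "INSUFFICIENT", "PARALOGOUS")


@dataclass
class LocusCall:
    locus_id: str
    # genotype -> size (int), MISSING (None), or list of sizes (multi)
    alleles: dict[str, object]
    status: str
    distinct_allele_sizes: list[int]

    def allele_str(self, genotype_id: str) -> str:
        a = self.alleles[genotype_id]
        if a is MISSING:
            return "NA"
        if isinstance(a, list):
            return "MULTI:" + ";".join(str(s) for s in a)
        return str(a)


@dataclass
class PolymorphismReport:
    calls: list[LocusCall]
    genotype_ids: list[str]
    summary: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.summary:
            self.summary = {s: 0 for s in STATUSES}
            for c in self.calls:
                self.summary[c.status] += 1
        if sum(self.summary.values()) != len(self.calls):
            raise ValueError("summary counts do not sum to number of loci")

    def matrix(self) -> pd.DataFrame:
        rows = [
            {"locus_id": c.locus_id, **{g: c.allele_str(g) for g in self.genotype_ids}}
            for c in self.calls
        ]
        return pd.DataFrame(rows, columns=["locus_id", *self.genotype_ids])

    def status_table(self) -> pd.DataFrame:
        rows = [
            {
                "locus_id": c.locus_id,
                "status": c.status,
                "n_alleles": len(c.distinct_allele_sizes),
                "allele_sizes": ";".join(str(s) for s in c.distinct_allele_sizes),
                "note": "",
            }
            for c in self.calls
        ]
        return pd.DataFrame(
            rows, columns=["locus_id", "status", "n_alleles", "allele_sizes", "note"]
        )


def call_locus(
    locus_id: str,
    per_genotype_hits: Mapping[str, Sequence[AmpliconHit] | Sequence[int]],
) -> LocusCall:
    """Classify one locus from its per-genotype hit (or size) lists.

    Accepts either AmpliconHit lists or plain size lists per genotype;
    genotype order is preserved from the input mapping.
    """
    alleles: dict[str, object] = {}
    multi = False
    singles: list[int] = []
    for gid, hits in per_genotype_hits.items():
        sizes = [h.size if isinstance(h, AmpliconHit) else int(h) for h in hits]
        if len(sizes) == 0:
            alleles[gid] = MISSING
        elif len(sizes) == 1:
            alleles[gid] = sizes[0]
            singles.append(sizes[0])
        else:
            alleles[gid] = sorted(sizes)
            multi = True
    distinct = sorted(set(singles))
    if multi:
        status = "PARALOGOUS"
    elif len(singles) < 2:
        status = "INSUFFICIENT"
    elif len(distinct) >= 2:
        status = "POLYMORPHIC"
    else:
        status = "MONOMORPHIC"
    return LocusCall(
        locus_id=locus_id, alleles=alleles, status=status, distinct_allele_sizes=distinct
    )


def detect_polymorphism(table: AmpliconTable) -> PolymorphismReport:
    """One LocusCall per locus of a complete amplicon table."""
    calls = [
        call_locus(lid, {gid: table.hits[(lid, gid)] for gid in table.genotype_ids})
        for lid in table.locus_ids
    ]
    return PolymorphismReport(calls=calls, genotype_ids=list(table.genotype_ids))


@dataclass
class TransferabilityReport:
    """Per-locus disposition of a marker panel against a host species genome.

    dispositions: locus_id -> (code, size-or-None) where code is one of
    TRANSFERABLE, FILTERED_SIZE, FILTERED_ASYMMETRIC, ABSENT.
    """

    dispositions: dict[str, tuple[str, int | None]]
    size_cutoff: int

    @property
    def count_transferable(self) -> int:
        return sum(1 for c, _ in self.dispositions.values() if c == "TRANSFERABLE")

    def table(self) -> pd.DataFrame:
        rows = [
            {"locus_id": lid, "disposition": code, "size": "" if s is None else s}
            for lid, (code, s) in self.dispositions.items()
        ]
        return pd.DataFrame(rows, columns=["locus_id", "disposition", "size"])


def evaluate_transferability(
    pairs: Sequence[tuple[str, str, str]],
    host: GenotypeSet,
    size_cutoff: int = 500,
    params: EPCRParams | None = None,
) -> TransferabilityReport:
    """Screen primer pairs against a heterologous host genome.

    A locus is TRANSFERABLE when a valid both-primer product of size
    <= ``size_cutoff`` exists; products only above the cutoff are
    FILTERED_SIZE; exactly one primer matching anywhere is
    FILTERED_ASYMMETRIC; otherwise ABSENT.
    """
    params = params if params is not None else EPCRParams()
    dispositions: dict[str, tuple[str, int | None]] = {}
    for lid, fwd, rev in pairs:
        hits: list[AmpliconHit] = []
        f_any = r_any = False
        for rec in host.records:
            h, fa, ra = _pair_hits(fwd, rev, rec, params, host.genotype_id)
            hits.extend(h)
            f_any = f_any or fa
            r_any = r_any or ra
        ok_sizes = sorted(h.size for h in hits if h.size <= size_cutoff)
        if ok_sizes:
            dispositions[lid] = ("TRANSFERABLE", ok_sizes[0])
        elif hits:
            dispositions[lid] = ("FILTERED_SIZE", min(h.size for h in hits))
        elif f_any != r_any:
            dispositions[lid] = ("FILTERED_ASYMMETRIC", None)
        else:
            dispositions[lid] = ("ABSENT", None)
    return TransferabilityReport(dispositions=dispositions, size_cutoff=size_cutoff)


@dataclass
class GenicVerdict:
    locus_id: str
    expected_size: int | None
    genomic_sizes: list[int]
    verdict: str  # OK | INTRON_CONTAINING | JUNCTION_PRIMER |
    #               NO_GENOMIC_PRODUCT_OVERSIZE | INPUT_ERROR
    delta: int | None = None
    note: str = ""


@dataclass
class GenicEvaluation:
    verdicts: list[GenicVerdict]

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "locus_id": v.locus_id,
                "expected_size": "" if v.expected_size is None else v.expected_size,
                "genomic_sizes": ";".join(str(s) for s in v.genomic_sizes),
                "verdict": v.verdict,
                "delta": "" if v.delta is None else v.delta,
                "note": v.note,
            }
            for v in self.verdicts
        ]
        return pd.DataFrame(
            rows,
            columns=["locus_id", "expected_size", "genomic_sizes", "verdict", "delta", "note"],
        )


def evaluate_genic_primers(
    pairs: Sequence[tuple[str, str, str]],
    transcripts: Sequence[SequenceRecord],
    genome: GenotypeSet,
    params: EPCRParams | None = None,
    oversize_search_factor: int = 10,
) -> GenicEvaluation:
    """Screen transcript-designed primers against the genomic template.

    Pairs designed on mRNA can fail on genomic DNA when the product spans
    an intron (product inflated by the intron length, possibly beyond any
    amplifiable size) or a primer sits on an exon-exon junction (no
    genomic binding site at all). Verdicts:

    * OK                  — genomic product equals the transcript size;
    * INTRON_CONTAINING   — a genomic product exceeds it (delta = bp excess);
    * NO_GENOMIC_PRODUCT_OVERSIZE — no product within max_product, but one
      appears when the size cap is raised ``oversize_search_factor``-fold
      (an intron pushed the product out of range);
    * JUNCTION_PRIMER     — no genomic product at any searched size;
    * INPUT_ERROR         — the pair has no (or no unique) transcript product.
    """
    params = params if params is not None else EPCRParams()
    wide = EPCRParams(
        max_mismatch=params.max_mismatch,
        three_prime_seed=params.three_prime_seed,
        max_product=params.max_product * oversize_search_factor,
        min_product=params.min_product,
    )
    verdicts: list[GenicVerdict] = []
    for lid, fwd, rev in pairs:
        t_hits = epcr((fwd, rev), transcripts, params)
        t_sizes = sorted({h.size for h in t_hits})
        if len(t_sizes) == 0:
            verdicts.append(
                GenicVerdict(lid, None, [], "INPUT_ERROR", note="no transcript product")
            )
            continue
        if len(t_sizes) > 1:
            verdicts.append(
                GenicVerdict(
                    lid, None, [], "INPUT_ERROR", note="ambiguous transcript product"
                )
            )
            continue
        expected = t_sizes[0]
        g_hits = epcr((fwd, rev), genome.records, params)
        g_sizes = sorted(h.size for h in g_hits)
        if g_sizes:
            over = [s for s in g_sizes if s > expected]
            if over:
                verdicts.append(
                    GenicVerdict(
                        lid, expected, g_sizes, "INTRON_CONTAINING", delta=max(over) - expected
                    )
                )
            else:
                verdicts.append(GenicVerdict(lid, expected, g_sizes, "OK"))
            continue
        g_wide = epcr((fwd, rev), genome.records, wide)
        if g_wide:
            sizes = sorted(h.size for h in g_wide)
            verdicts.append(
                GenicVerdict(
                    lid,
                    expected,
                    sizes,
                    "NO_GENOMIC_PRODUCT_OVERSIZE",
                    delta=max(sizes) - expected,
                )
            )
        else:
            verdicts.append(GenicVerdict(lid, expected, [], "JUNCTION_PRIMER"))
    return GenicEvaluation(verdicts=verdicts)
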