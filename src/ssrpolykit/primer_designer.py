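"""Primer-pair design from the flanks of a mined SSR locus.

For each locus, 500 bp of upstream and downstream flank (clipped at the
sequence ends, never padded) are extracted; all acceptable primer windows
are enumerated — forward primers wholly in the upstream flank, reverse
primers wholly in the downstream flank, so the repeat tract is always
inside the product and product-size differences between genotypes reflect
tract-length variation alone. Candidate windows pass hard filters
(length, Tm, GC, poly-X runs, N content, 3'-anchored self-complementarity)
and surviving pairs are ranked by a penalty that rewards primers near the
optimum length and melting temperature with matched Tm:

    penalty = |Tm_f - Tm_opt| + |Tm_r - Tm_opt|
              + 0.5 (|len_f - len_opt| + |len_r - len_opt|)
              + |Tm_f - Tm_r|

The default melting-temperature model is the salt-adjusted GC formula

    Tm = 81.5 + 16.6 log10([Na+]) + 0.41 (%GC) - 600 / length

which is deterministic and dependency-free; ``method="wallace"`` switches
to the Wallace rule 2(A+T) + 4(G+C) as a cross-check, and ``tm_function``
on :func:`design_primers` allows swapping in any other model (e.g. a
nearest-neighbor implementation, whose numbers will diverge from these).
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .sequence_io import SequenceRecord, reverse_complement
from .ssr_miner import SSRLocus

__all__ = [
    "PrimerParams",
    "FlankedLocus",
    "PrimerPair",
    "PrimerSet",
    "extract_flanks",
    "gc_content",
    "melting_temperature",
    "candidate_ok",
    "design_primers",
]


@dataclass(frozen=True)
class PrimerParams:
    flank_len: int = 500
    n_pairs: int = 5
    len_min: int = 18
    len_opt: int = 20
    len_max: int = 24
    tm_min: float = 57.0
    tm_opt: float = 60.0
    tm_max: float = 63.0
    gc_min: float = 0.20
    gc_max: float = 0.80
    product_min: int = 100
    product_max: int = 300
    max_polyx: int = 4
    max_3prime_selfcomp: int = 3
    na_conc: float = 0.05
    max_tm_diff: float = 5.0

    def __post_init__(self) -> None:
        if not (self.len_min <= self.len_opt <= self.len_max):
            raise ValueError("need len_min <= len_opt <= len_max")
        if not (self.tm_min <= self.tm_opt <= self.tm_max):
            raise ValueError("need tm_min <= tm_opt <= tm_max")
        if self.product_min < self.len_min * 2:
            raise ValueError("product_min must be >= 2 * len_min")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")


@dataclass(frozen=True)
class FlankedLocus:
    """A locus with its extracted flanks; template = upstream+tract+downstream."""

    locus: SSRLocus
    upstream: str
    downstream: str
    tract: str

    @property
    def template(self) -> str:
        return self.upstream + self.tract + self.downstream

    @property
    def template_start(self) -> int:
        """1-based position on the source record of template position 1."""
        return self.locus.start - len(self.upstream)


@dataclass(frozen=True)
class PrimerPair:
    """One ranked pair; coordinates are 1-based on the locus template.

    ``forward`` is read 5'->3' on the plus strand; ``reverse`` is the
    reverse complement of a template window right of the repeat tract.
    expected_product_size spans the forward 5' end through the reverse
    window's rightmost template base, inclusive.
    """

    forward: str
    reverse: str
    tm_forward: float
    tm_reverse: float
    gc_forward: float
    gc_reverse: float
    expected_product_size: int
    penalty: float
    rank: int
    forward_start: int
    reverse_end: int

    @property
    def forward_end(self) -> int:
        return self.forward_start + len(self.forward) - 1

    @property
    def reverse_start(self) -> int:
        return self.reverse_end - len(self.reverse) + 1


@dataclass
class PrimerSet:
    locus_id: str
    pairs: list[PrimerPair] = field(default_factory=list)
    failure_reason: str = ""


def extract_flanks(
    record: SequenceRecord, locus: SSRLocus, flank_len: int = 500
) -> FlankedLocus:
    """Flanks of up to ``flank_len`` bp each side, clipped at record bounds."""
    if locus.start < 1 or locus.end > record.length:
        raise ValueError(
            f"locus {locus.start}..{locus.end} outside record {record.id!r} "
            f"(length {record.length})"
        )
    s = record.residues
    up_start = max(1, locus.start - flank_len)
    down_end = min(record.length, locus.end + flank_len)
    return FlankedLocus(
        locus=locus,
        upstream=s[up_start - 1 : locus.start - 1],
        tract=s[locus.start - 1 : locus.end],
        downstream=s[locus.end : down_end],
    )


def gc_content(seq: str) -> float:
    """(G + C) / length; N counts in the denominator only."""
    if not seq:
        raise ValueError("gc_content of empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def melting_temperature(
    seq: str, na_conc: float = 0.05, method: str = "gc"
) -> float:
    """Primer melting temperature in deg C.

    ``gc``: salt-adjusted GC formula (default model of the package);
    ``wallace``: 2(A+T) + 4(G+C), the quick-and-dirty cross-check rule.
    """
    if "N" in seq:
        raise ValueError("melting_temperature of sequence containing N")
    if len(seq) < 8:
        raise ValueError("melting_temperature needs length >= 8")
    if method == "gc":
        gc_pct = 100.0 * gc_content(seq)
        return 81.5 + 16.6 * math.log10(na_conc) + 0.41 * gc_pct - 600.0 / len(seq)
    if method == "wallace":
        at = seq.count("A") + seq.count("T")
        gc = seq.count("G") + seq.count("C")
        return 2.0 * at + 4.0 * gc
    raise ValueError(f"unknown Tm method {method!r}")


def _max_mononucleotide_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _three_prime_selfcomp(seq: str) -> int:
    """Longest 3'-anchored suffix that can anneal to another copy of the primer.

    The suffix anneals if it appears (5'->3') within the primer's reverse
    complement; returns the longest such suffix length.
    """
    rc = reverse_complement(seq)
    best = 0
    for r in range(1, len(seq) + 1):
        if seq[-r:] in rc:
            best = r
        else:
            break
    return best


def candidate_ok(
    seq: str,
    params: PrimerParams,
    tm_function: Callable[[str], float] | None = None,
) -> tuple[bool, str]:
    """Hard filters for one primer candidate; returns (accept, reason)."""
    if "N" in seq:
        return False, "contains N"
    if not (params.len_min <= len(seq) <= params.len_max):
        return False, "length"
    if _max_mononucleotide_run(seq) > params.max_polyx:
        return False, "poly-X"
    gc = gc_content(seq)
    if not (params.gc_min <= gc <= params.gc_max):
        return False, "GC content"
    tm = (
        tm_function(seq)
        if tm_function is not None
        else melting_temperature(seq, params.na_conc)
    )
    if not (params.tm_min <= tm <= params.tm_max):
        return False, "Tm"
    if _three_prime_selfcomp(seq) > params.max_3prime_selfcomp:
        return False, "3' self-complementarity"
    return True, "ok"


def _enumerate_candidates(
    flank: str,
    params: PrimerParams,
    tm_fn: Callable[[str], float],
    offset: int,
    reverse: bool,
):
    """Accepted windows in one flank.

    Yields (template_start, template_end, primer_seq, tm, gc). ``offset`` is
    the 1-based template position of flank[0]. For the reverse side the
    primer is the reverse complement of the window.
    """
    out = []
    m = len(flank)
    for length in range(params.len_min, params.len_max + 1):
        for i in range(0, m - length + 1):
            window = flank[i : i + length]
            primer = reverse_complement(window) if reverse else window
            ok, _ = candidate_ok(primer, params, tm_function=tm_fn)
            if ok:
                out.append(
                    (
                        offset + i,
                        offset + i + length - 1,
                        primer,
                        tm_fn(primer),
                        gc_content(primer),
                    )
                )
    return out


def design_primers(
    flanked: FlankedLocus,
    params: PrimerParams | None = None,
    tm_function: Callable[[str], float] | None = None,
) -> PrimerSet:
    """Up to ``n_pairs`` ranked pairs for one flanked locus.

    Pairs must have product size within [product_min, product_max] and
    |Tm_f - Tm_r| <= max_tm_diff; the returned pairs have pairwise distinct
    forward 5' positions (five genuine alternatives, not near-duplicates)
    and are sorted by penalty with the deterministic tie-break
    (penalty, forward start, reverse start).
    """
    params = params if params is not None else PrimerParams()
    tm_fn = tm_function or (lambda s: melting_temperature(s, params.na_conc))
    locus_id = f"{flanked.locus.seq_id}:{flanked.locus.start}-{flanked.locus.end}"

    if len(flanked.upstream) < params.len_min or len(flanked.downstream) < params.len_min:
        return PrimerSet(locus_id=locus_id, failure_reason="flank too short")

    up_offset = 1
    down_offset = len(flanked.upstream) + len(flanked.tract) + 1
    fwd = _enumerate_candidates(flanked.upstream, params, tm_fn, up_offset, False)
    rev = _enumerate_candidates(flanked.downstream, params, tm_fn, down_offset, True)
    if not fwd or not rev:
        return PrimerSet(locus_id=locus_id, failure_reason="no acceptable candidates")

    rev.sort(key=lambda c: c[1])  # by template end
    rev_ends = [c[1] for c in rev]

    scored = []
    for fstart, fend, fseq, ftm, fgc in fwd:
        lo = bisect_left(rev_ends, fstart + params.product_min - 1)
        hi = bisect_right(rev_ends, fstart + params.product_max - 1)
        for rstart, rend, rseq, rtm, rgc in rev[lo:hi]:
            if abs(ftm - rtm) > params.max_tm_diff:
                continue
            size = rend - fstart + 1
            penalty = (
                abs(ftm - params.tm_opt)
                + abs(rtm - params.tm_opt)
                + 0.5 * (abs(len(fseq) - params.len_opt) + abs(len(rseq) - params.len_opt))
                + abs(ftm - rtm)
            )
            scored.append(
                (penalty, fstart, rstart, fseq, rseq, ftm, rtm, fgc, rgc, size, rend)
            )
    if not scored:
        return PrimerSet(locus_id=locus_id, failure_reason="no compatible pair")

    scored.sort(key=lambda t: (t[0], t[1], t[2]))
    pairs: list[PrimerPair] = []
    used_fstarts: set[int] = set()
    for penalty, fstart, rstart, fseq, rseq, ftm, rtm, fgc, rgc, size, rend in scored:
        if fstart in used_fstarts:
            continue
        used_fstarts.add(fstart)
        pairs.append(
            PrimerPair(
                forward=fseq,
                reverse=rseq,
                tm_forward=ftm,
                tm_reverse=rtm,
                gc_forward=fgc,
                gc_reverse=rgc,
                expected_product_size=size,
                penalty=penalty,
                rank=len(pairs) + 1,
                forward_start=fstart,
                reverse_end=rend,
            )
        )
        if len(pairs) == params.n_pairs:
            break
    return PrimerSet(locus_id=locus_id, pairs=pairs)


def primer_sets_table(sets: Sequence[PrimerSet]):
    """Tabular TSV-ready view; also the external-primer input dialect."""
    import pandas as pd

    rows = []
    for ps in sets:
        for p in ps.pairs:
            rows.append(
                {
                    "locus_id": ps.locus_id,
                    "rank": p.rank,
                    "forward": p.forward,
                    "reverse": p.reverse,
                    "tm_f": round(p.tm_forward, 2),
                    "tm_r": round(p.tm_reverse, 2),
                    "gc_f": round(p.gc_forward, 4),
                    "gc_r": round(p.gc_reverse, 4),
                    "product_size": p.expected_product_size,
                    "penalty": round(p.penalty, 4),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "locus_id",
            "rank",
            "forward",
            "reverse",
            "tm_f",
            "tm_r",
            "gc_f",
            "gc_r",
            "product_size",
            "penalty",
        ],
    )
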