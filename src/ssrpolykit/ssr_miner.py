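"""Perfect microsatellite (SSR) detection and compound-locus merging.

The miner reports every maximal tandem run of a 1-6 bp repeat unit that
meets a per-unit-length repeat-count threshold, in the style of MISA:

* a run is *maximal* — it cannot be extended left or right by one unit;
* the reported start is the leftmost position of the maximal run
  (left-anchored), and trailing partial units are not counted;
* the motif is reported as first encountered at the tract start
  ((AC)n starting on the A is reported as AC, never CA);
* a motif that is itself a whole-number repetition of a shorter unit
  (e.g. ATAT) is never reported — the shorter unit's run wins;
* N never matches anything, so a tract cannot span an N.

Nearby tracts (inter-tract gap <= ``max_interrupt``) are merged into one
compound locus of type ``c`` whose constituent motifs are kept in a
free-text note; downstream primer design treats any locus as an interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .sequence_io import SequenceRecord

__all__ = [
    "MiningConfig",
    "SSRLocus",
    "find_perfect_ssrs",
    "merge_compound",
    "mine_genome",
    "loci_table",
    "write_loci_tsv",
    "read_loci_tsv",
]

#: MISA-distributed default thresholds: unit length -> minimum repeat count.
DEFAULT_MIN_REPEATS: Mapping[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}
DEFAULT_MAX_INTERRUPT = 100


@dataclass(frozen=True)
class MiningConfig:
    min_repeats: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )
    max_interrupt: int = DEFAULT_MAX_INTERRUPT

    def __post_init__(self) -> None:
        for k in range(1, 7):
            if k not in self.min_repeats:
                raise ValueError(f"min_repeats must cover unit length {k}")
            if self.min_repeats[k] < 2:
                raise ValueError("every min_repeats threshold must be >= 2")
        if self.max_interrupt < 0:
            raise ValueError("max_interrupt must be >= 0")


@dataclass(frozen=True)
class SSRLocus:
    """One mined repeat tract (1-based, inclusive coordinates).

    For perfect types ``p1``..``p6``: tract_length == end - start + 1
    == repeat_count * len(motif). Compound loci (type ``c``) record only
    the span; their constituent motifs live in ``note``.
    """

    seq_id: str
    start: int
    end: int
    motif: str
    repeat_count: int
    ssr_type: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad coordinates {self.start}..{self.end}")
        if self.ssr_type.startswith("p"):
            if "N" in self.motif:
                raise ValueError("motif may not contain N")
            k = len(self.motif)
            if self.ssr_type != f"p{k}":
                raise ValueError("ssr_type does not match motif length")
            if self.tract_length != self.repeat_count * k:
                raise ValueError("tract_length != repeat_count * unit length")
            if _smallest_period(self.motif) != k:
                raise ValueError(f"motif {self.motif!r} is not primitive")
        elif self.ssr_type != "c":
            raise ValueError(f"unknown ssr_type {self.ssr_type!r}")

    @property
    def tract_length(self) -> int:
        return self.end - self.start + 1

    @property
    def unit_length(self) -> int:
        return len(self.motif)


def _smallest_period(motif: str) -> int:
    k = len(motif)
    for p in range(1, k):
        if k % p == 0 and motif == motif[:p] * (k // p):
            return p
    return k


def find_perfect_ssrs(record: SequenceRecord, config: MiningConfig) -> list[SSRLocus]:
    """All maximal perfect tracts in ``record`` meeting the thresholds.

    Scans, for each unit length k, the maximal regions of period k
    (positions t with s[t] == s[t+k], N never matching); each region yields
    at most one left-anchored tract of whole units. Tracts of a longer unit
    wholly contained in a shorter unit's tract are suppressed.
    """
    s = record.residues
    n = len(s)
    found: list[SSRLocus] = []
    for k in range(1, 7):
        thr = config.min_repeats[k]
        t = 0
        limit = n - k  # t ranges over 0 .. n-k-1
        while t < limit:
            c = s[t]
            if c != "N" and c == s[t + k]:
                a = t
                t += 1
                while t < limit and s[t] != "N" and s[t] == s[t + k]:
                    t += 1
                # period-k region covers a .. (t-1)+k ; whole units only
                count = (t + k - a) // k
                if count >= thr:
                    motif = s[a : a + k]
                    if "N" not in motif and _smallest_period(motif) == k:
                        found.append(
                            SSRLocus(
                                seq_id=record.id,
                                start=a + 1,
                                end=a + count * k,
                                motif=motif,
                                repeat_count=count,
                                ssr_type=f"p{k}",
                            )
                        )
            else:
                t += 1
    # shorter-unit-wins suppression: drop any tract contained in the span of
    # a tract with a strictly shorter unit
    found.sort(key=lambda L: (L.start, L.unit_length))
    kept: list[SSRLocus] = []
    for L in found:
        contained = any(
            M.unit_length < L.unit_length and M.start <= L.start and L.end <= M.end
            for M in found
            if M is not L
        )
        if not contained:
            kept.append(L)
    return kept


def merge_compound(loci: Sequence[SSRLocus], max_interrupt: int) -> list[SSRLocus]:
    """Merge chains of perfect tracts with pairwise gaps <= ``max_interrupt``.

    Input must be perfect tracts on one sequence, sorted by start. Isolated
    tracts pass through unchanged; each maximal chain of >= 2 tracts becomes
    one compound locus (type ``c``) spanning first start to last end.
    """
    if not loci:
        return []
    seq_ids = {L.seq_id for L in loci}
    if len(seq_ids) > 1:
        raise ValueError("merge_compound requires loci from a single sequence")
    for prev, cur in zip(loci, loci[1:]):
        if cur.start < prev.start:
            raise ValueError("merge_compound requires loci sorted by start")
    for L in loci:
        if not L.ssr_type.startswith("p"):
            raise ValueError("merge_compound requires perfect tracts only")

    out: list[SSRLocus] = []
    chain: list[SSRLocus] = [loci[0]]
    for cur in loci[1:]:
        gap = cur.start - chain[-1].end - 1
        if gap <= max_interrupt:
            chain.append(cur)
        else:
            out.append(_collapse(chain))
            chain = [cur]
    out.append(_collapse(chain))
    return out


def _collapse(chain: list[SSRLocus]) -> SSRLocus:
    if len(chain) == 1:
        return chain[0]
    note = "+".join(f"({L.motif}){L.repeat_count}" for L in chain)
    return SSRLocus(
        seq_id=chain[0].seq_id,
        start=chain[0].start,
        end=chain[-1].end,
        motif="",
        repeat_count=0,
        ssr_type="c",
        note=note,
    )


def mine_genome(
    records: Iterable[SequenceRecord], config: MiningConfig | None = None
) -> list[SSRLocus]:
    """Per-record mining driver: perfect tracts merged into compounds.

    Output order is deterministic: record order, then start position.
    """
    config = config if config is not None else MiningConfig()
    records = list(records)
    if not records:
        raise ValueError("mine_genome requires at least one record")
    out: list[SSRLocus] = []
    for rec in records:
        perfect = find_perfect_ssrs(rec, config)
        out.extend(merge_compound(perfect, config.max_interrupt))
    return out


def loci_table(loci: Sequence[SSRLocus]) -> pd.DataFrame:
    """Tabular view with stable column order; locus_id = seq_id + ordinal."""
    counters: dict[str, int] = {}
    rows = []
    for L in loci:
        counters[L.seq_id] = counters.get(L.seq_id, 0) + 1
        rows.append(
            {
                "locus_id": f"{L.seq_id}_{counters[L.seq_id]}",
                "seq_id": L.seq_id,
                "ssr_type": L.ssr_type,
                "motif": L.motif if L.ssr_type != "c" else L.note,
                "repeat_count": L.repeat_count,
                "tract_length": L.tract_length,
                "start": L.start,
                "end": L.end,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "locus_id",
            "seq_id",
            "ssr_type",
            "motif",
            "repeat_count",
            "tract_length",
            "start",
            "end",
        ],
    )


def write_loci_tsv(loci: Sequence[SSRLocus], path) -> None:
    loci_table(loci).to_csv(path, sep="\t", index=False)


def read_loci_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
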