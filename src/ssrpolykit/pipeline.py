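"""High-level drivers tying mining, design, e-PCR and calling together.

These are the functions the CLI subcommands and the example scripts wrap:
each one consumes/produces the package's domain objects plus plain TSV
files, with locus ids assigned once (``seq_id + "_" + ordinal``) and used
consistently across every downstream table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .epcr import AmpliconTable, EPCRParams, epcr_batch
from .polymorphism import PolymorphismReport, detect_polymorphism
from .primer_designer import (
    FlankedLocus,
    PrimerParams,
    PrimerSet,
    design_primers,
    extract_flanks,
    primer_sets_table,
)
from .sequence_io import GenotypeSet, SequenceRecord
from .ssr_miner import MiningConfig, SSRLocus, mine_genome

__all__ = [
    "DesignedLocus",
    "design_for_genome",
    "top_pairs",
    "primer_site_map",
    "self_designed_polymorphism",
    "external_primer_polymorphism",
    "read_primer_tsv",
]


@dataclass
class DesignedLocus:
    """A mined locus with its flanks and ranked primer pairs."""

    locus_id: str
    locus: SSRLocus
    flanked: FlankedLocus
    primers: PrimerSet


def design_for_genome(
    records: Sequence[SequenceRecord],
    mining_config: MiningConfig | None = None,
    primer_params: PrimerParams | None = None,
) -> list[DesignedLocus]:
    """Mine every record, extract flanks and design primers per locus."""
    mining_config = mining_config if mining_config is not None else MiningConfig()
    primer_params = primer_params if primer_params is not None else PrimerParams()
    by_id = {r.id: r for r in records}
    loci = mine_genome(records, mining_config)
    out: list[DesignedLocus] = []
    counters: dict[str, int] = {}
    for locus in loci:
        counters[locus.seq_id] = counters.get(locus.seq_id, 0) + 1
        locus_id = f"{locus.seq_id}_{counters[locus.seq_id]}"
        flanked = extract_flanks(by_id[locus.seq_id], locus, primer_params.flank_len)
        primers = design_primers(flanked, primer_params)
        primers.locus_id = locus_id
        out.append(
            DesignedLocus(locus_id=locus_id, locus=locus, flanked=flanked, primers=primers)
        )
    return out


def top_pairs(designed: Sequence[DesignedLocus]) -> list[tuple[str, str, str]]:
    """(locus_id, forward, reverse) for the rank-1 pair of each designed
    locus; loci whose design failed are skipped."""
    out = []
    for d in designed:
        if d.primers.pairs:
            p = d.primers.pairs[0]
            out.append((d.locus_id, p.forward, p.reverse))
    return out


def primer_site_map(designed: Sequence[DesignedLocus]) -> dict[int, tuple[str, int]]:
    """locus index -> absolute (seq_id, 1-based position) of the rank-1
    forward primer's 3'-terminal base — the site a null-allele mutation hits."""
    sites: dict[int, tuple[str, int]] = {}
    for idx, d in enumerate(designed):
        if not d.primers.pairs:
            continue
        p = d.primers.pairs[0]
        abs_pos = d.flanked.template_start + p.forward_end - 1
        sites[idx] = (d.locus.seq_id, abs_pos)
    return sites


def self_designed_polymorphism(
    reference: Sequence[SequenceRecord],
    genotypes: Sequence[GenotypeSet],
    mining_config: MiningConfig | None = None,
    primer_params: PrimerParams | None = None,
    epcr_params: EPCRParams | None = None,
    include_reference: bool = True,
) -> tuple[list[DesignedLocus], AmpliconTable, PolymorphismReport]:
    """The self-designed-primer workflow: mine the reference, design one
    primer pair per locus, e-PCR every genotype and call polymorphism.

    The reference itself participates as genotype ``reference`` (its
    expected product is part of the comparison) unless
    ``include_reference=False``.
    """
    designed = design_for_genome(reference, mining_config, primer_params)
    pairs = top_pairs(designed)
    if not pairs:
        raise ValueError("no locus yielded a primer pair")
    panel = list(genotypes)
    if include_reference:
        panel = [GenotypeSet(genotype_id="reference", records=list(reference))] + panel
    table = epcr_batch(pairs, panel, epcr_params)
    report = detect_polymorphism(table)
    return designed, table, report


def external_primer_polymorphism(
    pairs: Sequence[tuple[str, str, str]],
    genotypes: Sequence[GenotypeSet],
    epcr_params: EPCRParams | None = None,
) -> tuple[AmpliconTable, PolymorphismReport]:
    """The external-primer workflow: published pairs against N genotypes."""
    table = epcr_batch(pairs, genotypes, epcr_params)
    return table, detect_polymorphism(table)


def read_primer_tsv(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a primer TSV (columns locus_id, forward, reverse at minimum);
    this is also the dialect the designer writes."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"locus_id", "forward", "reverse"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"primer TSV missing column(s): {sorted(missing)}")
    if "rank" in df.columns:
        df = df[pd.to_numeric(df["rank"]) == 1]
    out = []
    for _, row in df.iterrows():
        out.append(
            (str(row["locus_id"]), str(row["forward"]).upper(), str(row["reverse"]).upper())
        )
    lids = [lid for lid, _, _ in out]
    if len(lids) != len(set(lids)):
        raise ValueError("duplicate locus_ids in primer TSV (after rank-1 filter)")
    return out
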