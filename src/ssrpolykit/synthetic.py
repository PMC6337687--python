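"""Seeded synthetic references, genotypes and truth tables.

The generator emulates the test surface of a genome re-sequencing project:
a reference with perfect SSR tracts planted in unique flanking context,
and genotype copies of that reference whose repeat counts differ by known
signed deltas. Optional perturbations mirror the failure modes the caller
must detect: a single substitution at a primer's 3'-terminal base (null
allele), a duplicated locus cassette elsewhere in the genome (paralogy),
and background SNPs kept out of the flank windows so exact-match e-PCR
stays valid by construction (a switch to place SNPs inside flanks
exercises mismatch-tolerant matching).

All randomness flows from one integer seed; identical seeds produce
byte-identical FASTA output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_io import GenotypeSet, SequenceRecord, write_fasta
from .ssr_miner import MiningConfig, SSRLocus, mine_genome

__all__ = [
    "PlantedLocus",
    "SyntheticTruth",
    "generate_reference",
    "generate_genotypes",
    "expected_products",
    "write_fixture",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

DEFAULT_MOTIF_POOL = ("AC", "AG", "AT", "CT", "AAG", "AAT", "ATC", "ACG", "AAAT", "AACC")


@dataclass(frozen=True)
class PlantedLocus:
    seq_id: str
    start: int  # 1-based inclusive
    end: int
    motif: str
    repeat_count: int

    @property
    def unit_length(self) -> int:
        return len(self.motif)


@dataclass
class SyntheticTruth:
    loci: list[PlantedLocus]
    flank_len: int = 500
    genotype_ids: list[str] = field(default_factory=list)
    # (locus index, genotype_id) -> signed repeat-count delta
    deltas: dict[tuple[int, str], int] = field(default_factory=dict)
    # (locus index, genotype_id) -> mutated reference position (1-based)
    null_alleles: dict[tuple[int, str], int] = field(default_factory=dict)
    # locus index -> genotype ids that carry an extra cassette copy
    duplications: dict[int, list[str]] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _scrub_background(
    seq: list[str], seq_id: str, config: MiningConfig, rng: np.random.Generator,
    max_rounds: int = 25,
) -> None:
    """Re-randomize any region of ``seq`` that mines as an SSR locus."""
    for _ in range(max_rounds):
        rec = SequenceRecord(id=seq_id, residues="".join(seq))
        found = mine_genome([rec], config)
        if not found:
            return
        for L in found:
            repl = _random_seq(rng, L.end - L.start + 1)
            seq[L.start - 1 : L.end] = list(repl)
    raise RuntimeError("could not scrub chance SSRs from background")


def generate_reference(
    n_loci: int,
    genome_len: int,
    motif_pool: Sequence[str] = DEFAULT_MOTIF_POOL,
    repeat_range: tuple[int, int] = (8, 15),
    seed: int = 0,
    config: MiningConfig | None = None,
    flank_len: int = 500,
    seq_id: str = "ref1",
    max_attempts: int = 10,
) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """A random genome with ``n_loci`` perfect tracts planted at recorded
    positions, guaranteed to be exactly what the miner reports.

    The background is scrubbed of chance SSRs, planted tracts get boundary
    bases that stop unit extension, loci sit >= 1 kb apart with full flanks
    inside the sequence, and no 20-mer is shared between two loci's flank
    windows. Deterministic under ``seed``.
    """
    config = config if config is not None else MiningConfig()
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        result = _try_generate(
            n_loci, genome_len, motif_pool, repeat_range, rng, config, flank_len, seq_id
        )
        if result is not None:
            return result
    raise RuntimeError("infeasible placement: could not generate a clean reference")


def _try_generate(
    n_loci, genome_len, motif_pool, repeat_range, rng, config, flank_len, seq_id
):
    margin = flank_len + 100
    max_tract = max(len(m) for m in motif_pool) * max(
        repeat_range[1], max(config.min_repeats.values())
    )
    spacing = (genome_len - 2 * margin) // max(n_loci, 1)
    if n_loci > 0 and spacing < 1000 + max_tract:
        raise ValueError(
            f"infeasible placement: genome_len {genome_len} too small for "
            f"{n_loci} loci with 1 kb spacing"
        )

    seq = list(_random_seq(rng, genome_len))
    _scrub_background(seq, seq_id, config, rng)

    planted: list[PlantedLocus] = []
    for i in range(n_loci):
        motif = str(motif_pool[rng.integers(0, len(motif_pool))])
        k = len(motif)
        lo = max(repeat_range[0], config.min_repeats[k])
        hi = max(repeat_range[1], lo)
        count = int(rng.integers(lo, hi + 1))
        tract = motif * count
        slack = max(1, spacing - max_tract - 200)
        pos = margin + i * spacing + int(rng.integers(0, slack))  # 0-based
        seq[pos : pos + len(tract)] = list(tract)
        # boundary bases must not extend the unit run or shift its anchor
        left = [b for b in "ACGT" if b != motif[-1]]
        right = [b for b in "ACGT" if b != motif[0]]
        seq[pos - 1] = left[int(rng.integers(0, 3))]
        seq[pos + len(tract)] = right[int(rng.integers(0, 3))]
        planted.append(
            PlantedLocus(
                seq_id=seq_id,
                start=pos + 1,
                end=pos + len(tract),
                motif=motif,
                repeat_count=count,
            )
        )

    record = SequenceRecord(id=seq_id, residues="".join(seq))
    mined = mine_genome([record], config)
    if not _mined_equals_planted(mined, planted):
        return None
    if n_loci > 1 and _flank_kmer_collision(record.residues, planted, flank_len):
        return None
    truth = SyntheticTruth(loci=planted, flank_len=flank_len)
    return [record], truth


def _mined_equals_planted(mined: list[SSRLocus], planted: list[PlantedLocus]) -> bool:
    if len(mined) != len(planted):
        return False
    for m, p in zip(mined, planted):
        if (m.seq_id, m.start, m.end, m.motif, m.repeat_count) != (
            p.seq_id,
            p.start,
            p.end,
            p.motif,
            p.repeat_count,
        ):
            return False
    return True


def _flank_kmer_collision(
    residues: str, planted: Sequence[PlantedLocus], flank_len: int, k: int = 20
) -> bool:
    owner: dict[str, int] = {}
    for idx, L in enumerate(planted):
        up = residues[max(0, L.start - 1 - flank_len) : L.start - 1]
        down = residues[L.end : L.end + flank_len]
        for flank in (up, down):
            for i in range(len(flank) - k + 1):
                kmer = flank[i : i + k]
                if owner.setdefault(kmer, idx) != idx:
                    return True
    return False


def generate_genotypes(
    reference: Sequence[SequenceRecord],
    truth: SyntheticTruth,
    n_genotypes: int,
    delta_distribution: Sequence[int] | Mapping[int, float] = (-2, -1, 0, 1, 2),
    null_rate: float = 0.0,
    snp_rate: float = 0.0,
    seed: int = 0,
    primer_sites: Mapping[int, tuple[str, int]] | None = None,
    duplicated_loci: Sequence[int] = (),
    snps_in_flanks: bool = False,
) -> tuple[list[GenotypeSet], SyntheticTruth]:
    """Genotype copies of the reference with planted, recorded differences.

    Each genotype's tract lengths change by ``delta * unit_length``. A null
    allele is one substitution at the forward primer's 3'-terminal base
    (``primer_sites``: locus index -> (seq_id, 1-based position) — required
    whenever ``null_rate > 0``, since the mutated site is defined by the
    designed primer). Duplicated loci get their full reference cassette
    (tract plus both flanks) appended to each genotype. SNPs land outside
    the flank windows unless ``snps_in_flanks`` is set.
    """
    rng = np.random.default_rng(seed)
    ref_by_id = {r.id: r for r in reference}
    if isinstance(delta_distribution, Mapping):
        delta_vals = np.array(list(delta_distribution.keys()))
        probs = np.array(list(delta_distribution.values()), dtype=float)
        probs = probs / probs.sum()
    else:
        delta_vals = np.array(list(delta_distribution))
        probs = None
    if null_rate > 0 and primer_sites is None:
        raise ValueError(
            "null_rate > 0 requires primer_sites (the mutated base is a "
            "primer 3'-terminal position, known only after primer design)"
        )

    genotype_ids = [f"geno_{g + 1}" for g in range(n_genotypes)]
    truth.genotype_ids = genotype_ids
    loci_by_seq: dict[str, list[tuple[int, PlantedLocus]]] = {}
    for idx, L in enumerate(truth.loci):
        loci_by_seq.setdefault(L.seq_id, []).append((idx, L))

    protected = _protected_mask(reference, truth)

    genotypes: list[GenotypeSet] = []
    for gid in genotype_ids:
        records: list[SequenceRecord] = []
        # sample per-locus deltas (>= 1 repeat always remains)
        deltas: dict[int, int] = {}
        for idx, L in enumerate(truth.loci):
            d = int(rng.choice(delta_vals, p=probs))
            if L.repeat_count + d < 1:
                d = 1 - L.repeat_count
            deltas[idx] = d
            truth.deltas[(idx, gid)] = d
        for rec in reference:
            base = list(rec.residues)
            # null alleles: single substitution under a primer 3' end
            for idx, L in loci_by_seq.get(rec.id, []):
                if null_rate > 0 and rng.random() < null_rate:
                    if idx not in primer_sites:
                        continue
                    site_seq, pos = primer_sites[idx]
                    if site_seq != rec.id:
                        continue
                    old = base[pos - 1]
                    choices = [b for b in "ACGT" if b != old]
                    base[pos - 1] = choices[int(rng.integers(0, 3))]
                    truth.null_alleles[(idx, gid)] = pos
            # background SNPs
            if snp_rate > 0:
                n_snp = rng.binomial(rec.length, snp_rate)
                mask = protected.get(rec.id)
                for _ in range(n_snp):
                    pos = int(rng.integers(0, rec.length))
                    if not snps_in_flanks and mask is not None and mask[pos]:
                        continue
                    old = base[pos]
                    choices = [b for b in "ACGT" if b != old]
                    base[pos] = choices[int(rng.integers(0, 3))]
            # apply tract-length deltas by reassembly
            pieces: list[str] = []
            prev = 0
            for idx, L in loci_by_seq.get(rec.id, []):
                pieces.append("".join(base[prev : L.start - 1]))
                pieces.append(L.motif * (L.repeat_count + deltas[idx]))
                prev = L.end
            pieces.append("".join(base[prev:]))
            residues = "".join(pieces)
            # paralogy: append the unmodified reference cassette
            for idx in duplicated_loci:
                L = truth.loci[idx]
                if L.seq_id != rec.id:
                    continue
                src = ref_by_id[rec.id].residues
                cassette = src[
                    max(0, L.start - 1 - truth.flank_len) : L.end + truth.flank_len
                ]
                spacer = _random_seq(rng, 500)
                residues = residues + spacer + cassette
                truth.duplications.setdefault(idx, [])
                if gid not in truth.duplications[idx]:
                    truth.duplications[idx].append(gid)
            records.append(SequenceRecord(id=rec.id, residues=residues))
        genotypes.append(GenotypeSet(genotype_id=gid, records=records))
    return genotypes, truth


def _protected_mask(
    reference: Sequence[SequenceRecord], truth: SyntheticTruth
) -> dict[str, np.ndarray]:
    masks: dict[str, np.ndarray] = {}
    for rec in reference:
        masks[rec.id] = np.zeros(rec.length, dtype=bool)
    for L in truth.loci:
        m = masks[L.seq_id]
        a = max(0, L.start - 1 - truth.flank_len)
        b = min(len(m), L.end + truth.flank_len)
        m[a:b] = True
    return masks


def expected_products(
    truth: SyntheticTruth, reference_sizes: Mapping[int, int]
) -> dict[tuple[int, str], list[int]]:
    """Expected e-PCR product sizes per (locus index, genotype).

    ``reference_sizes``: locus index -> the pair's product size on the
    reference. The original site contributes size + delta * unit_length
    (absent when a null allele was planted); a duplicated cassette
    contributes the unmodified reference size.
    """
    out: dict[tuple[int, str], list[int]] = {}
    for idx, L in enumerate(truth.loci):
        if idx not in reference_sizes:
            continue
        ref_size = reference_sizes[idx]
        for gid in truth.genotype_ids:
            sizes: list[int] = []
            if (idx, gid) not in truth.null_alleles:
                sizes.append(ref_size + truth.deltas[(idx, gid)] * L.unit_length)
            if gid in truth.duplications.get(idx, []):
                sizes.append(ref_size)
            out[(idx, gid)] = sorted(sizes)
    return out


def write_fixture(
    out_dir: str | Path,
    reference: Sequence[SequenceRecord],
    genotypes: Sequence[GenotypeSet],
    truth: SyntheticTruth,
) -> dict[str, Path]:
    """Write reference.fasta, genotype_<k>.fasta and truth.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"reference": out_dir / "reference.fasta"}
    write_fasta(reference, paths["reference"])
    for geno in genotypes:
        p = out_dir / f"{geno.genotype_id}.fasta"
        write_fasta(geno.records, p)
        paths[geno.genotype_id] = p

    rows = []
    for idx, L in enumerate(truth.loci):
        row = {
            "locus_index": idx,
            "seq_id": L.seq_id,
            "start": L.start,
            "end": L.end,
            "motif": L.motif,
            "repeat_count": L.repeat_count,
            "duplicated_in": ";".join(truth.duplications.get(idx, [])),
        }
        for gid in truth.genotype_ids:
            row[f"delta_{gid}"] = truth.deltas.get((idx, gid), 0)
            row[f"null_{gid}"] = truth.null_alleles.get((idx, gid), "")
        rows.append(row)
    truth_path = out_dir / "truth.tsv"
    pd.DataFrame(rows).to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths
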