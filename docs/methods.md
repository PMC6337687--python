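# Methods

## Scope and model

ssrpolykit predicts the outcome of length-based microsatellite (SSR)
genotyping directly from assembled sequence. The underlying model is the
standard one for SSR assays: alleles differ by replication-slippage
changes in the repeat count, so the PCR product length of a locus equals
a constant (the flanking distance between the primer sites) plus
`repeat_count × unit_length`. Everything the package computes — mining,
design, e-PCR, calling — serves that length arithmetic. Templates are
treated as haploid assemblies: one sequence per genotype, one allele per
locus per genotype. Diploid heterozygosity, sequencing error and
assembly artifacts are out of scope.

## Mining

A perfect SSR is a maximal tandem run of a primitive unit of length
1–6 bp. The implementation scans, per unit length k, the maximal regions
of period k (positions where `s[t] == s[t+k]`, with N never matching
anything including N) and reports one left-anchored tract of whole units
per region. Rules, fixed once here:

* **Primitivity** — a unit that is a whole-number repetition of a
  shorter unit (e.g. `ATAT`) is never a motif; the shorter unit's run is
  the locus. A tract of a longer unit wholly contained in the span of a
  shorter-unit tract is suppressed, so no two loci cover the same bases
  redundantly.
* **Left anchoring** — the motif is the unit as first encountered at the
  tract start (`ACAC…` starting on the A is `(AC)n`, never `(CA)n`);
  no reverse-complement collapsing. Trailing partial units are not
  counted in `repeat_count`.
* **Thresholds** — defaults `{1:10, 2:6, 3:5, 4:5, 5:5, 6:5}` minimum
  repeats and 100 bp maximum interruption for compound merging. These
  are the distributed defaults of the MISA mining tradition this module
  reproduces; they are stated explicitly because tools in the field
  often leave them implicit, and they are fully configurable.
* **Compound loci** — maximal chains of perfect tracts with pairwise
  gaps ≤ 100 bp become one type-`c` locus recording only its span (the
  constituent motifs go to a free-text note), because downstream primer
  design treats any locus as an interval to be bracketed.

Correctness is established against a quadratic brute-force enumerator
that tests every (position, unit-length) pair independently; the two
must agree exactly on randomized, repeat-rich sequences.

## Primer design

Flanks of up to 500 bp are taken each side of the tract, clipped (never
padded) at sequence ends. Primers are confined to the flanks so the
repeat tract always lies inside the product; this is what makes
product-size differences interpretable as repeat-count differences, and
is asserted by the round-trip property (every designed pair, e-PCR'd
against its own source genome, yields exactly one product of the stated
expected size).

Hard filters per candidate window: length 18/20/24 (min/opt/max), Tm
57/60/63 °C, GC fraction 0.20–0.80, homopolymer runs ≤ 4, no N, and a 3′
self-complementarity limit (longest 3′-anchored suffix that can anneal
to another copy of the primer, ≤ 3). Pairs additionally need product
size in 100–300 bp and |ΔTm| ≤ 5 °C. Ranking uses the penalty given in
the README; ties break deterministically by (penalty, forward start,
reverse start), and the returned pairs (default 5) must have pairwise
distinct forward 5′ positions so they are genuine alternatives — the
practical use of the lower-ranked pairs is rescuing loci whose best pair
fails in vitro (e.g. a mutated 3′ binding site).

**Tm model.** The default is the salt-adjusted GC formula
`Tm = 81.5 + 16.6·log10([Na+]) + 0.41·%GC − 600/len` at [Na+] = 50 mM —
deterministic, dependency-free, and adequate for *ranking* primers of
similar composition. It is not nearest-neighbor thermodynamics; absolute
values differ from NN-based designers by several °C, and a
`tm_function` hook on `design_primers` accepts any replacement model.
The Wallace rule `2(A+T) + 4(G+C)` is provided as a cross-check mode.

## In-silico PCR

`find_matches` locates primer footprints on both strands; `epcr` pairs a
plus-strand forward footprint with a downstream reverse-complemented
reverse footprint (and the mirror arrangement on the minus strand),
keeping products within size bounds (default: sum of primer lengths to
5000 bp) with non-overlapping footprints, deduplicated by coordinates.

Default stringency is **exact matching**. Re-sequenced genotypes of the
same species are expected to carry intact primer sites, and a site that
fails to amplify is itself the signal (null allele or missing sequence).
For heterologous templates a mismatch budget (≤ 3) is available, always
with zero mismatches required in the 3′-terminal seed (default 5 bp),
since 3′ mismatches are what actually abort extension. Whether a given
tool lineage tolerated mismatches is generally undocumented; exact
matching is this package's stated default, not a claim about others.

The engine is checked against a naive sliding-window scanner (every
position, every pattern, exhaustive footprint pairing) for exact and
mismatch modes, and against a strand-involution property (e-PCR of a
reverse-complemented genome gives mirrored coordinates with swapped
orientation).

## Polymorphism calling

Only genotypes with exactly one product participate in classification;
statuses are mutually exclusive and exhaustive:

* PARALOGOUS — any genotype with ≥ 2 products. Takes precedence over
  everything: multi-locus amplification produces multi-band lanes and
  unusable allele calls, so such loci should be discarded before
  validation.
* INSUFFICIENT — fewer than 2 genotypes amplified cleanly.
* POLYMORPHIC / MONOMORPHIC — ≥ 2 distinct sizes / all equal among the
  cleanly amplifying genotypes. Genotypes with no product are reported
  as missing but never create polymorphism on their own.

In self-designed mode the reference genome participates as genotype
`reference`, since its expected product is part of the comparison.

**Transferability** (cross-species screening) keeps a locus when a valid
both-primer product of ≤ 500 bp (configurable) exists on the host
genome; products only above the cutoff are `FILTERED_SIZE`, a single
matching primer is `FILTERED_ASYMMETRIC`, nothing matching is `ABSENT`.
"Asymmetric" is interpreted as exactly one primer matching anywhere;
orientation validity is already the e-PCR engine's job. Raising the
cutoff can only grow the transferable count (tested property).

**Genic screen**: for transcript-designed pairs, the transcript product
size is the expectation; genomic products exceeding it are
`INTRON_CONTAINING` (Δ = intron bp), no genomic product at any searched
size is `JUNCTION_PRIMER` (a primer spans an exon-exon junction), and no
product within the size cap but one within a 10× widened cap is
`NO_GENOMIC_PRODUCT_OVERSIZE` (the intron pushed the product out of
amplifiable range). A genomic product smaller than the transcript's
would imply a genomic deletion rather than an intron problem and is
reported under `OK` with the sizes listed.

## Simulated gel

Band migration is linear in log10 fragment size:
`migration = well_offset + lane_height · (log10(s_max) − log10(size)) / (log10(s_max) − log10(s_min))`,
the standard agarose approximation — monotone, and visually faithful for
the 25–500 bp range rendered. The default ladder
(25–450 bp in 11 steps) mimics a common capillary-electrophoresis sizing
marker. Output is deterministic SVG plus a band table carrying identical
(size, migration) pairs, so rendering is testable by diff. No intensity,
diffusion or heteroduplex modeling is attempted, and no attempt is made
to match the pixel output of any particular gel-simulation code.

## Synthetic fixtures

The generator emulates a re-sequencing study at the level this pipeline
consumes: a reference with planted perfect tracts in unique flanking
context, and genotype copies differing by known repeat-count deltas.
Design choices:

* The background is scrubbed of chance SSRs and tract boundaries are
  fixed so planted runs cannot extend or shift anchor — the planted
  truth *is* the mining ground truth, exactly.
* Planted loci sit ≥ 1 kb apart with full 500 bp flanks, and no 20-mer
  is shared between two loci's flanks, so primer sites are unique by
  construction.
* Null alleles are a single substitution at the rank-1 forward primer's
  3′-terminal base. Because that position only exists after primer
  design, `generate_genotypes` requires a primer-site map whenever
  `null_rate > 0` — the generation order (reference → design →
  genotypes) mirrors a real study, where primers predate the genotyping.
* Paralogy is planted by appending the unmodified reference cassette
  (tract ± flank) to the genotype, far from the original locus.
* Background SNPs avoid the flank windows so exact-match e-PCR remains
  valid by construction; `snps_in_flanks=True` exists to exercise the
  mismatch-tolerant mode.
* One integer seed drives everything; same seed, byte-identical FASTA.

What passing on these fixtures does **not** show: robustness to
assembly gaps, indel-containing primer sites, heterozygosity, or repeat
families with many near-identical genomic copies — real-data phenomena
the generator deliberately omits.

## Problem sizes and determinism

The test suite and acceptance script run the end-to-end recovery at
1 Mb / 50 loci / 4 genotypes / 5% null alleles / 2 duplicated loci, the
round-trip property over ≥ 100 designed loci (≥ 250 pairs), miner-oracle
agreement on 10 kb sequences and e-PCR-oracle agreement on 100 kb
genomes — sizes chosen so the whole validation is a desk-scale,
single-CPU computation while still exercising every code path at
genome-like scale. All randomness flows through explicit integer seeds;
every output table has a stable column order and no embedded timestamps
(the CLI writes timestamps only to its run manifest), so runs are
reproducible byte for byte.

## Known limitations

* Tm is a composition formula, not NN thermodynamics; no ΔG hairpin or
  cross-dimer evaluation.
* e-PCR matching is ungapped; an indel inside a primer site reads as a
  null allele rather than a shifted product.
* Circular templates are not supported.
* Compound loci are genotyped as intervals; constituent-motif dosage
  within a compound locus is not resolved.
* The polymorphism caller models haploid assemblies; it cannot emit
  heterozygous calls or diversity statistics (PIC, He).
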