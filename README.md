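# ssrpolykit

Microsatellite (SSR) marker discovery for genome re-sequencing projects:
mine perfect 1–6 bp tandem repeats from FASTA assemblies, design ranked
PCR primer pairs from the repeat flanks, run in-silico PCR (e-PCR) across
re-sequenced genotypes or heterologous species, and call allele-length
polymorphism — plus screens for paralogous loci, null alleles,
cross-species transferability and intron-containing genic amplicons, and
a simulated gel view of the allele matrix.

It is aimed at people building SSR genotyping panels from assembled
genomes or transcriptomes: the entire wet-lab outcome of a length-based
SSR assay is predictable from sequence, so candidate markers can be
ranked and triaged before any oligo is synthesised.

## The method

**Mining.** A locus is a maximal perfect tandem run of a primitive 1–6 bp
unit meeting per-unit-length repeat thresholds (defaults
`{1:10, 2:6, 3:5, 4:5, 5:5, 6:5}`, MISA-style); runs separated by ≤ 100 bp
merge into one compound locus. Coordinates are 1-based inclusive.

**Primer design.** From ≤ 500 bp flanks either side of the tract (primers
never overlap the repeat), all windows passing hard filters (length 18–24,
Tm 57–63 °C, GC 0.20–0.80, no >4 bp homopolymer run, limited 3′
self-complementarity) are paired subject to product size 100–300 bp and
|ΔTm| ≤ 5 °C, then ranked by

```
penalty = |Tm_f − Tm_opt| + |Tm_r − Tm_opt|
          + 0.5·(|len_f − len_opt| + |len_r − len_opt|) + |Tm_f − Tm_r|
```

keeping the 5 best pairs with distinct forward positions. Tm uses the
salt-adjusted GC formula `81.5 + 16.6·log10([Na+]) + 0.41·%GC − 600/len`.

**e-PCR.** A pair (F, R) amplifies wherever F and the reverse complement
of R flank an interval within the size bounds, on either strand; default
matching is exact (N never matches), with an optional mismatch budget plus
a mandatory exact 3′-terminal seed for heterologous work.

**Calling.** Per locus, each genotype's allele is its single product size.
A locus is POLYMORPHIC when ≥ 2 cleanly amplifying genotypes show ≥ 2
distinct sizes, MONOMORPHIC when they agree, INSUFFICIENT below 2, and
PARALOGOUS whenever any genotype yields multiple products (multi-locus
amplification makes length genotyping unreliable, so this overrides all
else). Transferability keeps loci whose host-species product is ≤ 500 bp
with both primers matched; the genic screen compares transcript-template
product sizes with genomic ones to flag intron-containing amplicons and
exon-junction primers.

## Worked example

`examples/04_external_primers_hvssr.py` replays a published four-marker
HvSSR rice panel (cultivars Cauvery, Co36, Co39, Dubraj) through the
external-primer workflow on synthetic cassette genomes built from the
published allele sizes:

```
  locus_id Cauvery Co36 Co39 Dubraj
HvSSR03-37     337  351  305    338
HvSSR04-27     292  292  293    296
HvSSR07-51     286  281  282    293
HvSSR08-14     257  258  266    257

All 4 of 4 loci are polymorphic; e.g. HvSSR03-37 spans a 46 bp allele range (305-351).
```

Each cell is an e-PCR product size in bp; rows with ≥ 2 distinct values
are length-polymorphic markers, and the recovered sizes equal the
published in-silico and in-vitro profiles exactly. The other example
scripts cover mining (`01`), primer design (`02`), the full synthetic
self-designed-primer workflow (`03`) and the transferability/genic
screens (`05`); each prints a short interpretation of its output.

The same pipeline is available as a CLI:

```bash
ssrpolykit simulate --out fixture --n-loci 10 --n-genotypes 3 --seed 5
ssrpolykit poly --reference fixture/reference.fasta \
    --genotype fixture/geno_1.fasta --genotype fixture/geno_2.fasta \
    --genotype fixture/geno_3.fasta --out run1 --gel
```

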