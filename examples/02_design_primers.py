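"""Design ranked primer pairs for a mined SSR locus.

Primers are drawn from 500 bp flanks either side of the repeat tract
(never from the tract itself, so product-size differences between
genotypes always reflect repeat-count variation), filtered on length,
Tm, GC and runs, and ranked by a penalty that favours opt-length,
opt-Tm, Tm-matched pairs.
"""

from ssrpolykit import (
    MiningConfig,
    PrimerParams,
    design_primers,
    extract_flanks,
    generate_reference,
    mine_genome,
)

records, _ = generate_reference(n_loci=3, genome_len=40_000, seed=7)
locus = mine_genome(records, MiningConfig())[0]
flanked = extract_flanks(records[0], locus, flank_len=500)
primer_set = design_primers(flanked, PrimerParams())

print(f"locus ({locus.motif}){locus.repeat_count} at "
      f"{locus.seq_id}:{locus.start}-{locus.end}\n")
print(f"{'rank':>4} {'forward':<25} {'reverse':<25} {'Tm_f':>6} {'Tm_r':>6} {'size':>5}")
for p in primer_set.pairs:
    print(f"{p.rank:>4} {p.forward:<25} {p.reverse:<25} "
          f"{p.tm_forward:>6.1f} {p.tm_reverse:>6.1f} {p.expected_product_size:>5}")
print()
print("Five alternative pairs with distinct forward positions; 'size' is the "
      "expected amplicon length (bp) on this reference, Tm in deg C from the "
      "salt-adjusted GC formula.")
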