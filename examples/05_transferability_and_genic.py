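"""Cross-species transferability and genic (intron-junction) screens.

Transferability: a marker panel designed in a focal species is screened
against a host-species genome; a locus transfers only if both primers
bind and the product is at most 500 bp (larger products and one-primer
"asymmetric" matches are filtered, mirroring how heterologous e-PCR
panels are curated).

Genic screen: primers designed on transcript (mRNA) templates are
checked against genomic DNA, where an intron inside the amplicon
inflates the product and a primer on an exon-exon junction has no
genomic binding site at all.
"""

import numpy as np

from ssrpolykit import evaluate_genic_primers, evaluate_transferability
from ssrpolykit.datasets import HVSSR_PANEL
from ssrpolykit.sequence_io import GenotypeSet, SequenceRecord, reverse_complement

rng = np.random.default_rng(11)
buf = lambda n: "".join(rng.choice(list("ACGT"), size=n))
F, R, _ = HVSSR_PANEL["HvSSR03-37"]
F2, R2 = "TGCATGGACTACGGATTAGC", "CCATGATCGGTTACGGATCA"
F3, R3 = "GATTACCAGGATGCTTGACC", "TTGGCATCAGGCTTCAGATG"

# --- transferability -------------------------------------------------------
host = GenotypeSet("host_species", [SequenceRecord("h_chr1", "".join([
    buf(200),
    F + buf(81) + reverse_complement(R),        # 120 bp product: transfers
    buf(200),
    F2 + buf(580) + reverse_complement(R2),     # 620 bp product: too large
    buf(200),
    F3,                                         # forward primer only
    buf(200),
]))])
pairs = [("mk_ok", F, R), ("mk_big", F2, R2), ("mk_one_sided", F3, R3)]
report = evaluate_transferability(pairs, host, size_cutoff=500)
print(report.table().to_string(index=False))
print(f"-> {report.count_transferable}/{len(pairs)} markers transfer to the "
      f"host at the 500 bp cutoff.\n")

# --- genic primer screen ---------------------------------------------------
exon1 = F + buf(70)
exon2 = buf(91) + reverse_complement(R)
transcript = SequenceRecord("tx1", exon1 + exon2)           # mRNA product: 200 bp
genome = GenotypeSet("genome", [SequenceRecord("chr1",
    buf(300) + exon1 + buf(550) + exon2 + buf(300))])       # 550 bp intron
(verdict,) = evaluate_genic_primers([("tx_marker", F, R)], [transcript],
                                    genome).verdicts
print(f"transcript product {verdict.expected_size} bp, genomic product "
      f"{verdict.genomic_sizes[0]} bp -> {verdict.verdict} "
      f"(intron adds {verdict.delta} bp); such pairs would mis-size alleles "
      f"on genomic DNA and are flagged before oligo synthesis.")
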