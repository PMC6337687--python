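"""Small published reference panels bundled for examples and validation.

HVSSR_PANEL: four markers of the HvSSR ("highly variable SSR") rice series
with their primer sequences and the e-PCR allele sizes (bp) reported for
four Indian rice cultivars (Cauvery, Co36, Co39, Dubraj). The in-vitro PCR
profiles published for the same markers match these sizes exactly, which
is what makes the panel a convenient ground truth for the external-primer
workflow: a synthetic genotype genome built to carry these alleles must
reproduce the sizes and the all-polymorphic classification.
"""

from __future__ import annotations

from .sequence_io import GenotypeSet, SequenceRecord, reverse_complement

__all__ = ["HVSSR_PANEL", "HVSSR_GENOTYPES", "hvssr_pairs", "cassette_genomes"]

HVSSR_GENOTYPES = ("Cauvery", "Co36", "Co39", "Dubraj")

#: marker -> (forward primer, reverse primer, {cultivar: allele size bp})
HVSSR_PANEL: dict[str, tuple[str, str, dict[str, int]]] = {
    "HvSSR03-37": (
        "GGAAATCGTCAAGAACGTC",
        "TAATTGTATACCACTCCGCC",
        {"Cauvery": 337, "Co36": 351, "Co39": 305, "Dubraj": 338},
    ),
    "HvSSR04-27": (
        "ATGGATTTAGGCTTGTTTGA",
        "ATACTGCGAAGGTGAAGAGA",
        {"Cauvery": 292, "Co36": 292, "Co39": 293, "Dubraj": 296},
    ),
    "HvSSR07-51": (
        "CGAGCATGTCTGTCAAGTAA",
        "GTTCGAATGTAATGTTGGCT",
        {"Cauvery": 286, "Co36": 281, "Co39": 282, "Dubraj": 293},
    ),
    "HvSSR08-14": (
        "TCCACTTTACATCGTCACAA",
        "CTACCTCTTAACCGCACATT",
        {"Cauvery": 257, "Co36": 258, "Co39": 266, "Dubraj": 257},
    ),
}


def hvssr_pairs() -> list[tuple[str, str, str]]:
    """The panel as (locus_id, forward, reverse) external-primer input."""
    return [(lid, f, r) for lid, (f, r, _) in HVSSR_PANEL.items()]


def cassette_genomes(seed: int = 0) -> list[GenotypeSet]:
    """Synthetic per-cultivar genomes carrying the published alleles.

    Each cultivar record concatenates, per marker, a cassette

        forward + spacer + reverse_complement(reverse)

    whose spacer length makes the amplicon exactly the published size
    (e.g. 337 = 19 + 298 + 20 for HvSSR03-37 in Cauvery), separated by
    random buffer sequence free of additional primer sites. The filename
    says it: these genomes are synthetic stand-ins for the cultivars'
    re-sequenced assemblies, built from the printed allele sizes.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")

    def buffer(n: int) -> str:
        return rng.choice(bases, size=n).tobytes().decode()

    all_primers = [p for f, r, _ in HVSSR_PANEL.values() for p in (f, r)]

    genomes = []
    for cultivar in HVSSR_GENOTYPES:
        while True:
            parts = [buffer(200)]
            for lid, (f, r, sizes) in HVSSR_PANEL.items():
                spacer = sizes[cultivar] - len(f) - len(r)
                if spacer < 0:
                    raise ValueError(f"published size for {lid} too small")
                parts.append(f + buffer(spacer) + reverse_complement(r))
                parts.append(buffer(200))
            residues = "".join(parts)
            if _clean(residues, all_primers):
                break
        genomes.append(
            GenotypeSet(
                genotype_id=cultivar,
                records=[SequenceRecord(id=f"{cultivar}_chr", residues=residues)],
            )
        )
    return genomes


def _clean(residues: str, primers: list[str]) -> bool:
    """True when each primer occurs exactly once (as planted) and its
    reverse complement only where planted — no chance extra sites."""
    for p in primers:
        rc = reverse_complement(p)
        if residues.count(p) + residues.count(rc) != 1:
            return False
    return True
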