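"""Shared fixtures: seeded synthetic genomes at the scales the heavier
integration checks use, built once per session."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ssrpolykit as spk
from ssrpolykit.synthetic import expected_products

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def random_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    arr = np.frombuffer(alphabet.encode(), dtype="S1")
    return rng.choice(arr, size=n).tobytes().decode()


@pytest.fixture(scope="session")
def e2e_fixture():
    """Parameter-recovery panel: 1 Mb reference, 50 planted loci, 4
    genotypes with planted repeat-count deltas, 5% null alleles and 2
    duplicated loci; e-PCR'd and called end to end."""
    reference, truth = spk.generate_reference(50, 1_000_000, seed=101)
    designed = spk.design_for_genome(reference)
    sites = spk.primer_site_map(designed)
    genotypes, truth = spk.generate_genotypes(
        reference,
        truth,
        n_genotypes=4,
        null_rate=0.05,
        seed=102,
        primer_sites=sites,
        duplicated_loci=(3, 17),
    )
    pairs = spk.top_pairs(designed)
    panel = [spk.GenotypeSet(genotype_id="reference", records=list(reference))] + genotypes
    table = spk.epcr_batch(pairs, panel)
    report = spk.detect_polymorphism(table)

    ref_sizes = {
        i: d.primers.pairs[0].expected_product_size
        for i, d in enumerate(designed)
        if d.primers.pairs
    }
    expected = expected_products(truth, ref_sizes)
    # the reference participates as genotype 0: delta 0, no null, no cassette
    for idx, size in ref_sizes.items():
        expected[(idx, "reference")] = [size]
    lid_by_idx = {i: d.locus_id for i, d in enumerate(designed)}
    return {
        "reference": reference,
        "truth": truth,
        "designed": designed,
        "genotypes": genotypes,
        "table": table,
        "report": report,
        "ref_sizes": ref_sizes,
        "expected": expected,
        "lid_by_idx": lid_by_idx,
    }


@pytest.fixture(scope="session")
def roundtrip_designed():
    """>= 100 designed loci with their source reference, for the
    design -> e-PCR round-trip property."""
    reference, truth = spk.generate_reference(110, 1_500_000, seed=201)
    designed = spk.design_for_genome(reference)
    return reference, designed
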