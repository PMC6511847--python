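import random

import pytest

from ripper.io_genbank import GeneFeature, GenomicRegion
from ripper.synthetic import make_synthetic_region, standard_region_spec


def random_dna(rng: random.Random, n: int, gc: float = 0.5) -> str:
    return "".join(
        rng.choice("GC") if rng.random() < gc else rng.choice("AT") for _ in range(n)
    )


@pytest.fixture(scope="session")
def fixture_region():
    """One deterministic 25 kb synthetic region with an in-window and a
    distant domain-bearing planted precursor, plus its truth table."""
    return make_synthetic_region(standard_region_spec(11, with_distant=True))


@pytest.fixture()
def toy_region():
    """A tiny hand-built region: two genes around a central RTE."""
    rng = random.Random(0)
    seq = random_dna(rng, 3000)
    # plant three clean CDS spans (start + body + stop), forward strand
    def cds(start, n_codons):
        body = "ATG" + "".join(rng.choice(("GCT", "GAA", "CTG", "AAA")) for _ in range(n_codons - 2)) + "TAA"
        return start, start + 3 * n_codons, body

    s1, e1, nt1 = cds(100, 100)
    s2, e2, nt2 = cds(1200, 150)
    s3, e3, nt3 = cds(2200, 80)
    seq = seq[:s1] + nt1 + seq[e1:s2] + nt2 + seq[e2:s3] + nt3 + seq[e3:]
    feats = [
        GeneFeature("g1", s1, e1, 1, product="hypothetical protein"),
        GeneFeature("rte1", s2, e2, 1, product="TfuA-like protein"),
        GeneFeature("g3", s3, e3, 1, product="hypothetical protein"),
    ]
    return GenomicRegion(
        accession="TOY1",
        organism="Synthetica exemplaris",
        sequence=seq,
        features=feats,
        rte_feature_id="rte1",
    )
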