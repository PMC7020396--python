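import numpy as np
import pytest

from gwaspath.models import GeneFeature, MarkerRecord
from gwaspath.synthetic import worked_toy


def make_marker(
    marker_id="M1",
    chromosome="chr1",
    position=100,
    effect=1.0,
    p_value=0.05,
    marker_r2=0.2,
    trait="t",
    alleles=("A", "G"),
):
    return MarkerRecord(
        marker_id=marker_id,
        chromosome=chromosome,
        position=position,
        trait=trait,
        p_value=p_value,
        marker_r2=marker_r2,
        effect=effect,
        alleles=alleles,
    )


@pytest.fixture
def marker_factory():
    return make_marker


@pytest.fixture
def toy_dataset():
    return worked_toy()


@pytest.fixture
def gene_factory():
    def make(gene_id="g1", chromosome="chr1", start=5_000, end=6_000, strand="+"):
        return GeneFeature(gene_id=gene_id, chromosome=chromosome, start=start, end=end, strand=strand)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
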