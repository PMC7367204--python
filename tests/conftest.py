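import numpy as np
import pytest

from antisenseq.annotation import GeneFeature, GenomeAnnotation
from antisenseq.simulate import RnaSeqConfig


@pytest.fixture
def toy_annotation():
    """Hand-built annotation with an overlapping gene pair and a non-coding gene."""
    feats = [
        GeneFeature("geneA", "chrI", 100, 600, "+"),
        GeneFeature("geneB", "chrI", 700, 1200, "-"),
        GeneFeature("geneC", "chrI", 1150, 1700, "-"),  # overlaps geneB 3' end
        GeneFeature("geneD", "chrI", 2000, 2400, "+"),
        GeneFeature("geneE", "chrII", 50, 500, "+"),
        GeneFeature("nc1", "chrII", 800, 1000, "-", "non_coding"),
    ]
    return GenomeAnnotation(feats, {"chrI": 3000, "chrII": 1500})


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


def small_design_config(noise="none", **overrides) -> RnaSeqConfig:
    """A scaled-down strain x treatment design for fast end-to-end tests."""
    base = dict(
        n_genes=80, n_chroms=2, depth=60_000, replicates=2, noise=noise,
        n_cdk9_only=5, n_h2bub1_only=5, n_shared=3, n_double_only=8,
        planted_baseline_min=30.0, planted_baseline_max=60.0,
    )
    base.update(overrides)
    return RnaSeqConfig(**base)


@pytest.fixture
def small_config():
    return small_design_config()
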