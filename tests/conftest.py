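import numpy as np
import pandas as pd
import pytest

from ecdnakit.amplicon import GeneAnnotation, GeneRecord, RegulatoryElement
from ecdnakit.signatures import SignatureModel


@pytest.fixture
def two_sig_model() -> SignatureModel:
    """Two signatures with hand-set weight on channel 1 (index 0).

    R[0, 0] = 0.02 and R[1, 0] = 0.01; the rest of each row is spread
    uniformly so rows sum to exactly 1. With equal exposures the posterior
    on channel 1 is (2/3, 1/3).
    """
    R = np.empty((2, 96))
    R[0] = (1 - 0.02) / 95
    R[0, 0] = 0.02
    R[1] = (1 - 0.01) / 95
    R[1, 0] = 0.01
    exposures = pd.DataFrame(
        {"sigA": [0.5, 1.0], "sigB": [0.5, 0.0]}, index=["s1", "s2"]
    )
    return SignatureModel(("sigA", "sigB"), R, exposures)


@pytest.fixture
def toy_annotation() -> GeneAnnotation:
    """Ten-gene toy annotation with one oncogene, one immune gene,
    ordinary coding genes and a few regulatory elements on chr1."""
    genes = [
        GeneRecord("chr1", 1_000, 2_000, "ONC1", True),
        GeneRecord("chr1", 2_500, 3_000, "IMM1", True),
        GeneRecord("chr1", 4_000, 5_000, "CODE1", True),
        GeneRecord("chr1", 9_000, 9_500, "CODE2", True),
        GeneRecord("chr2", 1_000, 2_000, "ONC2", True),
        GeneRecord("chr2", 3_000, 4_000, "IMM2", True),
        GeneRecord("chr2", 5_000, 6_000, "CODE3", True),
        GeneRecord("chr2", 7_000, 8_000, "CODE4", True),
        GeneRecord("chr3", 1_000, 2_000, "CODE5", True),
        GeneRecord("chr3", 3_000, 4_000, "CODE6", True),
    ]
    return GeneAnnotation(
        genes=genes,
        oncogenes=frozenset({"ONC1", "ONC2"}),
        immune_sets={"GO:TEST": frozenset({"IMM1", "IMM2"})},
        elements=[
            RegulatoryElement("chr1", 6_000, 6_100, "enhancer"),
            RegulatoryElement("chr1", 6_500, 6_600, "promoter"),
            RegulatoryElement("chr1", 7_000, 7_500, "lncRNA"),
        ],
    )
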