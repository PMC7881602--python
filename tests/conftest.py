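import numpy as np
import pytest
import scipy.stats as st

from polygrs.genotypes import GenotypeMatrix
from polygrs.panel import SNPPanel, SNPPanelEntry


def brute_force_w(f: float, odds_ratio: float) -> float:
    """Independent oracle: E[OR**g] for g ~ Binomial(2, f) by enumeration."""
    return sum(
        st.binom.pmf(g, 2, f) * odds_ratio**g for g in (0, 1, 2)
    )


@pytest.fixture
def single_snp_panel() -> SNPPanel:
    return SNPPanel(
        [
            SNPPanelEntry(
                snp_id="snp01", chrom="1", pos=1000, risk_allele="A",
                other_allele="G", odds_ratio=1.2, risk_allele_freq=0.3,
            )
        ]
    )


@pytest.fixture
def small_panel() -> SNPPanel:
    entries = [
        SNPPanelEntry("snp01", "1", 1000, "A", "G", 1.2, 0.3),
        SNPPanelEntry("snp02", "2", 2000, "C", "T", 1.1, 0.45),
        SNPPanelEntry("snp03", "3", 3000, "G", "C", 1.25, 0.15),
    ]
    return SNPPanel(entries)


@pytest.fixture
def small_genotypes(small_panel) -> GenotypeMatrix:
    dosages = np.array(
        [
            [0, 1, 2],
            [1, 1, 0],
            [2, 0, -1],  # one missing dosage
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(["s1", "s2", "s3"], small_panel.snp_ids, dosages)
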