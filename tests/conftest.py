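import dataclasses

import pytest

from mitodiv.genome_model import Msa
from mitodiv.simulate import (
    HetSimConfig,
    PanelConfig,
    QuartetConfig,
    generate_cr_panel,
    generate_genome_quartet,
    generate_het_pileup,
)


@pytest.fixture(scope="session")
def panel():
    """Control-region panel with the study-shaped segment/variant plan."""
    return generate_cr_panel(PanelConfig(seed=11))


@pytest.fixture(scope="session")
def quartet():
    """Four mitogenomes with the per-gene singleton/doubleton plan."""
    return generate_genome_quartet(QuartetConfig(seed=11))


@pytest.fixture(scope="session")
def het_exact():
    """Noise-off pileup: exact read counts, zero error rate."""
    cfg = dataclasses.replace(HetSimConfig(seed=11), exact_counts=True)
    return generate_het_pileup(cfg)


@pytest.fixture
def tiny_msa():
    return Msa(
        [
            ("s1", "ACGTACGTAC"),
            ("s2", "ACGTACGTAC"),
            ("s3", "ACATACGTAC"),
            ("s4", "ACGTAC-TAC"),
        ]
    )
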