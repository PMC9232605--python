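import pytest

from gwasint.experiments import DesignRunConfig, run_design1


@pytest.fixture(scope="session")
def design1_mc():
    """One moderate-scale null-GWAS error-rate run shared across tests.

    m = 20,000 SNPs, 10,000 replicates, all five methods; the scale keeps
    the binomial SE around 0.002 so 3-SE oracle comparisons are sharp.
    """
    cfg = DesignRunConfig(design=1, replicates=10_000, m=20_000, seed=20240907)
    return cfg, run_design1(cfg)
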