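import numpy as np
import pytest

from loopqtl.pipeline import RunConfig, run_demo
from loopqtl.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A scaled-down two-cohort study shared by read-only tests."""
    cfg = SimulationConfig(seed=7, n_genes=12, n_chromosomes=2,
                           n_variants_per_gene=20, n_discovery=150,
                           n_replication=200, n_drivers=2, n_gwas_null=40)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """The default end-to-end demo pipeline, run once per session."""
    out = tmp_path_factory.mktemp("demo")
    cfg = RunConfig(out_dir=str(out))
    cascade = run_demo(cfg)
    return cfg, out, cascade


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
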