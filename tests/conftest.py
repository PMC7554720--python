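import dataclasses

import pytest

from pamuslink.pipeline import RunConfig, run_pipeline
from pamuslink.simulate import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared by read-only tests."""
    cfg = SimConfig(n_genes=250, seed=11)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run on a mid-sized default-condition study."""
    outdir = tmp_path_factory.mktemp("pipeline") / "run"
    cfg = RunConfig(outdir=str(outdir), seed=7)
    cfg.sim = dataclasses.replace(cfg.sim, n_genes=600)
    report = run_pipeline(cfg)
    return cfg, report, outdir
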