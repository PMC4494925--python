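import numpy as np
import pandas as pd
import pytest

from gliomosaic import CohortConfig, PipelineConfig, generate_cohort, run_pipeline


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic study: 10 patients x 4 zones + 4 reference brains."""
    return generate_cohort(CohortConfig(seed=1))


def small_config(seed: int = 0, **overrides) -> CohortConfig:
    """A scaled-down cohort for fast unit tests (same structure, fewer genes)."""
    kwargs = dict(
        seed=seed,
        n_patients=6,
        n_genes=1500,
        module_sizes=(300, 240, 180, 140, 110, 80, 50),
        n_probes=800,
        n_subtype_genes=120,
        n_hub_genes=10,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config(seed=0))


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    """One full default pipeline run, shared by the slower end-to-end tests."""
    outdir = tmp_path_factory.mktemp("pipeline")
    return run_pipeline(PipelineConfig(outdir=outdir, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_track(values, chrom=1, start=1, step=1000, probe_prefix="P"):
    """Helper: a single-chromosome CNA track from a log2-ratio vector."""
    values = np.asarray(values, dtype=float)
    return pd.DataFrame({
        "probe": [f"{probe_prefix}{i:05d}" for i in range(len(values))],
        "chrom": chrom,
        "pos": start + step * np.arange(len(values)),
        "log2": values,
    })
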