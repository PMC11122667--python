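import numpy as np
import pytest

from habpop import synthetic
from habpop.calibration import BenchmarkRegion
from habpop.group_size import SpeciesParams
from habpop.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def params() -> SpeciesParams:
    return SpeciesParams()


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic study area shared across pipeline tests.

    120x120 raster, ~110 groups, known inquisitiveness 0.5; the benchmark is
    the densest high-preference 50x50 window.
    """
    seed = 11
    raster = synthetic.gen_habitat(seed, rows=120, cols=120)
    truth = synthetic.gen_groups(raster, seed=seed + 100, true_rho=0.5)
    records = synthetic.gen_detections(truth, seed=seed + 200)
    mask = synthetic.benchmark_mask(raster, rows=50, cols=50)
    bench_pop = truth.population_within(raster, mask)
    region = BenchmarkRegion(
        mask=mask,
        reported_lower=max(bench_pop * 0.5, 1.0),
        reported_best=float(bench_pop),
        reported_upper=bench_pop * 2.0,
    )
    return {
        "raster": raster,
        "truth": truth,
        "records": records,
        "mask": mask,
        "bench_pop": bench_pop,
        "region": region,
    }


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    return PipelineConfig(tensor_resolution=40)


@pytest.fixture(scope="session")
def small_result(small_world, small_config):
    return run_pipeline(
        small_world["raster"],
        small_world["records"],
        small_world["region"],
        small_config,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
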