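import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from promoterpoise.simulate import SimulationConfig, generate_all

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

TIMEPOINTS = ("ESC", "day1", "day3", "day16", "day30")


@pytest.fixture(scope="session")
def cohort():
    """A small synthetic cohort with planted truth, shared across tests."""
    return generate_all(SimulationConfig(n_genes=300, seed=11))


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run on the shared cohort."""
    from promoterpoise.pipeline import run_pipeline

    out = tmp_path_factory.mktemp("pipeline")
    return run_pipeline(
        {
            "simulate": True,
            "seed": 11,
            "simulate_config": {"n_genes": 300},
            "gsea_permutations": 200,
        },
        outdir=out,
    )


def truth_state_matrix(truth: pd.DataFrame) -> pd.DataFrame:
    cols = {f"state_{tp}": tp for tp in TIMEPOINTS}
    return truth.set_index("gene")[list(cols)].rename(columns=cols)


def brute_force_quantile(values, q: float) -> float:
    """Sort-and-interpolate quantile, independent of numpy.quantile."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    if n == 1:
        return xs[0]
    h = q * (n - 1)
    lo = int(np.floor(h))
    hi = min(lo + 1, n - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])
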