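import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mmint.pipeline import PipelineConfig, run, simulate_inputs
from mmint.types import CountMatrix

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def make_counts(array, n_control, n_treated, feature_ids=None):
    """Build a CountMatrix from a plain array for hand-computed examples."""
    array = np.asarray(array, dtype=np.int64)
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(array.shape[0])]
    samples = [f"control_{i+1}" for i in range(n_control)] + [
        f"treated_{i+1}" for i in range(n_treated)
    ]
    condition = {s: ("control" if s.startswith("control") else "treated") for s in samples}
    return CountMatrix(
        counts=pd.DataFrame(array, index=feature_ids, columns=samples),
        condition=condition,
    )


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig(seed=1)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory, default_config):
    """One full pipeline run under the default synthetic scenario (seed 1)."""
    outdir = tmp_path_factory.mktemp("default_run")
    summary = run(default_config, outdir)
    truth, *_ = simulate_inputs(default_config)
    return {"summary": summary, "outdir": outdir, "truth": truth, "config": default_config}
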