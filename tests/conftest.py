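import numpy as np
import pytest

from ccvoid.pipeline import RunConfig, run_study
from ccvoid.synthetic import CCSpec, StudySpec, generate_diurnal_study


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A small synthetic study (5 subjects x 1 visit x 5 timepoints, 96-px
    grids) with one record below the quality cutoff, generated once and
    quantified once for all pipeline-level tests."""
    out = tmp_path_factory.mktemp("study")
    n_rec = 5 * 1 * 5
    strengths = [10.0] * n_rec
    strengths[3] = 7.0  # one acquisition below the quality-8 cutoff
    spec = StudySpec(
        n_subjects=5, n_visits=1,
        cc_spec=CCSpec(grid_size=96),
        thickness_baseline_sd=30.0,
        signal_strengths=strengths,
        seed=42,
    )
    manifest_path = generate_diurnal_study(spec, out / "data")
    result = run_study(manifest_path, RunConfig(), out_dir=out / "results")
    return {"spec": spec, "manifest": manifest_path, "result": result,
            "out": out / "results", "data": out / "data"}
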