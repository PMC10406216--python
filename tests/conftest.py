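import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_sim():
    """One default simulated recording (seed 11)."""
    from respco2.synthetic import SimParams, simulate_recording
    return simulate_recording(SimParams(seed=11))


@pytest.fixture(scope="session")
def small_processed_cohort():
    """A small QA-accepted, fully preprocessed cohort (6 subjects x 1)."""
    from respco2.preprocess import preprocess_pipeline
    from respco2.synthetic import CohortParams, simulate_cohort
    cohort = simulate_cohort(
        6, 1, CohortParams(mean_duration_s=300.0, sd_duration_s=30.0,
                           min_duration_s=240.0, max_duration_s=360.0), seed=5)
    recs = []
    for out in cohort:
        proc, report = preprocess_pipeline(out.recording)
        if report.accepted:
            recs.append(proc)
    assert len(recs) >= 5
    return recs


@pytest.fixture(scope="session")
def study_cohort_results():
    """Cross-validated FCN-4L vs LR results on the default study-sized
    cohort; shared by the parameter-recovery and ordering checks."""
    from respco2.fcn import FCNSpec
    from respco2.preprocess import preprocess_pipeline
    from respco2.synthetic import simulate_cohort
    from respco2.train_eval import run_crossval
    cohort = simulate_cohort(seed=7)
    recs = []
    for out in cohort:
        proc, report = preprocess_pipeline(out.recording)
        if report.accepted:
            recs.append(proc)
    results = run_crossval(recs, FCNSpec(depth="4L"), k=5, seed=1)
    return recs, results


def rng(seed=0):
    return np.random.default_rng(seed)
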