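import pytest

from ntcpx import SyntheticConfig, derive_endpoint, generate_cohort, published_model
from ntcpx.cohort import likert_frame_from_counts


def make_endpoint_frame(n_assessed, n_baseline, n_events, timepoint="3m", seed=0):
    """Likert-score frame with exact endpoint accounting (package helper)."""
    return likert_frame_from_counts(n_assessed, n_baseline, n_events,
                                    timepoint=timepoint, seed=seed)


def endpoint_data(n: int, seed: int, timepoint: str, kind: str = "suboptimal"):
    """Generate a synthetic cohort and return (analysable frame, outcomes)."""
    cfg = SyntheticConfig(n_patients=n, seed=seed, timepoint_label=timepoint,
                          true_model=published_model(timepoint, kind))
    cohort = generate_cohort(cfg)
    ep = derive_endpoint(cohort.frame, timepoint)
    return ep.included, ep.included["outcome"].to_numpy()


@pytest.fixture(scope="session")
def cohort_3m():
    """Mid-sized 3-month-style cohort (3 true factors among 16)."""
    return endpoint_data(800, seed=42, timepoint="3m")


@pytest.fixture(scope="session")
def cohort_12m():
    """Mid-sized 12-month-style cohort (5 true factors among 16)."""
    return endpoint_data(800, seed=43, timepoint="12m")
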