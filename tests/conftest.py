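import numpy as np
import pytest

from fbnkit import BinaryNetwork, CohortSpec, SubjectTimeSeries, generate_cohort


def random_binary_network(n: int, p: float, seed: int) -> BinaryNetwork:
    rng = np.random.default_rng(seed)
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, k=1).astype(np.int8)
    adj = adj + adj.T
    return BinaryNetwork(adjacency=adj)


def random_subject(t: int, m: int, seed: int) -> SubjectTimeSeries:
    rng = np.random.default_rng(seed)
    return SubjectTimeSeries(
        data=rng.standard_normal((t, m)),
        region_labels=tuple(f"R{i:03d}" for i in range(m)),
        subject_id=f"rand_{seed}",
        group=0,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """30 subjects, 16 regions, strongly planted group effect — shared across tests."""
    spec = CohortSpec(
        n_patients=15, n_controls=15, m=16, t=134, n_modules=4,
        within_corr=0.6, between_corr=0.05, group_effect=0.5, seed=7,
    )
    return generate_cohort(spec)
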