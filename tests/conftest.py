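import numpy as np
import pytest

from sahscore.lods import OrganObservations


def random_observations(rng: np.random.Generator) -> OrganObservations:
    """Random valid first-24-h observations spanning every scoring band."""
    hr = np.sort(rng.uniform(10, 200, 2))
    sbp = np.sort(rng.uniform(20, 300, 2))
    wbc = np.sort(rng.uniform(0.1, 80, 2))
    ventilated = bool(rng.random() < 0.5)
    return OrganObservations(
        gcs_min=int(rng.integers(3, 16)),
        hr_min=hr[0], hr_max=hr[1],
        sbp_min=sbp[0], sbp_max=sbp[1],
        urea_max=float(rng.uniform(0, 40)),
        creatinine_max=float(rng.uniform(0, 4)),
        urine_24h=float(rng.uniform(0, 14)),
        ventilated_or_cpap=ventilated,
        pao2_fio2=float(rng.uniform(40, 450)) if ventilated else None,
        wbc_min=wbc[0], wbc_max=wbc[1],
        platelets_min=float(rng.uniform(0, 400)),
        bilirubin_max=float(rng.uniform(0, 6)),
        pt_excess_sec=float(rng.uniform(-2, 8)),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Study-sized synthetic cohort shared by the slower integration tests."""
    from sahscore.simulate import SimConfig, generate_cohort

    return generate_cohort(SimConfig(n=324, seed=2024))
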