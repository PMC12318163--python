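import numpy as np
import pytest

from crdesign import ContinuousDesign, CRParams, DoseInterval


@pytest.fixture
def worked_params() -> CRParams:
    """Nominal CR parameters of the worked example (toxicity -6, 0.72; efficacy -3.5, 1)."""
    return CRParams(alpha_tox=-6.0, beta_tox=0.72, alpha_eff=-3.5, beta_eff=1.0)


@pytest.fixture
def study_interval() -> DoseInterval:
    return DoseInterval(0.0, 10.0)


@pytest.fixture
def gamma() -> float:
    return 0.2


# Table 1 designs (support doses and weights as printed)
TABLE1 = {
    "I": (("D", False), [2.22, 5.31, 9.95], [0.304, 0.449, 0.247]),
    "II": (("D", True), [2.33, 4.42, 6.41], [0.409, 0.182, 0.409]),
    "III": (("c", False), [4.55, 8.33], [0.635, 0.365]),
    "IV": (("c", True), [3.61, 6.41], [0.376, 0.624]),
}


def table1_design(label: str) -> ContinuousDesign:
    _, doses, weights = TABLE1[label]
    return ContinuousDesign(np.array(doses), np.array(weights))


def random_valid_params(rng: np.random.Generator) -> CRParams:
    return CRParams(
        alpha_tox=rng.uniform(-8, 0),
        beta_tox=rng.uniform(0.2, 2.0),
        alpha_eff=rng.uniform(-6, 0),
        beta_eff=rng.uniform(0.2, 2.0),
    )
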