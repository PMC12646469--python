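import warnings

import pytest

from hivefit import default_config, generate_cohort

# sklearn 1.9 emits FutureWarnings from internal estimator defaults; they are
# not part of this package's contract
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def planted_cohort():
    """n = 200 study-condition cohort with a 3-feature planted signal."""
    cfg = default_config(
        n=200,
        seed=11,
        beta={"omega3": 1.5, "folic_acid": 1.2, "dietician_support": 1.0},
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """n = 300 study-condition cohort with no planted signal."""
    return generate_cohort(default_config(n=300, seed=5))
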