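import pytest

from sazdscreen.drive_model import CrossSpec, line_genotypes
from sazdscreen.estimators import SexRatioEstimate


@pytest.fixture
def sr_line():
    return line_genotypes("SR", driver=True)


@pytest.fixture
def even_line():
    return line_genotypes("EVEN")


@pytest.fixture
def sr_cross(sr_line):
    dam, sire = sr_line
    return CrossSpec(sire=sire, dam=dam, label="P0_SR")


def estimate(pf, lo, hi, n=5000, n_vials=40, alpha=0.05):
    return SexRatioEstimate(
        pf=pf, ci_low=lo, ci_high=hi, n=n, n_vials=n_vials,
        method="beta-binomial", alpha=alpha,
    )


@pytest.fixture
def published_screen_inputs():
    """The focal study's per-cross percent-female estimates with their 95% CIs."""
    from sazdscreen.screen_engine import ScreenInputs

    return ScreenInputs(
        e=estimate(76.5, 74.0, 78.7, n=1423),
        f=estimate(83.9, 82.7, 84.6, n=6588),
        control=estimate(50.2, 48.5, 52.1, n=2821),
        step2a=estimate(52.7, 51.1, 54.4, n=7013),
        step2b=estimate(84.6, 82.9, 86.2, n=5434),
        step3a=estimate(87.3, 85.6, 88.3, n=4307),
        step3b=estimate(87.2, 85.6, 88.7, n=4692),
        step3c=estimate(53.2, 52.1, 54.3, n=4692),
    )
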