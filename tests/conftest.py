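import numpy as np
import pytest

from drugcombo import MedianEffectFit, SynthConfig, ViabilityTable
from drugcombo.dose_response import effect_at_dose


@pytest.fixture
def cddp_fit() -> MedianEffectFit:
    """Ground-truth cisplatin median-effect curve (IC50 29.7 uM)."""
    return MedianEffectFit(dm=29.7, m=2.0, agent="CDDP")


@pytest.fixture
def am_fit() -> MedianEffectFit:
    """Ground-truth alpha-mangostin median-effect curve (IC50 19.1 uM)."""
    return MedianEffectFit(dm=19.1, m=2.0, agent="alphaM")


@pytest.fixture
def config() -> SynthConfig:
    return SynthConfig(seed=1234)


def noise_free_table(
    dm: float, m: float, doses, agent: str = "X"
) -> ViabilityTable:
    """Viability table generated exactly from a median-effect curve."""
    fit = MedianEffectFit(dm=dm, m=m, agent=agent)
    doses = np.asarray(doses, dtype=float)
    via = 100.0 * (1.0 - np.asarray(effect_at_dose(fit, doses)))
    return ViabilityTable(agent=agent, scheme="single", doses=doses,
                          viability_pct=via)
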