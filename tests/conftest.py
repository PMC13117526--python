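import warnings

import pytest

from pigtrial.synthetic import TrialConfig, generate_trial

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def trial():
    """One fixed synthetic trial at the study's default conditions."""
    return generate_trial(TrialConfig(seed=11))
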