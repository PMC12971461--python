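import pytest

import ictalkit as ik
from ictalkit.synthetic import SyntheticEEGSpec, archetype_spec, gen_baseline


@pytest.fixture(scope="session")
def baseline_recording():
    """240 s of event-free 4-channel 1/f baseline at 20 uV RMS."""
    return gen_baseline(SyntheticEEGSpec(duration=240, seed=11))


@pytest.fixture(scope="session")
def baseline_stats(baseline_recording):
    return ik.estimate_baseline(baseline_recording, (0.0, 120.0))


@pytest.fixture(scope="session")
def archetype_case():
    """One archetype recording with 4 scheduled events plus its baseline."""
    spec = archetype_spec(seed=21, n_events=4)
    rec, truth = ik.assemble_recording(spec)
    base = ik.estimate_baseline(rec, (0.0, 100.0))
    return rec, truth, base
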