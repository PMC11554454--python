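import numpy as np
import pytest

from eegstates.microstates import TemplateSet
from eegstates.montage import TEN_TWENTY_19, standard_positions
from eegstates.simulate import GroundTruthSpec, render_eeg, simulate_label_path


@pytest.fixture(scope="session")
def positions19():
    return standard_positions(TEN_TWENTY_19)


@pytest.fixture(scope="session")
def small_spec():
    """19-channel, 250 Hz ground truth for fast unit tests."""
    return GroundTruthSpec(n_channels=19, sampling_rate=250.0)


@pytest.fixture(scope="session")
def noise_free_spec():
    return GroundTruthSpec(n_channels=19, sampling_rate=250.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def rendered_subject(small_spec):
    """One 40 s noisy recording with its ground-truth label path."""
    rng = np.random.default_rng(11)
    labels = simulate_label_path(small_spec, 10_000, rng)
    rec = render_eeg(labels, small_spec, rng)
    return labels, rec


@pytest.fixture(scope="session")
def truth_templates(small_spec):
    return TemplateSet(small_spec.templates, ch_names=small_spec.ch_names,
                       labels=["A", "B", "C", "D"])
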