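import numpy as np
import pytest

from eegconsensus.synthetic import EEGEpoch, GeneratorConfig, generate_dataset


def small_config(**overrides) -> GeneratorConfig:
    """A fast study: 4 classes x 6 stimuli, 8 subjects, 16 channels."""
    defaults = dict(
        n_classes=4,
        n_stimuli_per_class=6,
        n_subjects=8,
        classes_per_subject=2,
        n_channels=16,
        n_samples=750,
        pre_stimulus_samples=250,
        seed=7,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_config())


def make_epoch(signal, sampling_rate=250.0, pre=0, **meta):
    defaults = dict(subject_id=0, stimulus_id=0, class_label=0)
    defaults.update(meta)
    return EEGEpoch(
        signal=np.asarray(signal, dtype=float),
        sampling_rate=sampling_rate,
        pre_stimulus_samples=pre,
        **defaults,
    )
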