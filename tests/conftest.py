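import numpy as np
import pytest

from cryscope import (
    RunConfig, SimulateConfig, default_profiles, synth_unit_dataset,
    synth_session, mfcc, spectrogram,
)
from cryscope.simulate import AUDIO_FS

SEED = 20230920


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def small_session():
    """One compact synthetic session shared by read-only tests."""
    sim = SimulateConfig(n_cry_episodes=2, n_distress_episodes=1,
                         resting_block_s=40.0, units_per_episode=8)
    return synth_session(SEED, sim=sim)


@pytest.fixture(scope="session")
def unit_dataset():
    """Shared labelled cry/distress units with MFCCs and spectrograms."""
    waves, labels = synth_unit_dataset(120, SEED)
    feats = np.stack([mfcc(w, AUDIO_FS) for w in waves])
    imgs = np.stack([spectrogram(w, AUDIO_FS) for w in waves])
    return {"waves": waves, "labels": np.asarray(labels),
            "mfcc": feats, "spectrograms": imgs}


@pytest.fixture()
def run_config(tmp_path):
    return RunConfig(
        seed=SEED, out_dir=str(tmp_path / "out"), classifier="rf",
        classifier_n_units=60,
        simulate=SimulateConfig(n_cry_episodes=1, n_distress_episodes=1,
                                resting_block_s=36.0, units_per_episode=6),
    )
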