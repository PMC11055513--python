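import numpy as np
import pytest

from itdeeg import (StimulusSpec, SynthRecordingConfig, make_filtered_clicks,
                    make_sam_itdenv, make_sam_itdfs)
from itdeeg.caep import lowpass_caep
from itdeeg.preprocess import run_pipeline
from itdeeg.synth_eeg import (CaepTemplateParams, NoiseModel,
                              simulate_recording)

SIM_FS = 1000.0  # simulation sampling rate used throughout the tests


@pytest.fixture(scope="session")
def itdfs_signal():
    return make_sam_itdfs(StimulusSpec())


@pytest.fixture(scope="session")
def itdenv_signal():
    return make_sam_itdenv(
        StimulusSpec(experiment="itdenv_sam", f_c=4000.0, f_m=40.0))


@pytest.fixture(scope="session")
def clicks_signal():
    return make_filtered_clicks(
        StimulusSpec(experiment="iptd_clicks", f_c=4000.0, f_m=160.0))


def noiseless_config(**kw):
    """60-trial-equivalent noiseless configuration at the 1-kHz test rate."""
    defaults = dict(
        stimulus=StimulusSpec(),
        n_trials=4,
        fs=SIM_FS,
        noise=NoiseModel(white_sd_uV=0.0, pink_sd_uV=0.0),
        caep=CaepTemplateParams(latency_jitter_sd_ms=0.0),
    )
    defaults.update(kw)
    return SynthRecordingConfig(**defaults)


@pytest.fixture(scope="session")
def noiseless_evoked():
    """Evoked response of a noiseless simulation through the full chain."""
    rec = simulate_recording(noiseless_config())
    return rec, run_pipeline(rec)


@pytest.fixture(scope="session")
def noiseless_caep_evoked(noiseless_evoked):
    _rec, ev = noiseless_evoked
    return lowpass_caep(ev)
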