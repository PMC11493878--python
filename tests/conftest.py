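import numpy as np
import pandas as pd
import pytest

from plaslab import detector, layout, synth


@pytest.fixture(scope="session")
def small_cfg():
    return synth.SynthConfig(n_channels=16)


@pytest.fixture(scope="session")
def hc_profile():
    return synth.ParticipantProfile(
        id="HC01", group="HC", age=68.0, gender="F", moca=28.0,
        responsiveness=1.0, sw_density=8.0, night_gain=(1.0, 1.0, 1.0),
        memory_slope=0.5, abeta_slope=0.0)


@pytest.fixture(scope="session")
def ci_profile():
    return synth.ParticipantProfile(
        id="CI01", group="CI", age=72.0, gender="M", moca=23.0,
        responsiveness=1.0, sw_density=5.0, night_gain=(0.4, 0.7, 1.0),
        memory_slope=0.5, abeta_slope=0.0008)


@pytest.fixture(scope="session")
def benchmark_rec():
    """Noise-free template-matched slow-wave night for detector checks."""
    return synth.benchmark_recording(n_events=30, seed=0)


@pytest.fixture(scope="session")
def benchmark_template(benchmark_rec):
    return detector.build_template(benchmark_rec.channel_names,
                                   benchmark_rec.channel_positions)


@pytest.fixture(scope="session")
def short_night(small_cfg, hc_profile):
    """A 10-minute default-SNR synthetic stimulation night."""
    return synth.generate_night(hc_profile, "E1", 10.0, small_cfg, seed=42)


def make_recording(data, rate=200.0, night="E1", hypnogram=None, events=None):
    """Wrap a raw array into a Recording with a spiral layout."""
    n_ch, n_samp = data.shape
    names, pos = layout.spiral_layout(n_ch)
    if hypnogram is None:
        hypnogram = np.array(["N2"] * int(n_samp / rate // 30))
    if events is None:
        events = pd.DataFrame(columns=["kind", "time", "amplitude"])
    return synth.Recording(data=np.asarray(data, np.float32), rate=rate,
                           channel_names=names, channel_positions=pos,
                           hypnogram=hypnogram, events=events, night=night)
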