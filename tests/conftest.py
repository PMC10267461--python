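import numpy as np
import pytest

from coldwave.pwd import KernelParams, recompose
from coldwave.signals import SampledSignal

FS = 2000.0


@pytest.fixture
def fs():
    return FS


@pytest.fixture
def default_params():
    """A finger-like two-kernel beat: systolic Gamma peak at 0.154 s,
    diastolic Gaussian at 0.42 s."""
    return KernelParams(s1=0.4, alpha1=3.0, beta1=13.0,
                        a2=0.45, mu2=0.42, sigma2=0.09)


@pytest.fixture
def clean_beat(default_params):
    t = np.arange(int(1.2 * FS)) / FS
    return SampledSignal(values=recompose(default_params, t), fs=FS)


def make_template(values, fs=FS, median_bbi=1.0):
    """Minimal template stand-in for fit/feature entry points."""
    class _T:
        pass

    t = _T()
    t.values = np.asarray(values, dtype=float)
    t.fs = fs
    t.median_bbi = median_bbi
    return t
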