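import numpy as np
import pytest

from noda2d import BandSpec, SpectralSeries, SyntheticSpec, generate_series


def naive_corr_maps(Itilde):
    """Brute-force triple-loop synchronous/asynchronous maps.

    Independent of the package's vectorized route: builds the Noda matrix
    element by element and evaluates both double sums with Python loops.
    """
    Itilde = np.asarray(Itilde, dtype=float)
    k, n = Itilde.shape
    M = [[0.0 if i == j else 1.0 / (np.pi * (j - i)) for j in range(k)] for i in range(k)]
    sync = np.zeros((n, n))
    async_ = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            s = 0.0
            t = 0.0
            for i in range(k):
                s += Itilde[i, a] * Itilde[i, b]
                inner = 0.0
                for j in range(k):
                    inner += M[i][j] * Itilde[j, b]
                t += Itilde[i, a] * inner
            sync[a, b] = s / (k - 1)
            async_[a, b] = t / (k - 1)
    return sync, async_


THREE_BAND = (
    BandSpec(center=980.0, width=10.0, delta_amplitude=0.2, onset_T=270.0, response_width=8.0),
    BandSpec(center=1030.0, width=10.0, delta_amplitude=0.2, onset_T=290.0, response_width=8.0),
    BandSpec(center=1080.0, width=10.0, delta_amplitude=0.2, onset_T=310.0, response_width=8.0),
)


def three_band_spec(noise_sigma=0.0, seed=0):
    """Three well-separated sigmoid bands with staggered onsets 270/290/310 K.

    Band separation (50 cm^-1) is 5 half-widths; onset separation (20 K) is
    2.5 response widths; the standard 250-340 K, 10 K step acquisition.
    """
    return SyntheticSpec(
        bands=THREE_BAND,
        nu_min=930.0,
        nu_max=1130.0,
        noise_sigma=noise_sigma,
        seed=seed,
    )


@pytest.fixture
def three_band_series():
    return generate_series(three_band_spec())


@pytest.fixture
def small_series():
    """A tiny arbitrary (non-degenerate) 3-spectrum, 4-channel series."""
    rng = np.random.default_rng(42)
    return SpectralSeries(
        nu=np.array([900.0, 904.0, 908.0, 912.0]),
        T=np.array([250.0, 260.0, 270.0]),
        I=rng.uniform(0.1, 1.0, size=(3, 4)),
        meta={"origin": "fixture"},
    )
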