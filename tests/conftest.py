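import numpy as np
import pytest

from spectrop.spectra_io import SpectrumSet


@pytest.fixture()
def toy_set():
    """Random 6-sample, 5-band set with a trait, for oracle comparisons."""
    rng = np.random.default_rng(42)
    grid = np.arange(500, 505)
    refl = rng.uniform(0.05, 0.9, size=(6, 5))
    lpc = rng.uniform(0.5, 4.0, size=6)
    return SpectrumSet(grid, refl, lpc=lpc)


@pytest.fixture()
def medium_set():
    """Random 30-sample, 50-band set for brute-force map oracles."""
    rng = np.random.default_rng(7)
    grid = np.arange(600, 650)
    refl = rng.uniform(0.05, 0.95, size=(30, 50))
    lpc = rng.uniform(0.5, 4.0, size=30)
    return SpectrumSet(grid, refl, lpc=lpc)


def bruteforce_pair_r2(s, index_type):
    """Independent per-pair univariate OLS oracle for pairwise_r2_map."""
    from scipy import stats

    n_b = s.n_bands
    out = np.full((n_b, n_b), np.nan)
    for i in range(n_b):
        for j in range(n_b):
            if i == j:
                continue
            r1 = s.reflectance[:, i]
            r2 = s.reflectance[:, j]
            if index_type == "RSI":
                x = r1 / r2
            elif index_type == "DSI":
                x = r1 - r2
            else:
                x = (r1 - r2) / (r1 + r2)
            if np.ptp(x) == 0:
                continue
            res = stats.linregress(x, s.lpc)
            out[i, j] = res.rvalue**2
    return out


def direct_cwt(f, psi, scale_index, support=8):
    """Direct-summation CWT oracle with explicit mirror padding."""
    dil = 2**scale_index
    pad = support * dil
    padded = np.pad(f, pad, mode="symmetric")
    v = np.arange(-pad, pad + 1, dtype=float)
    g = psi(v / dil) / np.sqrt(dil)
    out = np.empty(len(f))
    for b in range(len(f)):
        out[b] = padded[b : b + 2 * pad + 1] @ g
    return out
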