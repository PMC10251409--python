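"""Continuous wavelet transform of reflectance spectra and scalogram features.

Each spectrum ``f(λ)`` is projected onto translated, dilated copies of a
mother wavelet ψ along the wavelength axis:

    C(a, b) = Σ_λ f(λ) · s_a^{-1/2} · ψ((λ − b) / s_a) · Δλ,

with dyadic dilations ``s_a = 2^a`` for scale indices ``a = 1..10``,
Δλ = 1 nm, evaluated at every grid position ``b``.  Boundaries are handled
by mirror (symmetric) padding of length ``8·s_a`` on each side — the full
support of the sampled wavelet kernel — and the output is trimmed back to
the original grid.  The ``1/√s`` factor is L2 normalization: it rescales
each scale's coefficients by a positive constant only, so per-scale
correlation maps and selected wavelengths do not depend on it.

The default mother wavelet is the Mexican Hat (negative-normalized second
derivative of a Gaussian, two vanishing moments); Gaussian-derivative
wavelets of order 1–4 and a zero-mean real Morlet are available as a
configurable screening set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from scipy.signal import fftconvolve

from .spectra_io import SpectrumSet
from .index_search import ScoreMap, DegeneracyError, _VAR_TOL

__all__ = [
    "WaveletFeature",
    "WaveletCoefficients",
    "mexh",
    "wavelet_function",
    "WAVELET_NAMES",
    "cwt_transform",
    "scalogram_r2_map",
    "select_per_scale_features",
    "fit_wavelet_model",
    "coefficients_at",
]

logger = logging.getLogger(__name__)

#: half-width of the sampled wavelet support, in units of the dilation
_SUPPORT = 8


def mexh(u) -> np.ndarray | float:
    """Mexican Hat wavelet ψ(u) = (2 / (√3·π^{1/4})) (1 − u²) exp(−u²/2)."""
    u = np.asarray(u, dtype=np.float64)
    return (2.0 / (np.sqrt(3.0) * np.pi**0.25)) * (1.0 - u**2) * np.exp(-(u**2) / 2.0)


def _gaus_poly(order: int) -> np.polynomial.Polynomial:
    # Polynomial part of d^n/du^n exp(-u^2/2) (probabilists' Hermite, signed).
    p = np.polynomial.Polynomial([1.0])
    u = np.polynomial.Polynomial([0.0, 1.0])
    for _ in range(order):
        p = p.deriv() - u * p
    return p


def _l2_normalized(fn):
    u = np.linspace(-12, 12, 48001)
    nrm = np.sqrt(np.trapezoid(fn(u) ** 2, u))
    return lambda x, _fn=fn, _nrm=nrm: _fn(np.asarray(x, dtype=np.float64)) / _nrm


def _make_registry() -> dict:
    reg = {"mexh": mexh}
    for order in range(1, 5):
        poly = _gaus_poly(order)
        fn = lambda u, _p=poly: _p(np.asarray(u, dtype=np.float64)) * np.exp(
            -(np.asarray(u, dtype=np.float64) ** 2) / 2.0
        )
        reg[f"gaus{order}"] = _l2_normalized(fn)
    omega0 = 5.0
    kappa = np.exp(-(omega0**2) / 2.0)  # zero-mean correction
    morlet = lambda u: (np.cos(omega0 * np.asarray(u, dtype=np.float64)) - kappa) * np.exp(
        -(np.asarray(u, dtype=np.float64) ** 2) / 2.0
    )
    reg["morlet"] = _l2_normalized(morlet)
    return reg


_REGISTRY = _make_registry()
WAVELET_NAMES = tuple(_REGISTRY)


def wavelet_function(name: str):
    """Look up a mother wavelet ψ(u) by name."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown wavelet {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


@dataclass(frozen=True)
class WaveletFeature:
    """A (wavelength, scale) coefficient location with calibration statistics.

    ``scale_dilation = 2**scale_index`` under the default dyadic rule; the
    calibration model is ``LPC = slope × coefficient + intercept``.
    """

    wavelength_nm: int
    scale_index: int
    wavelet_name: str = "mexh"
    r2_cal: float = np.nan
    slope: float = np.nan
    intercept: float = np.nan

    @property
    def scale_dilation(self) -> float:
        return float(2**self.scale_index)

    @property
    def name(self) -> str:
        return f"{self.wavelet_name}({self.wavelength_nm}nm,{self.scale_index})"


@dataclass
class WaveletCoefficients:
    """Per-sample CWT coefficient stack: ``coefficients[sample, scale, band]``."""

    wavelengths_nm: np.ndarray
    scale_indices: np.ndarray
    coefficients: np.ndarray
    wavelet_name: str = "mexh"

    def __post_init__(self) -> None:
        self.scale_indices = np.asarray(self.scale_indices, dtype=np.int64)
        if self.coefficients.shape[1:] != (
            len(self.scale_indices),
            len(self.wavelengths_nm),
        ):
            raise ValueError("coefficient stack shape does not match axes")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite wavelet coefficients")

    def at(self, scale_index: int, wavelength_nm: int) -> np.ndarray:
        si = int(np.flatnonzero(self.scale_indices == scale_index)[0])
        bi = int(wavelength_nm - self.wavelengths_nm[0])
        return self.coefficients[:, si, bi]


def _kernel(name: str, dilation: int) -> np.ndarray:
    psi = wavelet_function(name)
    v = np.arange(-_SUPPORT * dilation, _SUPPORT * dilation + 1, dtype=np.float64)
    return psi(v / dilation) / np.sqrt(dilation)


def cwt_transform(
    s: SpectrumSet,
    wavelet_name: str = "mexh",
    scale_indices=range(1, 11),
) -> WaveletCoefficients:
    """Transform every spectrum at the requested dyadic scales."""
    scale_indices = np.asarray(list(scale_indices), dtype=np.int64)
    if scale_indices.size == 0 or np.any(scale_indices < 1):
        raise ValueError("scale indices must be positive integers")
    wavelet_function(wavelet_name)  # validate name early
    n, w = s.reflectance.shape
    out = np.empty((n, scale_indices.size, w), dtype=np.float64)
    for k, a in enumerate(scale_indices):
        dil = int(2**a)
        pad = _SUPPORT * dil
        g = _kernel(wavelet_name, dil)
        padded = np.pad(s.reflectance, ((0, 0), (pad, pad)), mode="symmetric")
        # cross-correlation with g == convolution with the reversed kernel
        conv = fftconvolve(padded, g[::-1][None, :], mode="same", axes=1)
        out[:, k, :] = conv[:, pad : pad + w]
    return WaveletCoefficients(
        wavelengths_nm=s.wavelengths_nm.copy(),
        scale_indices=scale_indices,
        coefficients=out,
        wavelet_name=wavelet_name,
    )


def coefficients_at(
    s: SpectrumSet, features: list[WaveletFeature]
) -> np.ndarray:
    """Evaluate the CWT only at the given (wavelength, scale) locations.

    Returns an ``(n_samples, n_features)`` matrix; much cheaper than a full
    transform when only a handful of selected features are needed.
    """
    n, w = s.reflectance.shape
    out = np.empty((n, len(features)), dtype=np.float64)
    for j, f in enumerate(features):
        dil = int(2**f.scale_index)
        pad = _SUPPORT * dil
        g = _kernel(f.wavelet_name, dil)
        b = int(f.wavelength_nm - s.wavelengths_nm[0])
        padded = np.pad(s.reflectance, ((0, 0), (pad, pad)), mode="symmetric")
        seg = padded[:, b : b + 2 * pad + 1]
        out[:, j] = seg @ g
    return out


def scalogram_r2_map(c: WaveletCoefficients, lpc: np.ndarray) -> ScoreMap:
    """Squared Pearson correlation of each (scale, wavelength) cell with LPC."""
    y = np.asarray(lpc, dtype=np.float64)
    n = c.coefficients.shape[0]
    if y.shape != (n,):
        raise ValueError("lpc length does not match coefficient sample count")
    yc = y - y.mean()
    var_y = float(yc @ yc) / n
    if var_y <= _VAR_TOL:
        raise ValueError("LPC is constant; correlation undefined")
    X = c.coefficients  # (n, S, W)
    mx = X.mean(axis=0)
    cov = np.einsum("i,isw->sw", yc, X) / n
    var_x = np.einsum("isw,isw->sw", X, X) / n - mx * mx
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = (cov * cov) / (var_x * var_y)
    r2[var_x <= _VAR_TOL] = np.nan
    np.clip(r2, 0.0, 1.0, out=r2)
    return ScoreMap(
        axis1=c.scale_indices.copy(),
        axis2=c.wavelengths_nm.copy(),
        values=r2,
        kind="scalogram",
        label=c.wavelet_name,
    )


def select_per_scale_features(smap: ScoreMap) -> list[WaveletFeature]:
    """Per scale, the wavelength maximizing R² (ties → smallest wavelength)."""
    if smap.kind != "scalogram":
        raise ValueError("expected a scalogram score map")
    feats: list[WaveletFeature] = []
    for i, a in enumerate(smap.axis1):
        row = smap.values[i]
        if not np.any(np.isfinite(row)):
            logger.warning("scale %d has no defined scalogram cell; feature omitted", a)
            continue
        j = int(np.nanargmax(row))  # first occurrence == smallest wavelength
        feats.append(
            WaveletFeature(
                wavelength_nm=int(smap.axis2[j]),
                scale_index=int(a),
                wavelet_name=smap.label or "mexh",
                r2_cal=float(row[j]),
            )
        )
    return feats


def fit_wavelet_model(
    feature: WaveletFeature, c_cal: WaveletCoefficients, lpc: np.ndarray
) -> WaveletFeature:
    """OLS of LPC on the coefficient at the feature's (wavelength, scale)."""
    x = c_cal.at(feature.scale_index, feature.wavelength_nm)
    y = np.asarray(lpc, dtype=np.float64)
    if np.var(x) <= _VAR_TOL:
        raise DegeneracyError(f"{feature.name}: coefficient constant on calibration data")
    res = stats.linregress(x, y)
    return replace(
        feature,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2_cal=float(res.rvalue**2),
    )
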