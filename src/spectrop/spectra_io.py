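"""Reading, writing and validation of leaf reflectance spectra.

The exchange object for the whole package is :class:`SpectrumSet`: a set of
leaf spectra on a common integer-nanometre wavelength grid, optionally
carrying the measured leaf phosphorus concentration (LPC, mg g⁻¹) and
per-sample metadata (cultivar, phosphorus treatment, leaf layer).

Two plain-text layouts are supported:

* wide CSV (primary): ``id,cultivar,treatment,layer,lpc,350,351,...,2500``
  — one row per sample, one column per wavelength;
* long CSV: ``id,wavelength_nm,reflectance`` triples, with traits supplied
  in a separate CSV ``id,cultivar,treatment,layer,lpc``.

Reflectance is stored as a fraction of incident light in [0, 1]; percent
inputs (0–100) are auto-detected and rescaled with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpectrumSet",
    "GridError",
    "RangeError",
    "IdentityError",
    "FULL_GRID",
    "read_spectra",
    "write_spectra",
    "subset_bands",
]

logger = logging.getLogger(__name__)

#: Default full grid of the field spectrometer product: 350..2500 nm at 1 nm.
FULL_GRID = np.arange(350, 2501)

_META_COLUMNS = ("cultivar", "treatment", "layer")
_RANGE_TOL = 1e-6


class GridError(ValueError):
    """Wavelength header is not a strictly increasing uniform 1 nm grid."""


class RangeError(ValueError):
    """Reflectance values outside [0, 1] beyond tolerance."""


class IdentityError(ValueError):
    """Duplicate or inconsistent sample identifiers."""


@dataclass
class SpectrumSet:
    """Aligned leaf spectra with optional trait and metadata columns.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing integer wavelengths with a uniform 1 nm step.
    reflectance
        ``(n_samples, n_bands)`` matrix of reflectance fractions in [0, 1].
    lpc
        Per-sample leaf phosphorus concentration (mg g⁻¹), or ``None`` for
        prediction-only sets.
    meta
        Per-sample metadata; must contain an ``id`` column, may contain
        ``cultivar``, ``treatment`` (P0–P3) and ``layer``
        (upper/middle/lower).
    """

    wavelengths_nm: np.ndarray
    reflectance: np.ndarray
    lpc: np.ndarray | None = None
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm)
        if self.wavelengths_nm.dtype.kind == "f":
            if not np.allclose(self.wavelengths_nm % 1, 0):
                raise GridError("fractional wavelengths are not supported")
            self.wavelengths_nm = self.wavelengths_nm.astype(np.int64)
        self.wavelengths_nm = self.wavelengths_nm.astype(np.int64)
        self.reflectance = np.asarray(self.reflectance, dtype=np.float64)
        if self.reflectance.ndim != 2:
            raise ValueError("reflectance must be 2-D (samples x bands)")
        steps = np.diff(self.wavelengths_nm)
        if self.wavelengths_nm.size < 1 or np.any(steps != 1):
            raise GridError("wavelength grid must be strictly increasing with a 1 nm step")
        if self.reflectance.shape[1] != self.wavelengths_nm.size:
            raise ValueError(
                f"reflectance has {self.reflectance.shape[1]} bands, "
                f"grid has {self.wavelengths_nm.size}"
            )
        if not np.all(np.isfinite(self.reflectance)):
            raise RangeError("reflectance contains non-finite values")
        if (self.reflectance.min() < -_RANGE_TOL) or (
            self.reflectance.max() > 1.0 + _RANGE_TOL
        ):
            raise RangeError(
                "reflectance outside [0, 1] beyond tolerance "
                f"(min {self.reflectance.min():.4g}, max {self.reflectance.max():.4g})"
            )
        n = self.reflectance.shape[0]
        if self.lpc is not None:
            self.lpc = np.asarray(self.lpc, dtype=np.float64)
            if self.lpc.shape != (n,):
                raise ValueError("lpc length does not match sample count")
            if not np.all(np.isfinite(self.lpc)) or np.any(self.lpc <= 0):
                raise ValueError("lpc values must be finite and > 0")
        if self.meta is None or len(self.meta) == 0:
            self.meta = pd.DataFrame({"id": [f"S{i:04d}" for i in range(n)]})
        self.meta = self.meta.reset_index(drop=True)
        if "id" not in self.meta.columns:
            raise IdentityError("meta must contain an 'id' column")
        if len(self.meta) != n:
            raise ValueError("meta row count does not match sample count")
        if self.meta["id"].duplicated().any():
            dups = self.meta["id"][self.meta["id"].duplicated()].tolist()
            raise IdentityError(f"duplicate sample ids: {dups}")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    @property
    def ids(self) -> np.ndarray:
        return self.meta["id"].to_numpy()

    def require_lpc(self) -> np.ndarray:
        """Return LPC values or raise if the set is prediction-only."""
        if self.lpc is None:
            raise ValueError("operation requires lpc, but this SpectrumSet has none")
        return self.lpc

    def band(self, wavelength_nm: int) -> np.ndarray:
        """Per-sample reflectance at one wavelength."""
        return self.reflectance[:, self.band_index(wavelength_nm)]

    def band_index(self, wavelength_nm: int) -> int:
        lo, hi = self.wavelengths_nm[0], self.wavelengths_nm[-1]
        if not (lo <= wavelength_nm <= hi):
            raise IndexError(f"wavelength {wavelength_nm} nm outside grid [{lo}, {hi}]")
        return int(wavelength_nm - lo)

    def take(self, idx: np.ndarray) -> "SpectrumSet":
        """Row subset (e.g. a calibration/validation split)."""
        idx = np.asarray(idx)
        return SpectrumSet(
            wavelengths_nm=self.wavelengths_nm.copy(),
            reflectance=self.reflectance[idx],
            lpc=None if self.lpc is None else self.lpc[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
        )


# ----------------------------------------------------------------------
def _validate_header_grid(cols: list[str]) -> np.ndarray:
    try:
        grid = np.array([int(c) for c in cols], dtype=np.int64)
    except ValueError as exc:
        raise GridError(f"non-integer wavelength column in header: {exc}") from None
    if np.any(np.diff(grid) != 1):
        raise GridError("wavelength columns are not a uniform 1 nm grid")
    return grid


def _rescale_percent(refl: np.ndarray) -> np.ndarray:
    if refl.size and np.nanmax(refl) > 1.5:
        warnings.warn(
            "reflectance maximum exceeds 1.5; interpreting values as percent "
            "and dividing by 100",
            stacklevel=3,
        )
        logger.warning("percent reflectance detected; rescaling by 1/100")
        refl = refl / 100.0
    return refl


def read_spectra(
    path: str | Path,
    layout: str = "wide",
    traits_path: str | Path | None = None,
) -> SpectrumSet:
    """Read a spectral dataset from CSV.

    Parameters
    ----------
    path
        CSV file. For ``layout="wide"``: one row per sample, wavelength
        columns named by integer nm, plus optional ``id``, ``lpc``,
        cultivar/treatment/layer columns. For ``layout="long"``:
        ``id,wavelength_nm,reflectance`` triples.
    layout
        ``"wide"`` or ``"long"``.
    traits_path
        Optional trait CSV (``id,cultivar,treatment,layer,lpc``) for the
        long layout.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout == "wide":
        df = pd.read_csv(path)
        wl_cols = [c for c in df.columns if str(c).strip().lstrip("-").isdigit()]
        if not wl_cols:
            raise GridError("no wavelength columns found in wide CSV header")
        grid = _validate_header_grid([str(c) for c in wl_cols])
        refl = _rescale_percent(df[wl_cols].to_numpy(dtype=np.float64))
        lpc = df["lpc"].to_numpy(dtype=np.float64) if "lpc" in df.columns else None
        meta_cols = ["id"] + [c for c in _META_COLUMNS if c in df.columns]
        if "id" in df.columns:
            meta = df[meta_cols].copy()
        else:
            meta = pd.DataFrame({"id": [f"S{i:04d}" for i in range(len(df))]})
        return SpectrumSet(grid, refl, lpc=lpc, meta=meta)
    if layout == "long":
        df = pd.read_csv(path)
        required = {"id", "wavelength_nm", "reflectance"}
        if not required.issubset(df.columns):
            raise ValueError(f"long CSV must have columns {sorted(required)}")
        wide = df.pivot(index="id", columns="wavelength_nm", values="reflectance")
        wide = wide.sort_index(axis=1)
        grid = _validate_header_grid([str(int(c)) for c in wide.columns])
        if wide.isna().any().any():
            raise ValueError("long CSV does not cover every (sample, wavelength) cell")
        meta = pd.DataFrame({"id": wide.index.astype(str)})
        lpc = None
        if traits_path is not None:
            traits = pd.read_csv(traits_path, dtype={"id": str})
            traits = meta.merge(traits, on="id", how="left")
            if "lpc" in traits.columns:
                lpc = traits["lpc"].to_numpy(dtype=np.float64)
            meta = traits[["id"] + [c for c in _META_COLUMNS if c in traits.columns]]
        refl = _rescale_percent(wide.to_numpy(dtype=np.float64))
        return SpectrumSet(grid, refl, lpc=lpc, meta=meta)
    raise ValueError(f"unknown layout {layout!r}; expected 'wide' or 'long'")


def write_spectra(s: SpectrumSet, path: str | Path) -> None:
    """Write a SpectrumSet as the wide CSV layout (round-trip safe)."""
    path = Path(path)
    out = s.meta.copy()
    if s.lpc is not None:
        out["lpc"] = s.lpc
    spec = pd.DataFrame(
        s.reflectance, columns=[str(w) for w in s.wavelengths_nm]
    )
    out = pd.concat([out.reset_index(drop=True), spec], axis=1)
    out.to_csv(path, index=False, float_format="%.12g")


def subset_bands(s: SpectrumSet, lo_nm: int, hi_nm: int) -> SpectrumSet:
    """Restrict a SpectrumSet to wavelengths in [lo_nm, hi_nm] (inclusive)."""
    if lo_nm > hi_nm:
        raise IndexError(f"lo_nm {lo_nm} > hi_nm {hi_nm}")
    lo_i = s.band_index(lo_nm)
    hi_i = s.band_index(hi_nm)
    return SpectrumSet(
        wavelengths_nm=s.wavelengths_nm[lo_i : hi_i + 1].copy(),
        reflectance=s.reflectance[:, lo_i : hi_i + 1].copy(),
        lpc=None if s.lpc is None else s.lpc.copy(),
        meta=s.meta.copy(),
    )
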