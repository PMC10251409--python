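"""Two-band spectral index computation and exhaustive band-pair optimization.

Three classic two-band formulations are searched over every ordered band
pair (λ1, λ2) of the wavelength grid:

* ``RSI  = R_λ1 / R_λ2``            (ratio spectral index)
* ``DSI  = R_λ1 − R_λ2``            (difference spectral index)
* ``NDSI = (R_λ1 − R_λ2) / (R_λ1 + R_λ2)``  (normalized difference)

For each pair the score is the squared Pearson correlation between the
index and the trait (identical to the R² of a univariate ordinary
least-squares fit).  The full 2151 × 2151 scan is vectorized: the DSI map
is computed in closed form from the band covariance matrix, while RSI and
NDSI (nonlinear in the band values) are computed one λ1 row at a time.

Undefined cells — the diagonal, pairs whose index is constant across
samples, and pairs with a near-zero denominator for some sample — carry
NaN and are excluded from ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .spectra_io import SpectrumSet

__all__ = [
    "INDEX_TYPES",
    "IndexFeature",
    "ScoreMap",
    "DegeneracyError",
    "compute_index",
    "pairwise_r2_map",
    "select_top_index_features",
    "fit_index_model",
    "optimize_indices",
]

logger = logging.getLogger(__name__)

INDEX_TYPES = ("RSI", "DSI", "NDSI")
_DENOM_TOL = 1e-12
_VAR_TOL = 1e-24
#: an index whose variance is below this fraction of its mean-square scale is
#: treated as constant across samples (undefined cell); the centred-moment
#: algebra has no significant digits left below this point
_REL_VAR_TOL = 1e-12


class DegeneracyError(ValueError):
    """An index is numerically degenerate (zero denominator or constant)."""


@dataclass(frozen=True)
class IndexFeature:
    """A two-band index with its calibration linear-model statistics.

    The calibration model is ``LPC = slope × index + intercept``.
    """

    index_type: str
    lambda1_nm: int
    lambda2_nm: int
    r2_cal: float = np.nan
    slope: float = np.nan
    intercept: float = np.nan

    def __post_init__(self) -> None:
        if self.index_type not in INDEX_TYPES:
            raise ValueError(f"unknown index type {self.index_type!r}")
        if self.lambda1_nm == self.lambda2_nm:
            raise ValueError("index bands must be distinct")

    @property
    def name(self) -> str:
        return f"{self.index_type}({self.lambda1_nm},{self.lambda2_nm})"


@dataclass
class ScoreMap:
    """Dense R² grid over band pairs or over (scale × wavelength).

    ``values[i, j]`` is the score for ``(axis1[i], axis2[j])``; undefined
    cells are NaN.  ``kind`` is ``"pairwise-index"`` or ``"scalogram"``.
    """

    axis1: np.ndarray
    axis2: np.ndarray
    values: np.ndarray
    kind: str
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.axis1), len(self.axis2)):
            raise ValueError("values shape does not match axes")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("R² values outside [0, 1]")

    def argmax(self) -> tuple[int, int]:
        """(axis1 value, axis2 value) of the best defined cell."""
        if not np.any(np.isfinite(self.values)):
            raise ValueError("score map has no defined cell")
        i, j = np.unravel_index(np.nanargmax(self.values), self.values.shape)
        return int(self.axis1[i]), int(self.axis2[j])


def compute_index(
    s: SpectrumSet, index_type: str, lambda1_nm: int, lambda2_nm: int
) -> np.ndarray:
    """Evaluate one two-band index per sample."""
    if index_type not in INDEX_TYPES:
        raise ValueError(f"unknown index type {index_type!r}")
    r1 = s.band(lambda1_nm)
    r2 = s.band(lambda2_nm)
    if index_type == "DSI":
        return r1 - r2
    denom = r2 if index_type == "RSI" else r1 + r2
    bad = np.abs(denom) <= _DENOM_TOL
    if np.any(bad):
        offender = s.ids[np.argmax(bad)]
        raise DegeneracyError(
            f"{index_type}({lambda1_nm},{lambda2_nm}): near-zero denominator "
            f"for sample {offender!r}"
        )
    return (r1 / r2) if index_type == "RSI" else (r1 - r2) / denom


def _r2_columns(x: np.ndarray, yc: np.ndarray, var_y: float) -> np.ndarray:
    """Squared Pearson correlation of each column of ``x`` with centred ``yc``."""
    n = x.shape[0]
    mx = x.mean(axis=0)
    cov = (yc @ x) / n  # yc has zero mean, so this is the covariance
    ms = np.einsum("ij,ij->j", x, x) / n
    var_x = ms - mx * mx
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = (cov * cov) / (var_x * var_y)
    r2[(var_x <= _VAR_TOL) | (var_x <= _REL_VAR_TOL * ms)] = np.nan
    return np.clip(r2, 0.0, 1.0, out=r2)


def pairwise_r2_map(s: SpectrumSet, index_type: str, step: int = 1) -> ScoreMap:
    """R² of every ordered band pair's index against LPC.

    ``step`` strides the band grid in both axes for quick looks; the
    default scans all pairs at full 1 nm resolution.
    """
    if index_type not in INDEX_TYPES:
        raise ValueError(f"unknown index type {index_type!r}")
    y = s.require_lpc()
    if s.n_samples < 3:
        raise ValueError("pairwise scan needs at least 3 samples")
    grid = s.wavelengths_nm[::step]
    R = np.ascontiguousarray(s.reflectance[:, ::step])
    n, m = R.shape
    yc = y - y.mean()
    var_y = float(yc @ yc) / n
    if var_y <= _VAR_TOL:
        raise ValueError("LPC is constant; correlation undefined")

    if index_type == "DSI":
        # DSI is linear in the bands: one Gram matrix gives the whole map.
        Rc = R - R.mean(axis=0)
        c = (Rc.T @ yc) / n
        C = (Rc.T @ Rc) / n
        v = np.diag(C).copy()
        vsum = v[:, None] + v[None, :]
        var_pair = vsum - 2.0 * C
        num = (c[:, None] - c[None, :]) ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = num / (var_pair * var_y)
        vals[(var_pair <= _VAR_TOL) | (var_pair <= _REL_VAR_TOL * vsum)] = np.nan
        np.clip(vals, 0.0, 1.0, out=vals)
    else:
        vals = np.empty((m, m), dtype=np.float64)
        bad_band = np.abs(R).min(axis=0) <= _DENOM_TOL  # for RSI denominators
        for i in range(m):
            r1 = R[:, i][:, None]
            if index_type == "RSI":
                X = r1 / R
                vals[i] = _r2_columns(X, yc, var_y)
                vals[i, bad_band] = np.nan
            else:  # NDSI
                ssum = r1 + R
                bad = np.abs(ssum).min(axis=0) <= _DENOM_TOL
                X = (r1 - R) / ssum
                vals[i] = _r2_columns(X, yc, var_y)
                if bad.any():
                    vals[i, bad] = np.nan
    np.fill_diagonal(vals, np.nan)
    return ScoreMap(axis1=grid, axis2=grid, values=vals, kind="pairwise-index", label=index_type)


def _candidates_from_map(smap: ScoreMap, top: int) -> list[tuple]:
    vals = smap.values
    flat = vals.ravel()
    defined = np.flatnonzero(np.isfinite(flat))
    if defined.size > top:
        part = defined[np.argpartition(flat[defined], -top)[-top:]]
    else:
        part = defined
    rows, cols = np.unravel_index(part, vals.shape)
    t_order = INDEX_TYPES.index(smap.label)
    return [
        (float(vals[i, j]), int(smap.axis1[i]), int(smap.axis2[j]), t_order)
        for i, j in zip(rows, cols)
    ]


def select_top_index_features(
    maps: dict[str, ScoreMap] | list[ScoreMap],
    k: int = 10,
    min_separation_nm: int = 10,
) -> list[IndexFeature]:
    """Greedy top-k selection of band-pair features across the three maps.

    Candidates are pooled over all maps and ranked by R² (ties broken by
    smaller λ1, then smaller λ2, then index-type order RSI < DSI < NDSI).
    A candidate is kept only if no already-kept candidate of the same index
    type has both bands within ``min_separation_nm`` (compared in either
    band orientation, so a kept (a, b) also suppresses (b, a)).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(maps, dict):
        maps = list(maps.values())
    cands: list[tuple] = []
    for smap in maps:
        if smap.label not in INDEX_TYPES:
            raise ValueError(f"score map label {smap.label!r} is not an index type")
        cands.extend(_candidates_from_map(smap, top=max(1000, 100 * k)))
    cands.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))

    kept: list[IndexFeature] = []
    for r2, l1, l2, t_order in cands:
        itype = INDEX_TYPES[t_order]
        clash = False
        for f in kept:
            if f.index_type != itype:
                continue
            same = (
                abs(f.lambda1_nm - l1) <= min_separation_nm
                and abs(f.lambda2_nm - l2) <= min_separation_nm
            )
            mirrored = (
                abs(f.lambda1_nm - l2) <= min_separation_nm
                and abs(f.lambda2_nm - l1) <= min_separation_nm
            )
            if same or mirrored:
                clash = True
                break
        if not clash:
            kept.append(IndexFeature(itype, l1, l2, r2_cal=r2))
            if len(kept) == k:
                return kept
    logger.warning("only %d of %d requested index features admissible", len(kept), k)
    return kept


def fit_index_model(feature: IndexFeature, s_cal: SpectrumSet) -> IndexFeature:
    """Ordinary least squares of LPC on the index; fills slope/intercept/R²."""
    y = s_cal.require_lpc()
    if s_cal.n_samples < 3:
        raise ValueError("need at least 3 calibration samples")
    x = compute_index(s_cal, feature.index_type, feature.lambda1_nm, feature.lambda2_nm)
    if np.ptp(x) == 0 or np.var(x) <= _VAR_TOL:
        raise DegeneracyError(f"{feature.name}: index constant on calibration data")
    res = stats.linregress(x, y)
    return replace(
        feature,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2_cal=float(res.rvalue**2),
    )


def optimize_indices(
    s_cal: SpectrumSet,
    k: int = 10,
    min_separation_nm: int = 10,
    step: int = 1,
) -> tuple[list[IndexFeature], dict[str, ScoreMap]]:
    """Full SI optimization: scan all three maps, select and calibrate top-k."""
    maps = {t: pairwise_r2_map(s_cal, t, step=step) for t in INDEX_TYPES}
    feats = select_top_index_features(maps, k=k, min_separation_nm=min_separation_nm)
    return [fit_index_model(f, s_cal) for f in feats], maps
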