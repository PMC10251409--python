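"""Taylor-diagram statistics for comparative model assessment.

A model's agreement with observations is summarized by three linked
statistics: the Pearson correlation r, the ratio of predicted to observed
standard deviation σ̂ = σ_pred/σ_obs, and the centered (bias-removed)
root-mean-square difference.  With population (divide-by-n) standard
deviations they satisfy the law of cosines exactly:

    cRMSD² = σ_pred² + σ_obs² − 2 σ_pred σ_obs r,

which is what lets all three be read off a single polar diagram
(radius = σ̂, angle = arccos r).  The normalized form (std ratio rather than
raw std) is used throughout, so the reference point is (1, 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TaylorPoint", "taylor_statistics", "taylor_coordinates"]


@dataclass(frozen=True)
class TaylorPoint:
    """One model's Taylor-diagram statistics against observations."""

    label: str
    pearson_r: float
    std_ratio: float
    centered_rmsd: float


def taylor_statistics(observed, predicted, label: str = "") -> TaylorPoint:
    """Pearson r, std ratio and centered RMSD of predictions vs observations."""
    o = np.asarray(observed, dtype=np.float64)
    p = np.asarray(predicted, dtype=np.float64)
    if o.shape != p.shape or o.ndim != 1 or o.size < 3:
        raise ValueError("observed and predicted must be equal-length 1-D, n >= 3")
    oc = o - o.mean()
    pc = p - p.mean()
    so = np.sqrt(np.mean(oc**2))
    sp = np.sqrt(np.mean(pc**2))
    if so == 0:
        raise ValueError("observed values are constant; Taylor statistics undefined")
    r = float(np.mean(oc * pc) / (so * sp)) if sp > 0 else 0.0
    crmsd = float(np.sqrt(np.mean((pc - oc) ** 2)))
    return TaylorPoint(
        label=label,
        pearson_r=r,
        std_ratio=float(sp / so),
        centered_rmsd=crmsd,
    )


def taylor_coordinates(point: TaylorPoint) -> tuple[float, float]:
    """Polar coordinates (radius, angle) of a point on the normalized diagram."""
    return point.std_ratio, float(np.arccos(np.clip(point.pearson_r, -1.0, 1.0)))
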