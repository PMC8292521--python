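"""Planar kidney quantification and hybrid planar-SPECT calibration.

Planar conjugate views (anterior/posterior) cannot measure absolute activity
on their own: counts depend on source depth through attenuation.  Two
standard devices fix this:

* **Conjugate-view geometric mean** — for a source at depth d in a body of
  thickness L, the anterior and posterior attenuation factors are
  exp(-mu d) and exp(-mu (L-d)); their geometric mean is exp(-mu L/2),
  independent of d, so multiplying by exp(+mu L/2) removes attenuation to
  first order.
* **Hybrid calibration** — the absolute kidney activity measured by
  quantitative SPECT at the shared ("clinical") time point divided by the
  corrected planar count rate at that same time gives a patient-specific
  factor that converts the other planar time point to MBq.

Scatter is removed by dual-window subtraction (a configurable fraction k of
the scatter-window counts inside the ROI), background by a per-pixel mean
from a background ROI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PlanarImage",
    "HybridCalibration",
    "corrected_kidney_counts",
    "hybrid_calibrate",
]


@dataclass
class PlanarImage:
    """Anterior/posterior photopeak count grids with optional scatter-window
    companions, all ``(n_u, n_v)`` and sharing geometry."""

    anterior: np.ndarray
    posterior: np.ndarray
    time_post_injection_h: float
    duration_s: float
    scatter_anterior: np.ndarray | None = None
    scatter_posterior: np.ndarray | None = None
    pixel_size_cm: float = 1.0

    def __post_init__(self):
        self.anterior = np.asarray(self.anterior, dtype=float)
        self.posterior = np.asarray(self.posterior, dtype=float)
        if self.anterior.shape != self.posterior.shape:
            raise ValueError("anterior and posterior grids must share geometry")
        if np.any(self.anterior < 0) or np.any(self.posterior < 0):
            raise ValueError("counts must be non-negative")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


@dataclass
class HybridCalibration:
    """MBq per corrected planar count rate, anchored at the SPECT time."""

    factor_mbq_per_cps: float
    anchor_time_h: float

    def __post_init__(self):
        if self.factor_mbq_per_cps <= 0:
            raise ValueError("calibration factor must be positive")

    def apply(self, corrected_rate_cps: float) -> float:
        """Convert a corrected planar count rate to absolute activity (MBq)."""
        return self.factor_mbq_per_cps * corrected_rate_cps


def _roi_counts(grid, scatter_grid, roi, background_roi, scatter_k):
    roi = np.asarray(roi, dtype=bool)
    bg = np.asarray(background_roi, dtype=bool)
    counts = float(grid[roi].sum())
    if scatter_grid is not None and scatter_k > 0:
        counts -= scatter_k * float(scatter_grid[roi].sum())
    bg_mean = float(grid[bg].mean())
    if scatter_grid is not None and scatter_k > 0:
        bg_mean -= scatter_k * float(scatter_grid[bg].mean())
    counts -= bg_mean * roi.sum()
    if counts < 0:
        warnings.warn("corrected planar counts were negative; floored at 0")
        counts = 0.0
    return counts


def corrected_kidney_counts(
    image: PlanarImage,
    kidney_roi: np.ndarray,
    background_roi: np.ndarray,
    body_thickness_cm: float,
    mu_cm: float = 0.15,
    scatter_k: float = 0.5,
) -> float:
    """Scatter-, background- and attenuation-corrected kidney count rate.

    Per view: ROI counts minus ``scatter_k`` x scatter-window ROI counts
    minus background mean per pixel x ROI area.  Views are combined by the
    conjugate-view geometric mean and attenuation-corrected by
    ``exp(mu * L / 2)``; the result is divided by the acquisition duration.

    Returns counts per second.  ``kidney_roi`` applies to the anterior grid
    and its left-right mirror to the posterior grid (the posterior detector
    sees the scene flipped).
    """
    kidney_roi = np.asarray(kidney_roi, dtype=bool)
    background_roi = np.asarray(background_roi, dtype=bool)
    if not background_roi.any():
        raise ValueError("background_roi is empty")
    if (kidney_roi & background_roi).any():
        raise ValueError("kidney and background ROIs must be disjoint")
    roi_post = kidney_roi[::-1, :]
    bg_post = background_roi[::-1, :]
    c_ant = _roi_counts(image.anterior, image.scatter_anterior, kidney_roi,
                        background_roi, scatter_k)
    c_post = _roi_counts(image.posterior, image.scatter_posterior, roi_post,
                         bg_post, scatter_k)
    geo = float(np.sqrt(c_ant * c_post))
    return geo * np.exp(mu_cm * body_thickness_cm / 2.0) / image.duration_s


def hybrid_calibrate(
    planar_rate_at_anchor_cps: float, spect_activity_at_anchor_mbq: float,
    anchor_time_h: float = 0.0,
) -> HybridCalibration:
    """SPECT-anchored calibration: factor = SPECT MBq / planar rate."""
    if planar_rate_at_anchor_cps <= 0:
        raise ValueError("planar rate at anchor must be positive")
    if spect_activity_at_anchor_mbq <= 0:
        raise ValueError("SPECT activity at anchor must be positive")
    return HybridCalibration(
        factor_mbq_per_cps=spect_activity_at_anchor_mbq / planar_rate_at_anchor_cps,
        anchor_time_h=anchor_time_h,
    )
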