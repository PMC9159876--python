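"""Centroid of the muscle-activity distribution and the DISTANCE statistic.

The centroid is the RMS-weighted mean of channel positions along the
cranial-caudal (y) axis — a barycenter summarizing where on the electrode
grid the activity is concentrated. DISTANCE is the absolute 1-D distance
(cm) between that centroid and the patient-indicated most painful site,
both measured from the top of the EMG sheet (0 cm). Both quantities are
taken in the extension phase, where the erector spinae acts as agonist.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import SIDES
from .processing import RMSMap


@dataclass(frozen=True)
class CentroidResult:
    """Per-side and bilateral-mean activity centroid for one phase (cm)."""

    y_left_cm: float
    y_right_cm: float
    y_mean_cm: float
    phase: str


@dataclass(frozen=True)
class DistanceResult:
    """Absolute cranial-caudal distance between centroid and pain site."""

    distance_cm: float
    centroid_y_cm: float
    pain_site_cm: float


def compute_centroid(
    rms_values: np.ndarray,
    channel_y_cm: np.ndarray,
    excluded_mask: np.ndarray | None = None,
) -> float:
    """Weighted mean position: y = sum(w_c * y_c) / sum(w_c).

    Excluded channels are dropped from both sums. The result is
    scale-invariant in the weights and always lies within the range of the
    contributing channel positions. Undefined (error) when every channel is
    excluded or all weights are zero.
    """
    w = np.asarray(rms_values, dtype=float)
    y = np.asarray(channel_y_cm, dtype=float)
    if w.shape != y.shape:
        raise ValueError("weights and positions must have matching shapes")
    if np.any(w < 0):
        raise ValueError("RMS weights must be non-negative")
    keep = (
        np.ones_like(w, dtype=bool)
        if excluded_mask is None
        else ~np.asarray(excluded_mask, dtype=bool)
    )
    if not keep.any():
        raise ValueError("centroid undefined: all channels excluded")
    total = w[keep].sum()
    if total <= 0:
        raise ValueError("centroid undefined: all non-excluded weights are zero")
    return float(np.dot(w[keep], y[keep]) / total)


def _side_centroid(rms: RMSMap, phase: str, side: str) -> float:
    cols = rms.side_columns(side)
    p = rms.phase_row(phase)
    return compute_centroid(
        rms.values[p, cols], rms.channel_y_cm[cols], rms.excluded[p, cols]
    )


def bilateral_trial_centroid(
    maps: Sequence[RMSMap], phase: str = "extension"
) -> CentroidResult:
    """Centroid per side per trial, averaged over trials, then over sides.

    Follows the study's averaging order: for each side the centroid is
    computed within each experimental trial and the per-trial centroids are
    averaged; the reported centroid is the mean of the left and right
    averages. The result is invariant to trial order and, because the
    centroid is scale-invariant, identical on raw and normalized maps.
    """
    if len(maps) == 0:
        raise ValueError("need at least one trial map")
    per_side = {
        side: float(np.mean([_side_centroid(m, phase, side) for m in maps]))
        for side in SIDES
    }
    return CentroidResult(
        y_left_cm=per_side["left"],
        y_right_cm=per_side["right"],
        y_mean_cm=(per_side["left"] + per_side["right"]) / 2.0,
        phase=phase,
    )


def compute_distance(
    centroid: CentroidResult | float, pain_site_cm: float
) -> DistanceResult:
    """DISTANCE = |pain site - activity centroid| on the sheet's y axis (cm)."""
    y = centroid.y_mean_cm if isinstance(centroid, CentroidResult) else float(centroid)
    site = float(pain_site_cm)
    if not site >= 0:
        raise ValueError(f"pain_site_cm={site} must be >= 0 (cm from sheet top)")
    return DistanceResult(
        distance_cm=abs(site - y), centroid_y_cm=y, pain_site_cm=site
    )
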