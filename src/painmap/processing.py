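"""Raw EMG trials -> normalized per-phase, per-channel RMS maps.

Processing chain per trial: zero-phase Butterworth band-pass (10-400 Hz),
segmentation into the four fixed 3-s task phases, RMS amplitude per
(phase, channel) cell, optional robust outlier exclusion, and amplitude
normalization of experimental trials by the reference trial's
extension-phase RMS (per channel), which makes activity dimensionless
(about 1 at the reference effort level).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .geometry import (
    N_PHASES,
    PHASE_DURATION_S,
    PHASE_NAMES,
    EMGRecording,
    PhaseWindow,
)

BAND_HZ = (10.0, 400.0)
DEFAULT_FILTER_ORDER = 4
DEFAULT_EXCLUSION_THRESHOLD_MAD = 5.0

_EXTENSION = PHASE_NAMES.index("extension")


@lru_cache(maxsize=8)
def _design_bandpass(sampling_rate_hz: float, order: int) -> np.ndarray:
    low, high = BAND_HZ
    if sampling_rate_hz <= 2 * high:
        raise ValueError(
            f"sampling rate {sampling_rate_hz} Hz must exceed twice the "
            f"upper cutoff ({high} Hz)"
        )
    return sps.butter(order, (low, high), btype="bandpass", fs=sampling_rate_hz, output="sos")


def _padlen(sos: np.ndarray) -> int:
    # scipy's sosfiltfilt default edge padding; inputs must be longer than this
    return 3 * (2 * len(sos) + 1 - min((sos[:, 2] == 0).sum(), (sos[:, 5] == 0).sum()))


def bandpass_filter(
    x: np.ndarray, sampling_rate_hz: float, order: int = DEFAULT_FILTER_ORDER
) -> np.ndarray:
    """Zero-phase 10-400 Hz band-pass (Butterworth, forward-backward).

    Accepts a 1-D channel or a 2-D time x channels array (filtered along
    time). Output length equals input length; DC is removed and in-band
    amplitudes are preserved to within ~1%.
    """
    x = np.asarray(x, dtype=float)
    sos = _design_bandpass(float(sampling_rate_hz), int(order))
    pad = _padlen(sos)
    if x.shape[0] <= pad:
        raise ValueError(
            f"signal of {x.shape[0]} samples is too short for zero-phase "
            f"filtering; need at least {pad + 1} samples"
        )
    return sps.sosfiltfilt(sos, x, axis=0)


def segment_phases(recording: EMGRecording) -> list[PhaseWindow]:
    """Split a 12-s recording into the four 3-s task phases.

    Phases follow the fixed auditory cueing of the task (standing, flexion,
    full flexion, extension), half-open and contiguous, exactly
    3 s x sampling rate samples each.
    """
    per_phase = round(PHASE_DURATION_S * recording.sampling_rate_hz)
    expected = N_PHASES * per_phase
    if recording.n_samples != expected:
        raise ValueError(
            f"recording has {recording.n_samples} samples; the 4-phase x 3-s "
            f"task at {recording.sampling_rate_hz:g} Hz requires exactly {expected}"
        )
    return [
        PhaseWindow(name, i * per_phase, (i + 1) * per_phase)
        for i, name in enumerate(PHASE_NAMES)
    ]


def compute_rms(window_samples: np.ndarray) -> float:
    """Root-mean-square amplitude of one window: sqrt(mean(x**2))."""
    x = np.asarray(window_samples, dtype=float)
    if x.size == 0:
        raise ValueError("cannot compute RMS of an empty window")
    return float(np.sqrt(np.mean(np.square(x))))


@dataclass(frozen=True)
class RMSMap:
    """Per-phase x per-channel RMS amplitudes for one trial (or trial mean).

    ``values`` has shape (4 phases, n_channels); channels are ordered left
    grid then right grid, cranial to caudal, with positions ``channel_y_cm``.
    ``excluded`` marks cells rejected as un-removable noise; values are
    retained, downstream statistics skip masked cells.
    """

    values: np.ndarray
    channel_y_cm: np.ndarray
    channel_sides: tuple[str, ...]
    normalized: bool = False
    excluded: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "channel_y_cm", np.asarray(self.channel_y_cm, dtype=float))
        if values.shape != (N_PHASES, self.channel_y_cm.size):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"({N_PHASES}, {self.channel_y_cm.size})"
            )
        if np.any(values < 0):
            raise ValueError("RMS values must be non-negative")
        excluded = self.excluded
        excluded = (
            np.zeros_like(values, dtype=bool)
            if excluded is None
            else np.asarray(excluded, dtype=bool)
        )
        if excluded.shape != values.shape:
            raise ValueError("excluded mask shape must match values")
        object.__setattr__(self, "excluded", excluded)

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def side_columns(self, side: str) -> np.ndarray:
        cols = np.array([s == side for s in self.channel_sides])
        if not cols.any():
            raise ValueError(f"no channels on side {side!r}")
        return cols

    def phase_row(self, phase: str) -> int:
        return PHASE_NAMES.index(phase)


def rms_map(
    recording: EMGRecording,
    bandpass: bool = True,
    filter_order: int = DEFAULT_FILTER_ORDER,
) -> RMSMap:
    """Compute the raw RMS map of one trial.

    Each channel is band-pass filtered (unless ``bandpass=False``, used for
    hand-checkable toy inputs), segmented into the task phases (using the
    recording's own phase boundaries when present), and reduced to one RMS
    value per (phase, channel) cell.
    """
    windows = (
        list(recording.phase_boundaries)
        if recording.phase_boundaries is not None
        else segment_phases(recording)
    )
    if len(windows) != N_PHASES:
        raise ValueError(f"expected {N_PHASES} phase windows, got {len(windows)}")
    x = (
        bandpass_filter(recording.samples, recording.sampling_rate_hz, filter_order)
        if bandpass
        else recording.samples
    )
    values = np.empty((N_PHASES, recording.n_channels))
    for p, w in enumerate(windows):
        seg = x[w.start_sample : w.end_sample]
        values[p] = np.sqrt(np.mean(np.square(seg), axis=0))
    return RMSMap(
        values=values,
        channel_y_cm=recording.channel_y_cm,
        channel_sides=tuple(recording.channel_sides),
    )


def exclude_noisy(
    rms: RMSMap, threshold_mad: float = DEFAULT_EXCLUSION_THRESHOLD_MAD
) -> RMSMap:
    """Flag cells whose RMS is a robust outlier within its phase.

    A cell is excluded when it deviates from the per-phase median across
    channels by more than ``threshold_mad`` median absolute deviations —
    a stand-in for the manual rejection of channels whose noise could not
    be removed. ``threshold_mad=inf`` excludes nothing. Values are kept;
    only the mask is updated (combined with any existing mask).
    """
    if not np.isfinite(threshold_mad):
        return rms
    med = np.median(rms.values, axis=1, keepdims=True)
    mad = np.median(np.abs(rms.values - med), axis=1, keepdims=True)
    new_mask = np.abs(rms.values - med) > threshold_mad * mad
    return replace(rms, excluded=rms.excluded | new_mask)


def normalize_rms(experimental_maps: Sequence[RMSMap], reference_map: RMSMap) -> RMSMap:
    """Normalize experimental RMS by the reference trial's extension RMS.

    For each channel c and phase p, the normalized value is the mean over
    experimental trials of raw RMS[p, c], divided by channel c's RMS in the
    *extension phase* of the reference trial. Cells excluded in any
    experimental trial, and channels excluded in the reference extension
    phase, stay excluded in the result.
    """
    if len(experimental_maps) == 0:
        raise ValueError("need at least one experimental map")
    ref_y = reference_map.channel_y_cm
    for m in experimental_maps:
        if m.normalized or reference_map.normalized:
            raise ValueError("normalize_rms expects raw (not yet normalized) maps")
        if m.values.shape != reference_map.values.shape or not np.allclose(
            m.channel_y_cm, ref_y
        ):
            raise ValueError("experimental and reference maps must share grid geometry")
    mean_raw = np.mean([m.values for m in experimental_maps], axis=0)
    denom = reference_map.values[_EXTENSION]
    ref_excluded = reference_map.excluded[_EXTENSION]
    if np.any((denom == 0) & ~ref_excluded):
        bad = np.flatnonzero((denom == 0) & ~ref_excluded).tolist()
        raise ValueError(
            f"reference extension-phase RMS is zero on non-excluded channel(s) {bad}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(denom > 0, mean_raw / np.where(denom > 0, denom, 1.0), 0.0)
    excluded = np.any([m.excluded for m in experimental_maps], axis=0) | ref_excluded
    return RMSMap(
        values=values,
        channel_y_cm=ref_y,
        channel_sides=reference_map.channel_sides,
        normalized=True,
        excluded=excluded,
    )


def extension_activity(normalized_map: RMSMap) -> float:
    """Mean normalized extension-phase RMS across all non-excluded channels.

    This is the scalar "muscle activity" outcome: the agonist (erector
    spinae) activity while returning from full flexion to upright, pooled
    over both sides' channels.
    """
    if not normalized_map.normalized:
        raise ValueError("extension_activity requires a normalized map")
    row = normalized_map.values[_EXTENSION]
    keep = ~normalized_map.excluded[_EXTENSION]
    if not keep.any():
        raise ValueError("all extension-phase channels are excluded")
    return float(np.mean(row[keep]))
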