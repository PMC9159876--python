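"""Electrode-grid geometry, task phases, and the raw-recording container.

The recording montage is two sheet-type electrode grids taped bilaterally
over the lumbar erector spinae, 3 cm lateral of the spinous processes. Each
grid is a single cranial–caudal column of five electrodes with 2.5 cm
inter-electrode distance, wired as four bipolar channels; a channel's
position is the midpoint of its electrode pair, measured in cm from the top
of the sheet (the same origin used for the patient-indicated pain site).

The motor task is a 12-s lumbar bending-and-returning movement of four
auditory-cued phases (standing, flexion, full flexion, extension), each
lasting exactly 3 s, recorded at 1000 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

PHASE_NAMES: tuple[str, ...] = ("standing", "flexion", "full_flexion", "extension")
N_PHASES = len(PHASE_NAMES)
PHASE_DURATION_S = 3.0
DEFAULT_SAMPLING_RATE_HZ = 1000.0
SIDES = ("left", "right")


@dataclass(frozen=True)
class ElectrodeGrid:
    """One side's bipolar electrode column.

    ``top_offset_cm`` places the topmost electrode relative to the sheet top
    (default 0, i.e. the grid starts at the pain-site origin);
    ``lateral_offset_cm`` is descriptive only (distance from the midline).
    """

    side: str
    n_electrodes: int = 5
    inter_electrode_distance_cm: float = 2.5
    top_offset_cm: float = 0.0
    lateral_offset_cm: float = 3.0

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.n_electrodes < 2:
            raise ValueError("a grid needs at least 2 electrodes (1 channel)")
        if self.inter_electrode_distance_cm <= 0:
            raise ValueError("inter_electrode_distance_cm must be > 0")

    @property
    def n_channels(self) -> int:
        return self.n_electrodes - 1

    @property
    def channel_y_cm(self) -> np.ndarray:
        """Cranial–caudal channel positions: electrode-pair midpoints (cm)."""
        d = self.inter_electrode_distance_cm
        return self.top_offset_cm + d * (np.arange(self.n_channels) + 0.5)


def default_grid_pair() -> tuple[ElectrodeGrid, ElectrodeGrid]:
    """The study montage: identical left and right 4-channel columns."""
    return ElectrodeGrid(side="left"), ElectrodeGrid(side="right")


@dataclass(frozen=True)
class PhaseWindow:
    """Half-open sample window [start_sample, end_sample) for one task phase."""

    name: str
    start_sample: int
    end_sample: int

    def __post_init__(self) -> None:
        if self.end_sample <= self.start_sample:
            raise ValueError("empty phase window")

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample


@dataclass
class EMGRecording:
    """One trial's multi-channel surface-EMG signal.

    ``samples`` is time x channels; columns are ordered left grid channels
    (cranial to caudal) followed by right grid channels. ``phase_boundaries``
    may be pre-recorded by a simulator; when absent, phases are derived from
    the fixed 3-s cueing via :func:`painmap.processing.segment_phases`.
    """

    samples: np.ndarray
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    grids: tuple[ElectrodeGrid, ElectrodeGrid] = field(default_factory=default_grid_pair)
    phase_boundaries: Sequence[PhaseWindow] | None = None
    trial_role: str = "experimental"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (time x channels) array")
        left, right = self.grids
        if left.side != "left" or right.side != "right":
            raise ValueError("grids must be the (left, right) pair")
        n_expected = left.n_channels + right.n_channels
        if self.samples.shape[1] != n_expected:
            raise ValueError(
                f"recording has {self.samples.shape[1]} columns, "
                f"grid pair defines {n_expected} channels"
            )
        if self.trial_role not in ("reference", "experimental"):
            raise ValueError(f"unknown trial_role {self.trial_role!r}")
        if self.phase_boundaries is not None:
            n = self.samples.shape[0]
            for w in self.phase_boundaries:
                if not (0 <= w.start_sample < w.end_sample <= n):
                    raise ValueError(f"phase window {w} outside recording of {n} samples")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    def columns_for_side(self, side: str) -> slice:
        left, _ = self.grids
        if side == "left":
            return slice(0, left.n_channels)
        if side == "right":
            return slice(left.n_channels, self.n_channels)
        raise ValueError(f"unknown side {side!r}")

    @property
    def channel_sides(self) -> list[str]:
        left, right = self.grids
        return ["left"] * left.n_channels + ["right"] * right.n_channels

    @property
    def channel_y_cm(self) -> np.ndarray:
        left, right = self.grids
        return np.concatenate([left.channel_y_cm, right.channel_y_cm])

    @property
    def channel_names(self) -> list[str]:
        left, right = self.grids
        return [f"left_{i + 1}" for i in range(left.n_channels)] + [
            f"right_{i + 1}" for i in range(right.n_channels)
        ]
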