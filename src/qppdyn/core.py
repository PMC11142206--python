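"""Shared containers and error types for the qppdyn analysis pipeline.

The universal analysis substrate is the :class:`ParcellatedScan` — a
region × time matrix of BOLD timecourses with the repetition time and the
experimental-group labels attached. Voxel-level data travels as a
:class:`VoxelScan`: a 4D volume plus brain mask and an integer parcellation
(label image), from which region timecourses are extracted by label-wise
voxel averaging.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

#: Viral-construct factor levels (control fluorophore vs. opsin).
VIRUS_LEVELS = ("mCherry", "ChR2")

#: Stimulation-condition factor levels.
STIM_LEVELS = ("baseline", "2Hz", "5Hz", "15Hz-phasic")


class QppdynError(Exception):
    """Base class for qppdyn-specific errors."""


class InvalidConfigError(QppdynError, ValueError):
    """A configuration object violates its invariants."""


class DegenerateInputError(QppdynError, ValueError):
    """Input is structurally valid but degenerate (e.g. zero-variance trace)."""


@dataclass
class ParcellatedScan:
    """Region × time BOLD matrix for one scan.

    Parameters
    ----------
    values
        Array of shape ``(n_regions, n_frames)``; finite, no missing values.
    region_names
        One name per row of ``values``.
    tr_seconds
        Repetition time (sampling interval) in seconds.
    scan_id
        Identifier used in tables and output files.
    virus, stimulation
        Group labels; ``None`` for data outside a cohort design.
    """

    values: np.ndarray
    region_names: list[str]
    tr_seconds: float
    scan_id: str = ""
    virus: str | None = None
    stimulation: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidConfigError("values must be 2D (regions × time)")
        if not np.all(np.isfinite(self.values)):
            raise InvalidConfigError("scan values must be finite")
        if len(self.region_names) != self.values.shape[0]:
            raise InvalidConfigError(
                f"{len(self.region_names)} region names for "
                f"{self.values.shape[0]} rows"
            )
        if not self.tr_seconds > 0:
            raise InvalidConfigError("tr_seconds must be positive")
        if self.virus is not None and self.virus not in VIRUS_LEVELS:
            raise InvalidConfigError(f"unknown virus level {self.virus!r}")
        if self.stimulation is not None and self.stimulation not in STIM_LEVELS:
            raise InvalidConfigError(f"unknown stimulation level {self.stimulation!r}")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def group(self) -> tuple[str | None, str | None]:
        return (self.virus, self.stimulation)

    def with_values(self, values: np.ndarray) -> "ParcellatedScan":
        """Copy of this scan with replaced timecourses (metadata preserved)."""
        return dataclasses.replace(self, values=np.asarray(values, dtype=float))


@dataclass
class VoxelScan:
    """4D BOLD volume with a brain mask and an integer parcellation.

    ``labels`` assigns every in-mask voxel a region id (0 = background);
    labels are nonzero only inside the mask.
    """

    data: np.ndarray  # (x, y, z, t)
    brain_mask: np.ndarray  # (x, y, z) bool
    labels: np.ndarray  # (x, y, z) nonneg int
    tr_seconds: float
    voxel_mm: float = 0.5

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 4:
            raise InvalidConfigError("data must be 4D (x, y, z, t)")
        if self.brain_mask.shape != self.data.shape[:3]:
            raise InvalidConfigError("brain_mask shape must match data grid")
        if self.labels.shape != self.data.shape[:3]:
            raise InvalidConfigError("labels shape must match data grid")
        if np.any(self.labels < 0):
            raise InvalidConfigError("labels must be nonnegative")
        if np.any((self.labels > 0) & ~self.brain_mask):
            raise InvalidConfigError("labels must be nonzero only inside the mask")
        if not np.all(np.isfinite(self.data)):
            raise InvalidConfigError("voxel data must be finite")
        if not self.tr_seconds > 0:
            raise InvalidConfigError("tr_seconds must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def with_data(self, data: np.ndarray) -> "VoxelScan":
        return dataclasses.replace(self, data=np.asarray(data, dtype=float))


def check_same_parcellation(scans: list[ParcellatedScan]) -> None:
    """Raise if scans disagree on region set or TR."""
    if not scans:
        raise InvalidConfigError("empty scan list")
    ref = scans[0]
    for s in scans[1:]:
        if s.region_names != ref.region_names:
            raise InvalidConfigError("scans have different parcellations")
        if not np.isclose(s.tr_seconds, ref.tr_seconds):
            raise InvalidConfigError("scans have different TR")
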