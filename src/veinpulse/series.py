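"""Cardiac-gated phase-contrast series container and NIfTI IO.

A gated 2D phase-contrast acquisition is stored as a pair of 3D stacks
(y, x, cardiac phase): the magnitude of the complex difference between
flow-compensated and flow-encoded readouts, and the corresponding phase
difference in radians.  Through-slice velocity v maps to signal phase
``pi * v / venc``; speeds beyond ``venc`` wrap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["GatedPCSeries", "load_series", "save_series"]


@dataclass
class GatedPCSeries:
    """Per-cardiac-phase magnitude and phase stacks with acquisition metadata.

    Parameters
    ----------
    magnitude : ndarray, shape (ny, nx, n_phases)
        Non-negative magnitude images, arbitrary units.
    phase : ndarray, shape (ny, nx, n_phases)
        Phase-difference images in radians, nominally in (-pi, pi].
    venc : float
        Velocity-encoding value in cm/s (phase of pi radians <-> venc).
    phase_duration : float
        Duration of one cardiac phase in ms (two TRs per phase).
    voxel_size : float
        In-plane voxel size in mm.
    """

    magnitude: np.ndarray
    phase: np.ndarray
    venc: float
    phase_duration: float
    voxel_size: float = 0.6

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.magnitude.ndim != 3:
            raise ValueError("magnitude must be a 3D (y, x, cardiac-phase) stack")
        if self.magnitude.shape != self.phase.shape:
            raise ValueError("magnitude and phase stacks must share shape")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be non-negative")
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("phase must be finite")
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        if self.phase_duration <= 0:
            raise ValueError("phase_duration must be positive")

    @property
    def n_phases(self) -> int:
        return self.magnitude.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Start time of each cardiac phase, ms from the gating trigger."""
        return np.arange(self.n_phases) * self.phase_duration


def save_series(series: GatedPCSeries, magnitude_path: str | Path,
                phase_path: str | Path) -> None:
    """Write magnitude and phase stacks as 3D NIfTI files."""
    affine = np.diag([series.voxel_size, series.voxel_size, 1.0, 1.0])
    for stack, path in ((series.magnitude, magnitude_path),
                        (series.phase, phase_path)):
        img = nib.Nifti1Image(np.asarray(stack, dtype=np.float64), affine)
        # third axis is cardiac phase; record its spacing as the phase duration
        img.header.set_zooms((series.voxel_size, series.voxel_size,
                              series.phase_duration))
        nib.save(img, str(path))


def load_series(magnitude_path: str | Path, phase_path: str | Path,
                venc: float, phase_duration: float | None = None,
                voxel_size: float | None = None) -> GatedPCSeries:
    """Read magnitude/phase NIfTI stacks into a :class:`GatedPCSeries`.

    ``phase_duration`` and ``voxel_size`` fall back to the NIfTI zooms when
    not supplied.
    """
    mag_img = nib.load(str(magnitude_path))
    phs_img = nib.load(str(phase_path))
    zooms = mag_img.header.get_zooms()
    if voxel_size is None:
        voxel_size = float(zooms[0])
    if phase_duration is None:
        phase_duration = float(zooms[2])
    return GatedPCSeries(
        magnitude=np.asanyarray(mag_img.dataobj, dtype=float),
        phase=np.asanyarray(phs_img.dataobj, dtype=float),
        venc=venc,
        phase_duration=phase_duration,
        voxel_size=voxel_size,
    )
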