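"""Phase images to per-vessel velocity waveforms.

Processing order (fixed): spatial median-filter background removal first,
then voxelwise temporal unwrapping, then spatial averaging over each
cluster and scaling by venc/pi to convert radians to cm/s.  The superior
sagittal sinus has its own pathway: its flow is fast enough that the phase
wraps several times, so the 20 brightest sinus voxels are pulled onto a
common wrap branch (subtracting 2*pi from positive-phase voxels, the
convention for superior-to-inferior, negatively-encoded flow) and combined
with a voxelwise median — the result is a timing reference, not an
absolute speed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .segmentation import VesselClusterMap
from .series import GatedPCSeries

__all__ = [
    "VelocityWaveform", "remove_background_phase", "unwrap_temporal",
    "cluster_waveform", "sinus_waveform", "extract_waveforms",
    "waveform_table",
]

DEFAULT_MEDIAN_WINDOW = 17  # voxels; 10 mm at 0.6 mm in-plane resolution
SINUS_TOP_N = 20


@dataclass
class VelocityWaveform:
    """Through-slice velocity (cm/s, signed) at each cardiac phase."""

    values: np.ndarray
    phase_duration: float       # ms per cardiac phase
    source_cluster: int | None = None
    pathway: str = "cluster_mean"   # or "sinus_median"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a non-empty 1D sequence")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("waveform values must be finite")
        if self.phase_duration <= 0:
            raise ValueError("phase_duration must be positive")

    @property
    def n_phases(self) -> int:
        return self.values.size

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_phases) * self.phase_duration

    @property
    def mean_abs_speed(self) -> float:
        """Time-averaged flow speed |v| in cm/s."""
        return float(np.mean(np.abs(self.values)))


def remove_background_phase(phase: np.ndarray,
                            window: int = DEFAULT_MEDIAN_WINDOW) -> np.ndarray:
    """Subtract a spatial median-filtered copy from each cardiac phase.

    The window (default 17 x 17 voxels, ~10 mm) is large compared to any
    vessel, so the median tracks the smooth background phase offset and the
    subtraction leaves vessel phase intact.  Edges are handled by
    reflection.  The output is no longer confined to (-pi, pi].
    """
    phase = np.asarray(phase, dtype=float)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if window > min(phase.shape[0], phase.shape[1]):
        raise ValueError("median filter window larger than the image")
    if phase.ndim == 2:
        phase = phase[:, :, None]
    out = np.empty_like(phase)
    for t in range(phase.shape[2]):  # each cardiac phase independently
        out[:, :, t] = phase[:, :, t] - median_filter(
            phase[:, :, t], size=window, mode="reflect")
    return np.squeeze(out) if out.shape[2] == 1 else out


def unwrap_temporal(phase: np.ndarray) -> np.ndarray:
    """Voxelwise 1D phase unwrapping along the cardiac-phase axis.

    Successive samples differing by more than pi are shifted by the multiple
    of 2*pi that minimises the jump; the first sample is left unchanged.
    """
    phase = np.asarray(phase, dtype=float)
    if phase.shape[-1] < 2:
        raise ValueError("need at least 2 cardiac phases to unwrap")
    return np.unwrap(phase, axis=-1)


def cluster_waveform(corrected_phase: np.ndarray, cluster_voxels: np.ndarray,
                     venc: float, phase_duration: float,
                     cluster_id: int | None = None) -> VelocityWaveform:
    """Spatial mean over the cluster, scaled by venc/pi to cm/s."""
    vox = np.atleast_2d(np.asarray(cluster_voxels, dtype=int))
    if vox.size == 0:
        raise ValueError("cluster is empty")
    if venc <= 0:
        raise ValueError("venc must be positive")
    mean_phase = corrected_phase[vox[:, 0], vox[:, 1], :].mean(axis=0)
    return VelocityWaveform(values=mean_phase * venc / np.pi,
                            phase_duration=phase_duration,
                            source_cluster=cluster_id,
                            pathway="cluster_mean")


def sinus_waveform(series: GatedPCSeries, sinus_region: np.ndarray,
                   window: int = DEFAULT_MEDIAN_WINDOW,
                   flow_sign: int = -1,
                   cluster_id: int | None = None) -> VelocityWaveform:
    """Reference waveform from the superior sagittal sinus.

    Takes the ``SINUS_TOP_N`` voxels of highest cycle-averaged magnitude in
    the given region (ties broken in raster order), runs the standard
    background removal and temporal unwrapping, then forces all voxels onto
    one wrap branch: for the usual superior-to-inferior (negative phase)
    sinus flow, 2*pi is subtracted wherever the phase is positive
    (``flow_sign=+1`` mirrors this for opposite geometries).  The voxelwise
    median across the selected voxels, scaled by venc/pi, is returned.
    Valid for waveform timing, not for absolute speed.
    """
    vox = np.atleast_2d(np.asarray(sinus_region, dtype=int))
    if vox.size == 0:
        raise ValueError("sinus region is empty")
    if flow_sign not in (-1, 1):
        raise ValueError("flow_sign must be -1 or +1")

    avg_mag = series.magnitude.mean(axis=2)[vox[:, 0], vox[:, 1]]
    if len(vox) < SINUS_TOP_N:
        warnings.warn(f"sinus region has only {len(vox)} voxels "
                      f"(< {SINUS_TOP_N}); using all of them")
        chosen = vox
    else:
        # stable sort on descending magnitude keeps raster order among ties
        order = np.argsort(-avg_mag, kind="stable")[:SINUS_TOP_N]
        chosen = vox[np.sort(order)]

    corrected = remove_background_phase(series.phase, window=window)
    unwrapped = unwrap_temporal(corrected)
    sel = unwrapped[chosen[:, 0], chosen[:, 1], :].copy()
    if flow_sign < 0:
        sel[sel > 0] -= 2 * np.pi
    else:
        sel[sel < 0] += 2 * np.pi
    median_phase = np.median(sel, axis=0)
    return VelocityWaveform(values=median_phase * series.venc / np.pi,
                            phase_duration=series.phase_duration,
                            source_cluster=cluster_id,
                            pathway="sinus_median")


def extract_waveforms(series: GatedPCSeries, cmap: VesselClusterMap,
                      window: int = DEFAULT_MEDIAN_WINDOW,
                      sinus_flow_sign: int = -1
                      ) -> dict[int, VelocityWaveform]:
    """Waveforms for every cluster; sinus clusters use the sinus pathway."""
    corrected = remove_background_phase(series.phase, window=window)
    unwrapped = unwrap_temporal(corrected)
    out: dict[int, VelocityWaveform] = {}
    for _, row in cmap.clusters.iterrows():
        cid = int(row["cluster_id"])
        if row["class_label"] == "sinus":
            out[cid] = sinus_waveform(series, cmap.voxels(cid), window=window,
                                      flow_sign=sinus_flow_sign,
                                      cluster_id=cid)
        else:
            out[cid] = cluster_waveform(unwrapped, cmap.voxels(cid),
                                        series.venc, series.phase_duration,
                                        cluster_id=cid)
    return out


def waveform_table(waveforms: dict[int, VelocityWaveform]) -> pd.DataFrame:
    """Long-format table: cluster id, cardiac phase, time (ms), cm/s."""
    rows = []
    for cid in sorted(waveforms):
        w = waveforms[cid]
        for t, v in enumerate(w.values):
            rows.append({"cluster_id": cid, "cardiac_phase": t,
                         "time_ms": t * w.phase_duration,
                         "velocity_cm_s": v, "pathway": w.pathway})
    return pd.DataFrame(rows, columns=["cluster_id", "cardiac_phase",
                                       "time_ms", "velocity_cm_s", "pathway"])
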