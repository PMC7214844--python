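"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the code paths they check: the
Savitzky-Golay oracle is built from explicit least-squares polynomial fits
(numpy.polyfit), the connected-component oracle is a breadth-first flood
fill, and the lag oracle is an exhaustive scan over all circular shifts.
"""

from __future__ import annotations

import numpy as np
import pytest

from veinpulse.synthetic import SceneConfig, VesselSpec, render_scene


# ---------------------------------------------------------------------------
# oracles

def sg_oracle(x: np.ndarray, frame: int = 15, order: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing via explicit polynomial least squares.

    Interior samples: fit an order-``order`` polynomial to the centred
    window and evaluate at its centre.  The first and last half-windows are
    taken from single polynomial fits to the first and last ``frame``
    samples (the standard edge convention).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    half = frame // 2
    t = np.arange(-half, half + 1)
    out = np.empty(n)
    for i in range(half, n - half):
        coef = np.polyfit(t, x[i - half:i + half + 1], order)
        out[i] = np.polyval(coef, 0.0)
    head = np.polyfit(np.arange(frame), x[:frame], order)
    for i in range(half):
        out[i] = np.polyval(head, i)
    tail = np.polyfit(np.arange(frame), x[-frame:], order)
    for i in range(half):
        out[n - half + i] = np.polyval(tail, frame - half + i)
    return out


def pcnr_oracle(x: np.ndarray) -> tuple[float, float, float]:
    """Brute-force pulsatility contrast-to-noise ratio from the SG oracle."""
    f = sg_oracle(x)
    delta_v = f.max() - f.min()
    res = x - f
    res_sd = np.sqrt(np.sum(res ** 2) / (x.size - 1))
    return delta_v / res_sd, delta_v, res_sd


def floodfill_label_oracle(mask: np.ndarray) -> np.ndarray:
    """8-connected component labelling by BFS, ids in raster order."""
    mask = np.asarray(mask, dtype=bool)
    label = np.zeros(mask.shape, dtype=int)
    nxt = 0
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c] and label[r, c] == 0:
                nxt += 1
                queue = [(r, c)]
                label[r, c] = nxt
                while queue:
                    rr, cc = queue.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            nr, nc = rr + dr, cc + dc
                            if (0 <= nr < mask.shape[0]
                                    and 0 <= nc < mask.shape[1]
                                    and mask[nr, nc]
                                    and label[nr, nc] == 0):
                                label[nr, nc] = nxt
                                queue.append((nr, nc))
    return label


def lag_oracle(w: np.ndarray, ref: np.ndarray) -> int:
    """Exhaustive circular cross-correlation argmax, smallest-|lag| ties."""
    w = np.asarray(w, float) - np.mean(w)
    ref = np.asarray(ref, float) - np.mean(ref)
    n = w.size
    best = None
    for s in range(n):
        c = sum(w[t] * ref[(t - s) % n] for t in range(n))
        signed = (s + n // 2) % n - n // 2
        key = (-c, abs(signed), signed < 0)
        if best is None or key < best[0]:
            best = (key, signed)
    return best[1]


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def single_vein_scene(noise_sd_phase=0.0, noise_sd_mag=0.0, lag_ms=0.0,
                      mean_speed=1.0, amplitude=0.15, background=((0.0,),),
                      seed=11, grid_size=40, n_phases=38):
    """One 4-voxel vein, defaults noiseless and background-free."""
    vein = VesselSpec(center=(20, 20),
                      footprint=((0, 0), (0, 1), (1, 0), (1, 1)),
                      class_label="small_vein", mean_speed=mean_speed,
                      pulse_amplitude=amplitude, lag_ms=lag_ms)
    cfg = SceneConfig(grid_size=grid_size, n_phases=n_phases, vessels=(vein,),
                      background_phase=background,
                      noise_sd_phase=noise_sd_phase,
                      noise_sd_mag=noise_sd_mag, seed=seed)
    return render_scene(cfg)


@pytest.fixture(scope="session")
def noiseless_scene():
    return single_vein_scene()


@pytest.fixture(scope="session")
def calibration_38():
    """Shared Monte Carlo calibration at the default acquisition length."""
    from veinpulse.pulsatility import calibrate_null
    return calibrate_null(n_phases=38, n_reps=50_000, seed=20200415)
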