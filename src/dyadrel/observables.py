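"""Per-instant dyadic observables.

At each time instant a walking dyad is summarized by the observation vector
``S = (delta, vg, omega, eta)``:

* ``delta`` — interpersonal distance, the Euclidean norm of the relative
  position vector (m);
* ``vg``    — group velocity, the magnitude of the *mean* instantaneous
  velocity vector of the two peers (m/s);
* ``omega`` — relative velocity, the magnitude of the velocity difference
  vector (m/s);
* ``eta``   — absolute body-height difference (m), constant along a dyad's
  trajectory.

The two tracks of a dyad are resampled by linear interpolation onto a common
uniform grid over their overlapping time span before velocities are estimated,
so tracks from heterogeneous sensors (different rates, phases) are comparable.
No range filtering happens here — raw observables stay inspectable; validity
filtering belongs to the distribution-building step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DyadRecord, PedestrianTrack, ValidationError

#: Observable names, in canonical order.
OBSERVABLES = ("delta", "vg", "omega", "eta")

#: Default resampling step (s) and velocity smoothing window (s).
DEFAULT_GRID_STEP = 0.5
DEFAULT_SMOOTHING_WINDOW = 1.0


@dataclass(frozen=True)
class ObservationVector:
    """One dyadic observation ``S = (delta, vg, omega, eta)`` at time ``t``."""

    t: float
    delta: float
    vg: float
    omega: float
    eta: float

    def as_array(self) -> np.ndarray:
        return np.array([self.delta, self.vg, self.omega, self.eta])


def interpersonal_distance(pos_i, pos_j) -> float:
    """Euclidean distance between two planar positions (m)."""
    pos_i = np.asarray(pos_i, dtype=float)
    pos_j = np.asarray(pos_j, dtype=float)
    return float(np.hypot(*(pos_i - pos_j)))


def group_velocity(v_i, v_j) -> float:
    """Magnitude of the mean velocity vector (not the mean of magnitudes)."""
    v = (np.asarray(v_i, dtype=float) + np.asarray(v_j, dtype=float)) / 2.0
    return float(np.hypot(*v))


def relative_velocity_magnitude(v_i, v_j) -> float:
    """Magnitude of the velocity difference vector."""
    d = np.asarray(v_i, dtype=float) - np.asarray(v_j, dtype=float)
    return float(np.hypot(*d))


def height_difference(h_i: float, h_j: float) -> float:
    """Absolute body-height difference; symmetric in its arguments."""
    return abs(float(h_i) - float(h_j))


def estimate_velocity(
    track: PedestrianTrack, smoothing_window: float = DEFAULT_SMOOTHING_WINDOW
) -> np.ndarray:
    """Per-sample 2-D velocity by finite differences over a time window.

    For each sample the difference is taken between the farthest neighbours
    within ``smoothing_window / 2`` on each side (at least the immediate
    neighbours, so ``smoothing_window=0`` is the plain central difference);
    forward/backward differences are used at the track ends.

    Returns an ``(n, 2)`` array of (vx, vy) in m/s.
    """
    if smoothing_window < 0:
        raise ValueError("smoothing_window must be >= 0")
    t, x, y = track.t, track.x, track.y
    n = t.size
    if n < 2:
        raise ValidationError("velocity estimation needs >= 2 samples")
    half = smoothing_window / 2.0
    # farthest neighbour with t[j] <= t[k] + half, but at least k+1 (clipped)
    j_hi = np.searchsorted(t, t + half, side="right") - 1
    j_hi = np.clip(np.maximum(j_hi, np.arange(n) + 1), 0, n - 1)
    j_lo = np.searchsorted(t, t - half, side="left")
    j_lo = np.clip(np.minimum(j_lo, np.arange(n) - 1), 0, n - 1)
    dt = t[j_hi] - t[j_lo]
    v = np.empty((n, 2))
    v[:, 0] = (x[j_hi] - x[j_lo]) / dt
    v[:, 1] = (y[j_hi] - y[j_lo]) / dt
    return v


def _resample(track: PedestrianTrack, grid: np.ndarray) -> PedestrianTrack:
    return PedestrianTrack(
        ped_id=track.ped_id,
        t=grid,
        x=np.interp(grid, track.t, track.x),
        y=np.interp(grid, track.t, track.y),
        height=track.height,
    )


def extract_observations(
    dyad: DyadRecord,
    smoothing_window: float = DEFAULT_SMOOTHING_WINDOW,
    grid_step: float = DEFAULT_GRID_STEP,
) -> list[ObservationVector]:
    """Observation sequence for one dyad on the common resampling grid.

    The overlapping time span of the two tracks is discretized with step
    ``grid_step``; both tracks are linearly interpolated onto that grid and
    velocities estimated there.  Raises if the overlap holds fewer than two
    grid points (no velocity estimate possible).
    """
    lo = max(dyad.track_a.t[0], dyad.track_b.t[0])
    hi = min(dyad.track_a.t[-1], dyad.track_b.t[-1])
    if hi <= lo:
        raise ValidationError(f"dyad {dyad.dyad_id!r}: tracks do not overlap in time")
    n_grid = int(np.floor((hi - lo) / grid_step)) + 1
    if n_grid < 2:
        raise ValidationError(
            f"dyad {dyad.dyad_id!r}: overlap too short for grid step {grid_step}"
        )
    grid = lo + grid_step * np.arange(n_grid)
    ta = _resample(dyad.track_a, grid)
    tb = _resample(dyad.track_b, grid)
    va = estimate_velocity(ta, smoothing_window)
    vb = estimate_velocity(tb, smoothing_window)

    dx = ta.x - tb.x
    dy = ta.y - tb.y
    delta = np.hypot(dx, dy)
    vmean = (va + vb) / 2.0
    vdiff = va - vb
    vg = np.hypot(vmean[:, 0], vmean[:, 1])
    omega = np.hypot(vdiff[:, 0], vdiff[:, 1])
    eta = height_difference(ta.height, tb.height)

    return [
        ObservationVector(t=float(grid[k]), delta=float(delta[k]), vg=float(vg[k]),
                          omega=float(omega[k]), eta=eta)
        for k in range(n_grid)
    ]


def observations_to_frame(dyad_id: str, observations) -> pd.DataFrame:
    """Tabular export (dyad_id, t, delta, vg, omega, eta) for debugging."""
    return pd.DataFrame(
        {
            "dyad_id": dyad_id,
            "t": [s.t for s in observations],
            "delta": [s.delta for s in observations],
            "vg": [s.vg for s in observations],
            "omega": [s.omega for s in observations],
            "eta": [s.eta for s in observations],
        }
    )
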