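"""Helix axis fitting and bend/tilt angles from Cα traces.

An α-helix axis is estimated by smoothing the Cα trace with a 3-residue
sliding mean (which collapses the helical wobble onto the axis) and fitting
a best least-squares line through the smoothed points.  Two angle notions
are exposed, because both occur when describing factor rearrangements:

* **bend**: the angle between the axes of two flanking segments of a single
  conformation (a kink within one model, e.g. a helix turning sharply by
  90° around one residue);
* **tilt**: the angle between the axes of the *same* helix segment in two
  conformations, measured after the caller has superposed the models on a
  common anchor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class HelixError(Exception):
    pass


class InsufficientPointsError(HelixError):
    pass


@dataclass(frozen=True)
class HelixAxisFit:
    axis_direction: np.ndarray   # unit vector, oriented first -> last residue
    axis_point: np.ndarray       # centroid of the smoothed trace, Å
    first_index: int
    last_index: int
    fit_rms: float               # Å, residual of smoothed points about the line


def _smooth(coords: np.ndarray, window: int = 3) -> np.ndarray:
    """Sliding-window mean; end points keep shorter windows."""
    n = len(coords)
    half = window // 2
    out = np.empty_like(coords)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = coords[lo:hi].mean(axis=0)
    return out


def fit_helix_axis(ca_coords: np.ndarray, smoothing_window: int = 3) -> HelixAxisFit:
    """Fit the axis of an ordered Cα trace (>= 4 residues).

    The primary estimator uses the discrete-helix construction: for chord
    vectors v_i = p_{i+1} - p_i, the differences c_i = v_{i+1} - v_i point
    radially toward the axis, so successive cross products c_i × c_{i+1}
    all lie along the axis.  This is exact for an ideal helix of any length
    >= 4, which matters for the short 7-residue flanks used in kink
    measurement where a principal-component fit of the smoothed trace is
    biased by the incomplete final turn.  For (near-)collinear traces, where
    the curvature vectors vanish, the fit falls back to the principal
    component of the 3-residue sliding-mean smoothed trace.  The direction
    is oriented from the first toward the last residue.
    """
    coords = np.asarray(ca_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise HelixError(f"expected (n, 3) coordinates, got {coords.shape}")
    n = len(coords)
    if n < 4:
        raise InsufficientPointsError(f"need >= 4 Cα positions, got {n}")
    sm = _smooth(coords, smoothing_window)
    center = sm.mean(axis=0)
    span = coords[-1] - coords[0]

    chords = np.diff(coords, axis=0)
    curv = np.diff(chords, axis=0)
    crosses = np.cross(curv[:-1], curv[1:])
    norms = np.linalg.norm(crosses, axis=1)
    scale = float(np.linalg.norm(chords, axis=1).mean())
    usable = norms > 1e-8 * scale ** 2
    if usable.any():
        units = crosses[usable] / norms[usable, None]
        units[units @ span < 0] *= -1  # orient along the trace
        direction = units.mean(axis=0)
        direction = direction / np.linalg.norm(direction)
    else:
        # straight or degenerate trace: line fit of the smoothed points
        _, _, vt = np.linalg.svd(sm - center)
        direction = vt[0]
    if direction @ span < 0:
        direction = -direction
    resid = (sm - center) - np.outer((sm - center) @ direction, direction)
    fit_rms = float(np.sqrt((resid ** 2).sum() / n))
    return HelixAxisFit(direction, center, 0, n - 1, fit_rms)


def bend_angle(ca_coords: np.ndarray, kink_index: int, flank: int = 6) -> float:
    """Angle in degrees between helix segments on either side of *kink_index*.

    Each flanking segment spans ``flank`` residues up to (and including) the
    kink residue; 0° for a straight helix, in [0, 180].
    """
    coords = np.asarray(ca_coords, dtype=float)
    n = len(coords)
    if flank < 4:
        raise HelixError(f"flank must be >= 4 residues, got {flank}")
    if kink_index - flank < 0 or kink_index + flank >= n:
        raise HelixError(
            f"flank window of {flank} around index {kink_index} exceeds trace of {n}")
    before = fit_helix_axis(coords[kink_index - flank: kink_index + 1])
    after = fit_helix_axis(coords[kink_index: kink_index + flank + 1])
    return angle_between(before.axis_direction, after.axis_direction)


def tilt_angle(ca_coords_a: np.ndarray, ca_coords_b: np.ndarray) -> float:
    """Angle between the fitted axes of one helix segment in two conformations.

    Meaningful only after both conformations are expressed in a common frame
    (anchor superposition is the caller's responsibility).
    """
    fa = fit_helix_axis(ca_coords_a)
    fb = fit_helix_axis(ca_coords_b)
    return angle_between(fa.axis_direction, fb.axis_direction)


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors in degrees, [0, 180]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    c = (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))
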