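"""Joint-angle extraction from optical hand-marker trajectories.

The hand is instrumented with 20 reflective markers: three per finger along
the phalange chain (for the thumb: metacarpal, proximal and distal phalange;
for the other fingers: proximal, middle and distal phalange), three on the
metacarpals spanning the palm surface, and two on the wrist joint.

Two angles summarise each finger:

* ``theta1`` — the angle between the palm-plane normal and the line from the
  palm-marker centroid to the finger's base marker (proximal phalange;
  thumb: metacarpal).
* ``theta2`` — the flexion angle between the base->middle and middle->tip
  segment directions, so a straight finger reads 0 deg and flexion
  increases the angle.

Both are invariant to rigid motion and uniform scaling of the marker cloud,
which is what makes them usable across subjects with different hand sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import (
    DegenerateGeometryError,
    InputTooShortError,
    MissingDataError,
)

FINGERS: tuple[str, ...] = ("thumb", "index", "middle", "ring", "pinky")

#: Marker order used throughout the package: three markers per finger
#: (base -> tip), then three palm markers, then two wrist markers.
MARKER_NAMES: tuple[str, ...] = tuple(
    f"{finger}_{part}"
    for finger in FINGERS
    for part in (("metacarpal", "proximal", "distal") if finger == "thumb"
                 else ("proximal", "middle", "distal"))
) + ("palm_a", "palm_b", "palm_c", "wrist_a", "wrist_b")

PALM_SLICE = slice(15, 18)
WRIST_SLICE = slice(18, 20)

#: Angle order: per finger, theta1 then theta2.
ANGLE_NAMES: tuple[str, ...] = tuple(
    f"{finger}_{angle}" for finger in FINGERS for angle in ("theta1", "theta2")
)

_GEOM_TOL = 1e-9


@dataclass(frozen=True)
class PalmFrame:
    """Palm reference frame: centroid of the three palm markers and the
    unit normal of the plane they span (sign fixed by marker order)."""

    centroid: np.ndarray  # (3,) mm
    normal: np.ndarray    # (3,) unit vector


@dataclass
class AngleSeriesSet:
    """Ten joint-angle time series (deg) at the kinematic rate.

    ``values`` is (10, T) ordered as :data:`ANGLE_NAMES`.
    """

    values: np.ndarray
    names: tuple[str, ...] = ANGLE_NAMES
    rate_hz: float = 120.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.names):
            raise ValueError(
                f"expected ({len(self.names)}, T) angle array, got {self.values.shape}"
            )

    def series(self, name: str) -> np.ndarray:
        return self.values[self.names.index(name)]


def lowpass_trajectories(
    marker_block: np.ndarray,
    cutoff_hz: float = 15.0,
    rate_hz: float = 120.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter of marker trajectories.

    Parameters
    ----------
    marker_block : (n_markers, T, 3) array, mm.
    cutoff_hz : cutoff frequency; the motion-capture pipeline uses 15 Hz.
    rate_hz : sampling rate (must exceed twice the cutoff).

    Zero-phase (forward-backward) application avoids the group delay that
    would otherwise shift phase boundaries relative to the force channels.
    """
    if rate_hz <= 2 * cutoff_hz:
        raise ValueError("sampling rate must exceed twice the cutoff frequency")
    block = np.asarray(marker_block, dtype=float)
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rate_hz, output="sos")
    padlen = 3 * (2 * order + 1)
    if block.shape[-2] <= padlen:
        raise InputTooShortError(
            f"need more than {padlen} frames for zero-phase filtering, "
            f"got {block.shape[-2]}"
        )
    return signal.sosfiltfilt(sos, block, axis=-2)


def palm_frame(palm_markers: np.ndarray) -> PalmFrame:
    """Centroid and unit normal of the plane spanned by the 3 palm markers.

    The normal direction is ``(b - a) x (c - a)`` normalised, so its sign is
    fixed by the marker labelling order.
    """
    pts = np.asarray(palm_markers, dtype=float)
    if pts.shape != (3, 3):
        raise ValueError(f"expected (3, 3) palm markers, got {pts.shape}")
    centroid = pts.mean(axis=0)
    cross = np.cross(pts[1] - pts[0], pts[2] - pts[0])
    norm = np.linalg.norm(cross)
    scale = max(np.linalg.norm(pts[1] - pts[0]), np.linalg.norm(pts[2] - pts[0]), 1.0)
    if norm <= _GEOM_TOL * scale**2:
        raise DegenerateGeometryError("palm markers are collinear or coincident")
    return PalmFrame(centroid=centroid, normal=cross / norm)


def _angle_deg(u: np.ndarray, v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Angle in degrees between vectors, stable near 0 and 180 deg."""
    cross = np.linalg.norm(np.cross(u, v, axis=axis), axis=axis)
    dot = np.sum(u * v, axis=axis)
    return np.degrees(np.arctan2(cross, dot))


def proximal_angle_theta1(palm: PalmFrame, proximal_marker: np.ndarray) -> float:
    """theta1: angle (deg, in [0, 180]) between the palm normal and the line
    from the palm centroid to the finger's base marker."""
    d = np.asarray(proximal_marker, dtype=float) - palm.centroid
    if np.linalg.norm(d) <= _GEOM_TOL:
        raise DegenerateGeometryError("proximal marker coincides with palm centroid")
    return float(_angle_deg(palm.normal, d))


def flexion_angle_theta2(
    proximal_marker: np.ndarray,
    middle_marker: np.ndarray,
    distal_marker: np.ndarray,
) -> float:
    """theta2: flexion angle (deg) between successive segment directions.

    Collinear extension of the two segments reads 0 deg; flexion increases
    the angle towards 180 deg.
    """
    p, m, d = (np.asarray(x, dtype=float) for x in (proximal_marker, middle_marker, distal_marker))
    u, v = m - p, d - m
    if np.linalg.norm(u) <= _GEOM_TOL or np.linalg.norm(v) <= _GEOM_TOL:
        raise DegenerateGeometryError("coincident phalange markers")
    return float(_angle_deg(u, v))


def _check_missing(block: np.ndarray) -> None:
    bad = ~np.isfinite(block).all(axis=2)  # (n_markers, T)
    if bad.any():
        marker_idx, frame_idx = np.nonzero(bad)
        m = int(marker_idx[0])
        frames = frame_idx[marker_idx == m]
        raise MissingDataError(
            f"marker '{MARKER_NAMES[m]}' missing in frames "
            f"{int(frames.min())}..{int(frames.max())}; trial rejected"
        )


def extract_joint_angles(
    trial,
    lowpass: bool = True,
    cutoff_hz: float = 15.0,
) -> AngleSeriesSet:
    """Compute the ten joint-angle series from a trial's marker block.

    Parameters
    ----------
    trial : TrialRecording (or any object with ``marker_block`` of shape
        (20, T, 3) in mm, ``kinematic_rate`` and optional ``handedness``).
    lowpass : apply the 15 Hz zero-phase trajectory filter first.

    Raises
    ------
    MissingDataError
        if any marker has non-finite frames (the trial is rejected, mirroring
        the rejection of recordings with marker dropout).
    """
    block = np.asarray(trial.marker_block, dtype=float)
    if block.ndim != 3 or block.shape[0] != len(MARKER_NAMES) or block.shape[2] != 3:
        raise ValueError(f"expected (20, T, 3) marker block, got {block.shape}")
    _check_missing(block)
    if getattr(trial, "handedness", "right") == "left":
        # mirror left hands so one angle convention serves all subjects
        block = block.copy()
        block[:, :, 0] *= -1.0
    rate = float(getattr(trial, "kinematic_rate", 120.0))
    if lowpass:
        block = lowpass_trajectories(block, cutoff_hz=cutoff_hz, rate_hz=rate)

    palm = block[PALM_SLICE]  # (3, T, 3)
    centroid = palm.mean(axis=0)  # (T, 3)
    cross = np.cross(palm[1] - palm[0], palm[2] - palm[0])  # (T, 3)
    norms = np.linalg.norm(cross, axis=1)
    if np.any(norms <= _GEOM_TOL):
        raise DegenerateGeometryError("palm markers collinear in at least one frame")
    normal = cross / norms[:, None]

    T = block.shape[1]
    values = np.empty((len(ANGLE_NAMES), T))
    for i, _finger in enumerate(FINGERS):
        base, mid, tip = block[3 * i], block[3 * i + 1], block[3 * i + 2]
        values[2 * i] = _angle_deg(normal, base - centroid)
        values[2 * i + 1] = _angle_deg(mid - base, tip - mid)
    return AngleSeriesSet(values=values, rate_hz=rate)


def wrist_speed(trial, lowpass: bool = True, cutoff_hz: float = 15.0) -> np.ndarray:
    """Speed (mm/s) of the mean wrist-marker position, length T.

    Used by phase segmentation to detect movement onset and end.
    """
    block = np.asarray(trial.marker_block, dtype=float)
    _check_missing(block)
    rate = float(getattr(trial, "kinematic_rate", 120.0))
    if lowpass:
        block = lowpass_trajectories(block, cutoff_hz=cutoff_hz, rate_hz=rate)
    wrist = block[WRIST_SLICE].mean(axis=0)  # (T, 3)
    vel = np.gradient(wrist, 1.0 / rate, axis=0)
    return np.linalg.norm(vel, axis=1)
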