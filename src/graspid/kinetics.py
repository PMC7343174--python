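"""Fingertip force processing: spring-platform calibration and filtering.

Each fingertip carries a thin-film force sensor whose output voltage is a
monotone but not necessarily linear function of the applied normal force.
Before a session, the subject presses each finger on a spring-loaded
platform riding on low-friction rails; the platform displacement ``dx`` is
tracked optically, so the applied force is known from Hooke's law
``F = k * dx`` with spring constant ``k`` (0.45 N/mm by default). Three
repetitions per finger are pooled and averaged on a common voltage grid,
then monotonised by isotonic regression, yielding a piecewise-linear
voltage-to-force curve.

Raw force channels are sampled at 960 Hz; the mains hum at 50 Hz is removed
with a zero-phase band-stop filter and the channels are decimated by the
integer rate ratio (8) down to the 120 Hz kinematic rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from sklearn.isotonic import IsotonicRegression

from .errors import CalibrationError, ConfigurationError, InputTooShortError

logger = logging.getLogger(__name__)


@dataclass
class CalibrationRecording:
    """Raw spring-platform calibration data for one finger.

    ``repetitions`` holds (voltage, displacement_mm) sample pairs for each of
    the (normally three) presses; displacement is converted to force through
    the known spring constant.
    """

    finger: str
    repetitions: list[tuple[np.ndarray, np.ndarray]]
    spring_constant: float = 0.45  # N/mm

    def __post_init__(self) -> None:
        if self.spring_constant <= 0:
            raise ConfigurationError("spring constant must be positive")
        if not self.repetitions:
            raise CalibrationError("calibration recording has no repetitions")
        self.repetitions = [
            (np.asarray(v, dtype=float), np.asarray(d, dtype=float))
            for v, d in self.repetitions
        ]
        for v, d in self.repetitions:
            if v.shape != d.shape or v.ndim != 1:
                raise CalibrationError("voltage/displacement shape mismatch")


@dataclass
class CalibrationCurve:
    """Monotone piecewise-linear voltage -> force (N) mapping for one finger."""

    finger: str
    voltage_grid: np.ndarray
    force_values: np.ndarray  # non-decreasing, >= 0, starts at 0

    def __post_init__(self) -> None:
        self.voltage_grid = np.asarray(self.voltage_grid, dtype=float)
        self.force_values = np.asarray(self.force_values, dtype=float)
        if np.any(np.diff(self.voltage_grid) <= 0):
            raise CalibrationError("voltage grid must be strictly increasing")
        if np.any(np.diff(self.force_values) < -1e-9):
            raise CalibrationError("calibration curve must be non-decreasing")

    @property
    def voltage_range(self) -> tuple[float, float]:
        return float(self.voltage_grid[0]), float(self.voltage_grid[-1])

    def __call__(self, volts: np.ndarray) -> np.ndarray:
        """Map voltages to forces; out-of-range inputs clamp to the endpoints."""
        v = np.asarray(volts, dtype=float)
        lo, hi = self.voltage_range
        n_out = int(np.sum((v < lo) | (v > hi)))
        if n_out:
            logger.warning(
                "finger %s: %d voltage sample(s) outside calibrated range "
                "[%.3f, %.3f] V, clamped", self.finger, n_out, lo, hi,
            )
        return np.interp(v, self.voltage_grid, self.force_values)

    def to_dict(self) -> dict:
        return {
            "finger": self.finger,
            "voltage_grid": self.voltage_grid.tolist(),
            "force_values": self.force_values.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(d["finger"], np.asarray(d["voltage_grid"]), np.asarray(d["force_values"]))


def fit_calibration(rec: CalibrationRecording, n_grid: int = 200) -> CalibrationCurve:
    """Build the monotone voltage->force curve from a calibration recording.

    For each repetition the force is ``k * dx``; repetitions are interpolated
    onto a common voltage grid spanning the overlap of their voltage ranges,
    averaged, then monotonised with isotonic regression and anchored so the
    baseline (lowest calibrated) voltage maps to 0 N.
    """
    lo = max(float(v.min()) for v, _ in rec.repetitions)
    hi = min(float(v.max()) for v, _ in rec.repetitions)
    if not hi > lo:
        raise CalibrationError(
            f"finger {rec.finger}: repetition voltage ranges do not overlap"
        )
    grid = np.linspace(lo, hi, n_grid)
    pooled = np.zeros(n_grid)
    for volts, disp in rec.repetitions:
        force = rec.spring_constant * disp
        order = np.argsort(volts, kind="stable")
        pooled += np.interp(grid, volts[order], force[order])
    pooled /= len(rec.repetitions)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    fitted = iso.fit_transform(grid, pooled)
    fitted = np.maximum(fitted - fitted[0], 0.0)  # baseline voltage -> 0 N
    return CalibrationCurve(rec.finger, grid, fitted)


def bandstop_mains(
    force_block: np.ndarray,
    stop_hz: float = 50.0,
    rate_hz: float = 960.0,
    half_width_hz: float = 2.0,
    order: int = 4,
) -> np.ndarray:
    """Remove the mains-frequency hum from force channels.

    A narrow zero-phase Butterworth band-stop (default 48-52 Hz) applied
    along the last axis. Attenuates a pure 50 Hz tone essentially to zero
    while leaving DC and the low-frequency grip-force band untouched.
    """
    if rate_hz <= 2 * stop_hz:
        raise ConfigurationError("sampling rate must exceed twice the stop frequency")
    block = np.asarray(force_block, dtype=float)
    sos = signal.butter(
        order,
        [stop_hz - half_width_hz, stop_hz + half_width_hz],
        btype="bandstop",
        fs=rate_hz,
        output="sos",
    )
    padlen = 3 * (4 * order + 1)
    if block.shape[-1] <= padlen:
        raise InputTooShortError(
            f"need more than {padlen} samples for zero-phase band-stop, "
            f"got {block.shape[-1]}"
        )
    return signal.sosfiltfilt(sos, block, axis=-1)


def downsample_to_kinematic_rate(force_block: np.ndarray, factor: int = 8) -> np.ndarray:
    """Anti-aliased decimation of force channels by the integer rate ratio.

    The trailing samples that do not fill a whole decimation step are
    truncated, so the output length is ``floor(T / factor)``.
    """
    if factor < 1:
        raise ConfigurationError("decimation factor must be >= 1")
    block = np.asarray(force_block, dtype=float)
    if factor == 1:
        return block.copy()
    T = block.shape[-1]
    keep = (T // factor) * factor
    if keep == 0:
        raise InputTooShortError("fewer samples than the decimation factor")
    block = block[..., :keep]
    # polyphase FIR resampling; line-extension padding avoids the edge droop
    # zero padding would cause on signals with a non-zero baseline
    return signal.resample_poly(block, up=1, down=factor, axis=-1, padtype="line")


def voltage_to_force(curve: CalibrationCurve, force_block_volts: np.ndarray) -> np.ndarray:
    """Elementwise monotone mapping of a voltage block to forces in newtons."""
    if curve is None:
        raise CalibrationError("no calibration curve available for this finger")
    return curve(force_block_volts)
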