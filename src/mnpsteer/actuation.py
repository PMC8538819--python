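"""Two-electromagnet field model and actuation waveforms.

The experimental rig is a pair of coils facing each other across a 10 mm
region of interest; the measured axial field magnitude (mT) versus coil
current (A) and distance from the coil face (mm) is shipped as a packaged
calibration table.  This module exposes:

* :func:`calibrate` — a monotone interpolant of that table (PCHIP in
  distance, linear in current) that reproduces every printed node exactly;
* :class:`ActuationScheme` — the programmable coil-switching waveforms:

  - ``static``: one coil continuously on (the baseline used for the
    aggregation parameter studies);
  - ``dma``: dynamic actuation, equal-magnitude alternation (H, H, Fr.);
  - ``a-dma``: asymmetrical dynamic actuation, strong coil at H for 2/3 of
    the period, weak coil at h for 1/3 (H, h, Fr.);
  - ``da-dma``: discontinuous asymmetrical actuation, an a-dma cycle
    followed by an all-off interval Tdis (H, h, Fr., Tdis);

* :func:`field_at` / :func:`field_batch` — the quasi-1D spatial field
  sample (intensity + gradient) seen by particles at a given time.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Tuple

import numpy as np
from scipy.interpolate import PchipInterpolator

from .forces import MU0, MagneticSample

__all__ = [
    "CalibrationTable",
    "FieldCalibration",
    "CoilPair",
    "ActuationScheme",
    "calibrate",
    "waveform",
    "field_at",
    "field_batch",
    "load_calibration_table",
]

SCHEMES = ("static", "dma", "a-dma", "da-dma")


class CalibrationRangeError(ValueError):
    """Query outside the calibrated current/distance range without the
    extrapolation flag."""


@dataclass
class CalibrationTable:
    """Printed current–distance field map: ``field[i, j]`` is the field in mT
    at ``currents[i]`` A and ``distances[j]`` mm from the coil face."""

    currents: np.ndarray
    distances: np.ndarray
    field: np.ndarray

    def __post_init__(self) -> None:
        self.currents = np.asarray(self.currents, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        self.field = np.asarray(self.field, dtype=float)
        if self.field.shape != (self.currents.size, self.distances.size):
            raise ValueError("field matrix shape must be (n_currents, n_distances)")
        if self.currents.size < 2 or self.distances.size < 2:
            raise ValueError("need at least 2 currents and 2 distances")
        if np.any(np.diff(self.currents) <= 0) or np.any(np.diff(self.distances) <= 0):
            raise ValueError("currents and distances must be strictly increasing")

    def validate(self) -> list:
        """Check physical orderings; anomalies are reported (and warned
        about), never silently edited — the packaged table keeps the printed
        4 A / 2.5 mm value even though it breaks current-monotonicity."""
        anomalies = []
        for i, cur in enumerate(self.currents):
            if np.any(np.diff(self.field[i]) >= 0):
                anomalies.append(f"row {cur:g} A not strictly decreasing in distance")
        for j, dist in enumerate(self.distances):
            col = self.field[:, j]
            if np.any(np.diff(col) <= 0):
                anomalies.append(
                    f"column {dist:g} mm not strictly increasing in current"
                )
        for msg in anomalies:
            warnings.warn(f"calibration table anomaly: {msg}", stacklevel=2)
        return anomalies


def load_calibration_table() -> CalibrationTable:
    """Load the packaged coil calibration table (mT vs A and mm)."""
    path = resources.files("mnpsteer.data").joinpath("coil_field_mT.csv")
    with path.open() as fh:
        rows = list(csv.reader(fh))
    distances = [float(x) for x in rows[0][1:]]
    currents = [float(r[0]) for r in rows[1:]]
    fieldmat = [[float(x) for x in r[1:]] for r in rows[1:]]
    return CalibrationTable(np.array(currents), np.array(distances), np.array(fieldmat))


class FieldCalibration:
    """Callable field-magnitude map ``(current A, distance mm) -> mT``.

    Monotone piecewise-cubic (PCHIP) in distance so the printed ordering is
    preserved without overshoot; linear in current.  Exact at every table
    node.  Queries outside the table range raise unless ``extrapolate`` is
    set, in which case the current axis is extended linearly and the
    distance axis is clamped to the table edge.
    """

    def __init__(self, table: CalibrationTable):
        self.table = table
        self._rows = [PchipInterpolator(table.distances, row) for row in table.field]
        self._drows = [r.derivative() for r in self._rows]

    def _current_weights(self, current: float, extrapolate: bool):
        c = self.table.currents
        if current < c[0] or current > c[-1]:
            if not extrapolate:
                raise CalibrationRangeError(
                    f"current {current:g} A outside calibrated range "
                    f"[{c[0]:g}, {c[-1]:g}] A (pass extrapolate=True)"
                )
            i = 0 if current < c[0] else c.size - 2
        else:
            i = int(np.clip(np.searchsorted(c, current, side="right") - 1, 0, c.size - 2))
        w = (current - c[i]) / (c[i + 1] - c[i])
        return i, w

    def _distance(self, distance, extrapolate: bool):
        d = self.table.distances
        s = np.asarray(distance, dtype=float)
        out_of_range = (s < d[0]) | (s > d[-1])
        if np.any(out_of_range):
            if not extrapolate:
                raise CalibrationRangeError(
                    f"distance outside calibrated range [{d[0]:g}, {d[-1]:g}] mm "
                    "(pass extrapolate=True)"
                )
            s = np.clip(s, d[0], d[-1])
        return s

    def __call__(self, current: float, distance, extrapolate: bool = False):
        """Field magnitude in mT; table nodes are reproduced bit-exactly."""
        i, w = self._current_weights(current, extrapolate)
        s = self._distance(distance, extrapolate)
        lo = np.asarray(self._rows[i](s))
        hi = np.asarray(self._rows[i + 1](s))
        # snap exact node distances to the printed values (the interpolant
        # itself is exact there only up to rounding)
        d = self.table.distances
        s_arr = np.atleast_1d(s)
        for j, dj in enumerate(d):
            at_node = s_arr == dj
            if np.any(at_node):
                np.place(lo, np.reshape(at_node, lo.shape), self.table.field[i, j])
                np.place(hi, np.reshape(at_node, hi.shape), self.table.field[i + 1, j])
        val = (1.0 - w) * lo + w * hi
        return float(val) if np.isscalar(distance) else np.asarray(val)

    def derivative(self, current: float, distance, extrapolate: bool = False):
        """d(field)/d(distance) in mT/mm (numerically equal to T/m)."""
        i, w = self._current_weights(current, extrapolate)
        s = self._distance(distance, extrapolate)
        val = (1.0 - w) * self._drows[i](s) + w * self._drows[i + 1](s)
        return float(val) if np.isscalar(distance) else np.asarray(val)


def calibrate(table: CalibrationTable) -> FieldCalibration:
    """Build the interpolated field-magnitude function from a printed table."""
    return FieldCalibration(table)


@dataclass
class CoilPair:
    """Two coaxial coils whose faces bound the region of interest.

    The region center is the coordinate origin; coil faces sit at
    ``-separation/2`` and ``+separation/2`` along ``axis`` ("left" and
    "right").  Both coils share one calibration.
    """

    separation_mm: float = 10.0
    axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    calibration: FieldCalibration = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.separation_mm > 0:
            raise ValueError("separation must be positive")
        a = np.asarray(self.axis, dtype=float)
        self.axis = a / np.linalg.norm(a)
        if self.calibration is None:
            self.calibration = calibrate(load_calibration_table())


@dataclass
class ActuationScheme:
    """Coil-switching waveform (scheme, H, h, Fr., Tdis).

    ``H`` drives the strong (left) coil, ``h`` the weak (right) coil;
    ``frequency`` is the switching frequency Fr.; ``t_dis`` is the all-off
    interval appended to each cycle (da-dma only).  The strong:weak
    activation-time ratio defaults to 2:1.
    """

    scheme: str = "static"
    H: float = 3.0
    h: float = 1.0
    frequency: float = 1.0
    t_dis: float = 0.0
    duty_ratio: Tuple[float, float] = (2.0, 1.0)

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        if not (self.H >= self.h >= 0.0):
            raise ValueError("require H >= h >= 0")
        if not self.frequency > 0:
            raise ValueError("frequency must be positive")
        if self.t_dis < 0:
            raise ValueError("t_dis must be non-negative")
        if self.scheme == "dma" and self.H != self.h:
            raise ValueError("dma requires equal magnitudes H == h")
        if self.scheme != "da-dma" and self.t_dis != 0.0:
            raise ValueError("t_dis is used only by da-dma")

    @property
    def period(self) -> float:
        """Full waveform period: 1/Fr., plus Tdis for da-dma."""
        base = 1.0 / self.frequency
        return base + self.t_dis if self.scheme == "da-dma" else base

    def waveform(self, t: float) -> Tuple[float, float]:
        """Coil currents ``(left, right)`` in A at time ``t`` (s).

        At any instant exactly one coil is active, or none during the
        da-dma off interval.
        """
        if t < 0:
            raise ValueError("time must be non-negative")
        if self.scheme == "static":
            return (self.H, 0.0)
        T = 1.0 / self.frequency
        if self.scheme == "dma":
            phase = t - T * np.floor(t / T)
            return (self.H, 0.0) if phase < 0.5 * T else (0.0, self.H)
        frac = self.duty_ratio[0] / (self.duty_ratio[0] + self.duty_ratio[1])
        if self.scheme == "a-dma":
            phase = t - T * np.floor(t / T)
            return (self.H, 0.0) if phase < frac * T else (0.0, self.h)
        # da-dma: a-dma cycle of length T, then all-off for t_dis
        full = T + self.t_dis
        phase = t - full * np.floor(t / full)
        if phase >= T:
            return (0.0, 0.0)
        return (self.H, 0.0) if phase < frac * T else (0.0, self.h)


def waveform(scheme: ActuationScheme, t: float) -> Tuple[float, float]:
    """Functional alias for :meth:`ActuationScheme.waveform`."""
    return scheme.waveform(t)


def field_batch(
    positions: np.ndarray,
    t: float,
    coils: CoilPair,
    scheme: ActuationScheme,
    msat: float,
    extrapolate: bool = False,
):
    """Vectorized field sample at many positions (m) at time ``t``.

    Returns ``(H, J)`` with ``H`` of shape (N, 3) in A/m and ``J`` of shape
    (N, 3, 3) in A/m^2, where ``J[n, a, b] = dH_a/dx_b``.  The quasi-1D
    model points the field along the coil axis toward the active coil with
    the calibrated axial magnitude; the gradient is the analytic derivative
    of the interpolant.
    """
    x = np.atleast_2d(np.asarray(positions, dtype=float))
    n = x.shape[0]
    left, right = scheme.waveform(t)
    if left == 0.0 and right == 0.0:
        return np.zeros((n, 3)), np.zeros((n, 3, 3))
    axis = coils.axis
    half = 0.5 * coils.separation_mm  # mm
    axial_mm = (x @ axis) * 1e3  # coordinate along axis, mm from center
    if left > 0.0:
        current = left
        dist_mm = axial_mm + half  # distance from the left coil face
        toward = -axis  # field points toward the active (left) coil
    else:
        current = right
        dist_mm = half - axial_mm
        toward = axis
    cal = coils.calibration
    b_mT = np.asarray(cal(current, dist_mm, extrapolate=extrapolate), dtype=float)
    # d|B|/ds in mT/mm == T/m; s increases away from the coil.
    db_Tm = np.asarray(cal.derivative(current, dist_mm, extrapolate=extrapolate), dtype=float)
    h_mag = b_mT.reshape(n) * 1e-3 / MU0  # A/m
    # H(x) = |H|(s) * toward, s = (x - coil).u with u = -toward:
    # J = d|H|/ds * toward (x) u = -(d|H|/ds) toward (x) toward
    dh_ds = db_Tm.reshape(n) / MU0  # A/m^2, negative (field decays with s)
    outer = np.outer(toward, toward)
    H = h_mag[:, None] * toward[None, :]
    J = -dh_ds[:, None, None] * outer[None, :, :]
    return H, J


def field_at(
    x: np.ndarray,
    t: float,
    coils: CoilPair,
    scheme: ActuationScheme,
    msat: float,
    extrapolate: bool = False,
) -> MagneticSample:
    """Field sample (intensity, gradient, Msat) at one position and time."""
    H, J = field_batch(np.asarray(x, dtype=float)[None, :], t, coils, scheme, msat, extrapolate)
    return MagneticSample(intensity=H[0], gradient=J[0], saturation=msat)
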