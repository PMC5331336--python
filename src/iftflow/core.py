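"""Shared containers and small kinetic helpers.

Coordinate convention used across the whole package: the axial coordinate
``x`` is measured in nanometres along the cilium, ``x = 0`` at the ciliary
base, increasing toward the tip at ``x = L``.  Anterograde motion is
base-to-tip (``dx/dt > 0``), retrograde is tip-to-base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Trajectory",
    "Kymograph",
    "PiecewiseSpeed",
    "survival_probability",
    "run_length_from_hazard",
]


@dataclass
class Trajectory:
    """Time-ordered localizations of a single motor.

    Parameters
    ----------
    t : array of frame times, seconds (strictly increasing, uniform spacing)
    x : axial position, nm (0 = base, increasing toward tip)
    y : lateral offset from the ciliary axis, nm
    id : integer label
    dt_frame : frame interval, s
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    id: int = 0
    dt_frame: float = 0.15

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("t must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("t must be uniformly spaced")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) > 1 else 0.0


@dataclass
class Kymograph:
    """2-D intensity map, rows = frames (time), columns = axial position."""

    I: np.ndarray
    dt_frame: float
    dx_pixel: float
    channel: str = "ch1"

    def __post_init__(self) -> None:
        self.I = np.asarray(self.I, dtype=float)
        if self.I.ndim != 2:
            raise ValueError("kymograph intensity must be 2-D (time x position)")

    @property
    def n_frames(self) -> int:
        return self.I.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.I.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames * self.dt_frame

    @property
    def x_nm(self) -> np.ndarray:
        return (np.arange(self.n_pixels) + 0.5) * self.dx_pixel

    def copy_with(self, I: np.ndarray, channel: str | None = None) -> "Kymograph":
        return Kymograph(I=np.asarray(I, dtype=float), dt_frame=self.dt_frame,
                         dx_pixel=self.dx_pixel,
                         channel=self.channel if channel is None else channel)


@dataclass
class PiecewiseSpeed:
    """Piecewise-linear speed profile v(x) in nm/s.

    ``knots_x`` are axial positions (nm), ``knots_v`` the speeds there;
    evaluation interpolates linearly and clamps outside the knot range.
    """

    knots_x: np.ndarray = field(default_factory=lambda: np.array([0.0, 9000.0]))
    knots_v: np.ndarray = field(default_factory=lambda: np.array([1700.0, 1700.0]))

    def __post_init__(self) -> None:
        self.knots_x = np.asarray(self.knots_x, dtype=float)
        self.knots_v = np.asarray(self.knots_v, dtype=float)
        if self.knots_x.ndim != 1 or self.knots_x.shape != self.knots_v.shape:
            raise ValueError("knots_x and knots_v must be 1-D and equally long")
        if np.any(np.diff(self.knots_x) <= 0):
            raise ValueError("knots_x must be strictly increasing")

    def __call__(self, x):
        return np.interp(x, self.knots_x, self.knots_v)

    @classmethod
    def constant(cls, v: float, L: float = 9000.0) -> "PiecewiseSpeed":
        return cls(np.array([0.0, L]), np.array([float(v), float(v)]))

    @classmethod
    def with_transition_zone_dip(cls, v: float = 1700.0, L: float = 9000.0,
                                 dip_start: float = 500.0, dip_center: float = 1000.0,
                                 dip_end: float = 1500.0, dip_factor: float = 0.5
                                 ) -> "PiecewiseSpeed":
        """Constant speed with a linear dip in the transition zone.

        Only the ~1.7 um/s plateau is an observed quantity; the dip depth
        (``dip_factor``) is a configurable default.
        """
        return cls(np.array([0.0, dip_start, dip_center, dip_end, L]),
                   np.array([v, v, v * dip_factor, v, v]))


def survival_probability(hazard_per_um: float, distance_um: float) -> float:
    """Probability of travelling ``distance_um`` without a directional switch.

    Under a constant turnaround probability density ``P`` (per um travelled)
    the distance to the next switch is exponential, so the survival over a
    distance d is exp(-P d).  With the measured anterograde hazard of
    0.14 um^-1 over a 9 um cilium this evaluates to exp(-1.26) = 0.284.
    """
    if hazard_per_um < 0 or distance_um < 0:
        raise ValueError("hazard and distance must be non-negative")
    return float(np.exp(-hazard_per_um * distance_um))


def run_length_from_hazard(hazard_per_um: float) -> float:
    """Mean free path 1/P (um) of the exponential-distance switching model."""
    if hazard_per_um < 0:
        raise ValueError("hazard must be non-negative")
    if hazard_per_um == 0:
        return float("inf")
    return 1.0 / hazard_per_um
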