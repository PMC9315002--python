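"""Egg meridian geometry.

An egg is modelled as a surface of revolution about its long axis. The
meridian is the curve ``r(z)`` for ``z`` in ``[0, B]`` (``B`` = egg length,
pole to pole) with ``r(0) = r(B) = 0`` and ``max r = A/2`` (``A`` = egg
breadth). Profiles come either from a two-parameter egg-shape polynomial
(ellipticity, asymmetry) or from a tabulated ``(z, r)`` table, e.g. one
digitised from an egg photograph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import simpson

__all__ = ["EggProfile", "build_profile", "profile_volume"]

#: admissible range for the shape parameters of :func:`build_profile`
MAX_SHAPE_PARAM = 0.5


@dataclass(frozen=True)
class EggProfile:
    """Meridian of an egg-shaped surface of revolution.

    Attributes
    ----------
    length : float
        Pole-to-pole length ``B`` along the axis of revolution (m).
    breadth : float
        Maximum diameter ``A`` perpendicular to the axis (m).
    z, r : ndarray
        Dense meridian samples, ``z`` strictly increasing from 0 to
        ``length``, ``r >= 0`` with ``r[0] = r[-1] = 0``.
    ellipticity, asymmetry : float or None
        Shape-polynomial parameters when the profile was built
        parametrically; ``None`` for tabulated profiles.
    """

    length: float
    breadth: float
    z: np.ndarray = field(repr=False)
    r: np.ndarray = field(repr=False)
    ellipticity: float | None = None
    asymmetry: float | None = None

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        r = np.asarray(self.r, dtype=float)
        if z.ndim != 1 or z.shape != r.shape or z.size < 5:
            raise ValueError("profile needs matching 1-d z and r arrays (>= 5 points)")
        if np.any(np.diff(z) <= 0):
            raise ValueError("z must be strictly increasing")
        if r[0] != 0.0 or r[-1] != 0.0:
            raise ValueError("meridian must close at both poles (r(0) = r(B) = 0)")
        if np.any(r < 0):
            raise ValueError("negative meridian radius")
        if not np.isclose(r.max(), self.breadth / 2, rtol=1e-6):
            raise ValueError("max r must equal breadth / 2")
        if not (self.length > 0 and self.breadth > 0):
            raise ValueError("length and breadth must be positive")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "r", r)

    @classmethod
    def from_table(cls, z: np.ndarray, r: np.ndarray) -> "EggProfile":
        """Build a profile from a tabulated ``(z, r)`` meridian."""
        z = np.asarray(z, dtype=float)
        r = np.asarray(r, dtype=float)
        return cls(length=float(z[-1] - z[0]), breadth=float(2 * r.max()),
                   z=z - z[0], r=r)

    def radius_at(self, z: np.ndarray) -> np.ndarray:
        """Interpolate the meridian radius at axial positions ``z``."""
        return np.interp(np.asarray(z, dtype=float), self.z, self.r)

    def arc_length(self) -> np.ndarray:
        """Cumulative meridian arc length at each stored sample."""
        ds = np.hypot(np.diff(self.z), np.diff(self.r))
        return np.concatenate([[0.0], np.cumsum(ds)])


def build_profile(breadth: float, length: float, ellipticity: float = 0.0,
                  asymmetry: float = 0.0, n_samples: int = 2001) -> EggProfile:
    """Construct an egg meridian from breadth, length and two shape parameters.

    The raw shape is ``sqrt(1 - x^2) * (1 + asymmetry*x + ellipticity*x^2)``
    with ``x = 2 z / B - 1``, rescaled radially so the maximum radius equals
    ``A/2``. ``ellipticity = asymmetry = 0`` gives a prolate spheroid with
    semi-axes ``A/2`` and ``B/2`` (a sphere when ``A == B``); positive
    asymmetry makes the ``z = B`` end blunter than the ``z = 0`` end.

    Samples are cosine-spaced in ``x`` so the polyline is well resolved at
    the poles, where ``dr/dz`` diverges.
    """
    if breadth <= 0 or length <= 0:
        raise ValueError("breadth and length must be positive")
    if abs(ellipticity) > MAX_SHAPE_PARAM or abs(asymmetry) > MAX_SHAPE_PARAM:
        raise ValueError(f"|ellipticity|, |asymmetry| must be <= {MAX_SHAPE_PARAM}")
    theta = np.linspace(0.0, np.pi, n_samples)
    x = -np.cos(theta)
    shape = 1.0 + asymmetry * x + ellipticity * x ** 2
    if np.any(shape <= 0):
        raise ValueError("shape parameters produce non-positive radii")
    raw = np.sqrt(np.clip(1.0 - x ** 2, 0.0, None)) * shape
    r = (breadth / 2) * raw / raw.max()
    z = (x + 1.0) * length / 2
    return EggProfile(length=length, breadth=breadth, z=z, r=r,
                      ellipticity=ellipticity, asymmetry=asymmetry)


def profile_volume(profile: EggProfile) -> float:
    """Enclosed volume ``pi * integral r(z)^2 dz`` (m^3) by quadrature."""
    return float(np.pi * simpson(profile.r ** 2, x=profile.z))
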