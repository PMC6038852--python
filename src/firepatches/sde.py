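"""Standard deviation ellipse (SDE) of a patch's pixel coordinates.

The SDE is the classical centrographic summary of a point set: centred on
the coordinate mean, oriented along the principal axes of the 2x2
coordinate covariance, with half-axes proportional to the directional
standard deviations. Conventions differ between implementations by scale
factors; here the half-axes are sqrt(2) times the eigen-standard-deviations
of the covariance computed with an (n - 2) denominator, the documented
default of the centrographic package this mirrors. For roughly convex
patches the resulting ellipse covers about two thirds of the pixels.

The fit is done twice: on raw lon/lat degrees, and in a per-patch local
flat (equirectangular) projection in kilometres, from which the ellipse
ratio R = sigma_minor/sigma_major and eccentricity
E = sqrt(1 - (minor/major)^2) are derived (so R^2 + E^2 = 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

KM_PER_DEG_LON_EQ = 111.320  # at the equator, scaled by cos(lat)
KM_PER_DEG_LAT = 110.574

_DEGENERATE_EPS = 1e-12


@dataclass
class EllipseFit:
    """SDE parameters of one patch.

    ``sigma_x*`` is the small half-axis and ``sigma_y*`` the big one
    (catalogue convention); ``theta*`` is the azimuth of the major axis
    measured clockwise from north, folded to [0, 180). ``degenerate`` is
    set when the points are (near-)collinear, in which case ``r_sde`` is
    reported as 0.
    """

    x_deg: float
    y_deg: float
    sigma_x_deg: float
    sigma_y_deg: float
    theta_deg: float
    sigma_x_km: float
    sigma_y_km: float
    theta_km_deg: float
    r_sde: float
    e_sde: float
    n_points: int
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "sigma_x_deg": self.sigma_x_deg,
            "sigma_y_deg": self.sigma_y_deg,
            "theta_deg": self.theta_deg,
            "sigma_x_km": self.sigma_x_km,
            "sigma_y_km": self.sigma_y_km,
            "theta_km_deg": self.theta_km_deg,
            "r_sde": self.r_sde,
            "e_sde": self.e_sde,
        }


def ellipse_ratio(sigma_a: float, sigma_b: float) -> float:
    """R = minor/major half-axis ratio, in (0, 1]."""
    lo, hi = sorted((abs(sigma_a), abs(sigma_b)))
    if hi == 0:
        return float("nan")
    return lo / hi


def ellipse_eccentricity(sigma_a: float, sigma_b: float) -> float:
    """E = sqrt(1 - (minor/major)^2); satisfies R^2 + E^2 = 1."""
    r = ellipse_ratio(sigma_a, sigma_b)
    return math.sqrt(max(0.0, 1.0 - r * r))


def _axes_and_theta(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Half-axes (small, big) and major-axis azimuth from north, [0, 180).

    x is the eastward coordinate, y the northward one, already centred.
    Covariance uses an (n - 2) denominator; half-axes are sqrt(2) times
    the eigen-standard-deviations.
    """
    n = len(x)
    cov = np.array(
        [
            [np.dot(x, x), np.dot(x, y)],
            [np.dot(x, y), np.dot(y, y)],
        ]
    ) / (n - 2)
    eigvals, eigvecs = np.linalg.eigh(cov)
    eigvals = np.clip(eigvals, 0.0, None)
    small, big = np.sqrt(2.0 * eigvals)
    vx, vy = eigvecs[:, 1]  # major-axis direction (east, north components)
    theta = math.degrees(math.atan2(vx, vy)) % 180.0
    return float(small), float(big), theta


def fit_sde(lons, lats) -> EllipseFit:
    """Fit the standard deviation ellipse to pixel-centre coordinates.

    Needs at least 3 points; fewer return a missing (NaN) fit. Collinear
    point sets give a zero small half-axis, R reported as 0 and the
    ``degenerate`` flag set.
    """
    lons = np.asarray(lons, dtype=float).ravel()
    lats = np.asarray(lats, dtype=float).ravel()
    if lons.shape != lats.shape:
        raise ValueError("lons and lats must have the same length")
    n = len(lons)
    x0, y0 = float(np.mean(lons)), float(np.mean(lats))
    if n < 3:
        nan = float("nan")
        return EllipseFit(x0, y0, nan, nan, nan, nan, nan, nan, nan, nan,
                          n_points=n, degenerate=True)

    sx_deg, sy_deg, theta = _axes_and_theta(lons - x0, lats - y0)

    # per-patch equirectangular projection about the centre
    xk = (lons - x0) * KM_PER_DEG_LON_EQ * math.cos(math.radians(y0))
    yk = (lats - y0) * KM_PER_DEG_LAT
    sx_km, sy_km, theta_km = _axes_and_theta(xk, yk)

    degenerate = sx_km * sx_km <= _DEGENERATE_EPS * max(sy_km * sy_km, 1.0)
    if degenerate:
        r = 0.0
        e = 1.0 if sy_km > 0 else float("nan")
    else:
        r = ellipse_ratio(sx_km, sy_km)
        e = ellipse_eccentricity(sx_km, sy_km)
    return EllipseFit(
        x_deg=x0,
        y_deg=y0,
        sigma_x_deg=sx_deg,
        sigma_y_deg=sy_deg,
        theta_deg=theta,
        sigma_x_km=sx_km,
        sigma_y_km=sy_km,
        theta_km_deg=theta_km,
        r_sde=r,
        e_sde=e,
        n_points=n,
        degenerate=bool(degenerate),
    )
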