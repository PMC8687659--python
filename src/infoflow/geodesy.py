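"""WGS84 geodesics and a local azimuthal-equidistant projection.

Flight tracks are logged in geographic coordinates but every analysis step
(rotation encoding, inter-bird distances, route efficiency) needs planar
metres.  We project about a fixed origin — conventionally the home loft —
with an azimuthal-equidistant mapping: a point at geodesic distance ``s``
and forward azimuth ``alpha`` from the origin maps to
``(x, y) = (s sin alpha, s cos alpha)`` so x points east and y north, and
distances measured from the origin are exact by construction.  Distances
between arbitrary nearby points are preserved to well under 0.1 % at the
<50 km scale of a homing release.

Geodesic distance/azimuth use Vincenty's inverse and direct formulae on the
WGS84 ellipsoid (millimetre-level at these ranges; the iteration cannot hit
its antipodal failure mode on a homing-flight scale).
"""

from __future__ import annotations

import math

import numpy as np

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_B = _A * (1.0 - _F)


def geodesic_inverse(lat1: float, lon1: float, lat2: float, lon2: float,
                     tol: float = 1e-12, max_iter: int = 200) -> tuple[float, float]:
    """Vincenty inverse problem.

    Returns ``(distance_m, forward_azimuth_rad)`` from point 1 to point 2;
    azimuth is clockwise from north.
    """
    if abs(lat1) > 90 or abs(lat2) > 90:
        raise ValueError("latitude outside [-90, 90]")
    if abs(lon1) > 180 or abs(lon2) > 180:
        raise ValueError("longitude outside [-180, 180]")
    if lat1 == lat2 and lon1 == lon2:
        return 0.0, 0.0
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    L = math.radians(lon2 - lon1)
    U1 = math.atan((1 - _F) * math.tan(phi1))
    U2 = math.atan((1 - _F) * math.tan(phi2))
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sinU2, cosU2 = math.sin(U2), math.cos(U2)

    lam = L
    for _ in range(max_iter):
        sin_lam, cos_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(cosU2 * sin_lam,
                               cosU1 * sinU2 - sinU1 * cosU2 * cos_lam)
        if sin_sigma == 0.0:
            return 0.0, 0.0
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha * sin_alpha
        if cos2_alpha == 0.0:  # equatorial line
            cos_2sigma_m = 0.0
        else:
            cos_2sigma_m = cos_sigma - 2.0 * sinU1 * sinU2 / cos2_alpha
        C = _F / 16.0 * cos2_alpha * (4.0 + _F * (4.0 - 3.0 * cos2_alpha))
        lam_new = L + (1.0 - C) * _F * sin_alpha * (
            sigma + C * sin_sigma * (
                cos_2sigma_m + C * cos_sigma * (-1.0 + 2.0 * cos_2sigma_m ** 2)))
        if abs(lam_new - lam) < tol:
            lam = lam_new
            break
        lam = lam_new

    sin_lam, cos_lam = math.sin(lam), math.cos(lam)
    sin_sigma = math.hypot(cosU2 * sin_lam, cosU1 * sinU2 - sinU1 * cosU2 * cos_lam)
    cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
    sigma = math.atan2(sin_sigma, cos_sigma)
    sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
    cos2_alpha = 1.0 - sin_alpha * sin_alpha
    cos_2sigma_m = 0.0 if cos2_alpha == 0.0 else cos_sigma - 2.0 * sinU1 * sinU2 / cos2_alpha
    u2 = cos2_alpha * (_A * _A - _B * _B) / (_B * _B)
    A_ = 1 + u2 / 16384 * (4096 + u2 * (-768 + u2 * (320 - 175 * u2)))
    B_ = u2 / 1024 * (256 + u2 * (-128 + u2 * (74 - 47 * u2)))
    delta_sigma = B_ * sin_sigma * (
        cos_2sigma_m + B_ / 4 * (
            cos_sigma * (-1 + 2 * cos_2sigma_m ** 2)
            - B_ / 6 * cos_2sigma_m * (-3 + 4 * sin_sigma ** 2)
            * (-3 + 4 * cos_2sigma_m ** 2)))
    s = _B * A_ * (sigma - delta_sigma)
    alpha1 = math.atan2(cosU2 * sin_lam, cosU1 * sinU2 - sinU1 * cosU2 * cos_lam)
    return s, alpha1


def geodesic_direct(lat1: float, lon1: float, azimuth_rad: float, distance_m: float,
                    tol: float = 1e-12, max_iter: int = 200) -> tuple[float, float]:
    """Vincenty direct problem: destination ``(lat, lon)`` in degrees."""
    if distance_m == 0.0:
        return lat1, lon1
    phi1 = math.radians(lat1)
    U1 = math.atan((1 - _F) * math.tan(phi1))
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sin_a1, cos_a1 = math.sin(azimuth_rad), math.cos(azimuth_rad)
    sigma1 = math.atan2(math.tan(U1), cos_a1)
    sin_alpha = cosU1 * sin_a1
    cos2_alpha = 1 - sin_alpha ** 2
    u2 = cos2_alpha * (_A * _A - _B * _B) / (_B * _B)
    A_ = 1 + u2 / 16384 * (4096 + u2 * (-768 + u2 * (320 - 175 * u2)))
    B_ = u2 / 1024 * (256 + u2 * (-128 + u2 * (74 - 47 * u2)))
    sigma = distance_m / (_B * A_)
    for _ in range(max_iter):
        cos_2sigma_m = math.cos(2 * sigma1 + sigma)
        sin_sigma, cos_sigma = math.sin(sigma), math.cos(sigma)
        delta_sigma = B_ * sin_sigma * (
            cos_2sigma_m + B_ / 4 * (
                cos_sigma * (-1 + 2 * cos_2sigma_m ** 2)
                - B_ / 6 * cos_2sigma_m * (-3 + 4 * sin_sigma ** 2)
                * (-3 + 4 * cos_2sigma_m ** 2)))
        sigma_new = distance_m / (_B * A_) + delta_sigma
        if abs(sigma_new - sigma) < tol:
            sigma = sigma_new
            break
        sigma = sigma_new
    sin_sigma, cos_sigma = math.sin(sigma), math.cos(sigma)
    cos_2sigma_m = math.cos(2 * sigma1 + sigma)
    phi2 = math.atan2(
        sinU1 * cos_sigma + cosU1 * sin_sigma * cos_a1,
        (1 - _F) * math.hypot(sin_alpha,
                              sinU1 * sin_sigma - cosU1 * cos_sigma * cos_a1))
    lam = math.atan2(sin_sigma * sin_a1,
                     cosU1 * cos_sigma - sinU1 * sin_sigma * cos_a1)
    C = _F / 16 * cos2_alpha * (4 + _F * (4 - 3 * cos2_alpha))
    L = lam - (1 - C) * _F * sin_alpha * (
        sigma + C * sin_sigma * (
            cos_2sigma_m + C * cos_sigma * (-1 + 2 * cos_2sigma_m ** 2)))
    lon2 = lon1 + math.degrees(L)
    return math.degrees(phi2), lon2


def project_to_plane(lat, lon, origin: tuple[float, float]) -> np.ndarray:
    """Azimuthal-equidistant projection about ``origin=(lat0, lon0)``.

    Accepts scalars or arrays; returns an ``(n, 2)`` array of planar metres
    (x east, y north).
    """
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    if lat.shape != lon.shape:
        raise ValueError("lat and lon must have the same shape")
    lat0, lon0 = origin
    out = np.empty((lat.size, 2), dtype=float)
    for i, (la, lo) in enumerate(zip(lat.ravel(), lon.ravel())):
        s, az = geodesic_inverse(lat0, lon0, la, lo)
        out[i, 0] = s * math.sin(az)
        out[i, 1] = s * math.cos(az)
    return out


def unproject_from_plane(xy: np.ndarray, origin: tuple[float, float]) -> np.ndarray:
    """Inverse of :func:`project_to_plane`; returns ``(n, 2)`` of (lat, lon)."""
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    lat0, lon0 = origin
    out = np.empty_like(xy)
    for i, (x, y) in enumerate(xy):
        s = math.hypot(x, y)
        az = math.atan2(x, y)
        out[i] = geodesic_direct(lat0, lon0, az, s)
    return out
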