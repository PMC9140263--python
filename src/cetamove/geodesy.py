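"""WGS84 geodesic computations and the azimuthal equidistant projection.

Distances between whale relocations span ~50 degrees of latitude, so planar
approximations are not acceptable for speed estimation.  All distances here are
ellipsoidal (WGS84) via Vincenty's inverse/direct formulae, which are accurate
to well below a millimetre for non-antipodal point pairs.  The azimuthal
equidistant projection is built directly on the geodesic: a point at geodesic
distance d and azimuth a from the projection centre maps to
(x, y) = (d sin a, d cos a), which preserves distance from the centre exactly.
"""

from __future__ import annotations

import numpy as np

WGS84_A = 6378137.0
WGS84_F = 1.0 / 298.257223563
WGS84_B = WGS84_A * (1.0 - WGS84_F)

_MAX_ITER = 200
_TOL = 1e-12


class ProjectionError(ValueError):
    """Raised for geodesically degenerate inputs (e.g. antipodal points)."""


def geodesic_inverse(lon1, lat1, lon2, lat2):
    """Vincenty inverse problem on WGS84.

    Parameters are decimal degrees.  Returns ``(distance_m, azimuth_deg)``
    where the azimuth is the initial bearing at point 1, clockwise from north.

    Raises
    ------
    ProjectionError
        If the iteration fails to converge (nearly antipodal points).
    """
    if lon1 == lon2 and lat1 == lat2:
        return 0.0, 0.0
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    L = np.radians(lon2 - lon1)
    U1 = np.arctan((1 - WGS84_F) * np.tan(phi1))
    U2 = np.arctan((1 - WGS84_F) * np.tan(phi2))
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)

    lam = L
    for _ in range(_MAX_ITER):
        sin_lam, cos_lam = np.sin(lam), np.cos(lam)
        sin_sigma = np.hypot(cosU2 * sin_lam, cosU1 * sinU2 - sinU1 * cosU2 * cos_lam)
        if sin_sigma == 0.0:
            return 0.0, 0.0  # coincident
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = np.arctan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha**2
        if cos2_alpha == 0.0:  # equatorial line
            cos_2sigma_m = 0.0
        else:
            cos_2sigma_m = cos_sigma - 2.0 * sinU1 * sinU2 / cos2_alpha
        C = WGS84_F / 16.0 * cos2_alpha * (4 + WGS84_F * (4 - 3 * cos2_alpha))
        lam_prev = lam
        lam = L + (1 - C) * WGS84_F * sin_alpha * (
            sigma
            + C * sin_sigma * (cos_2sigma_m + C * cos_sigma * (-1 + 2 * cos_2sigma_m**2))
        )
        if abs(lam - lam_prev) < _TOL:
            break
    else:
        raise ProjectionError(
            "geodesic inverse failed to converge (points may be nearly antipodal)"
        )

    u2 = cos2_alpha * (WGS84_A**2 - WGS84_B**2) / WGS84_B**2
    A = 1 + u2 / 16384 * (4096 + u2 * (-768 + u2 * (320 - 175 * u2)))
    B = u2 / 1024 * (256 + u2 * (-128 + u2 * (74 - 47 * u2)))
    delta_sigma = B * sin_sigma * (
        cos_2sigma_m
        + B / 4 * (
            cos_sigma * (-1 + 2 * cos_2sigma_m**2)
            - B / 6 * cos_2sigma_m * (-3 + 4 * sin_sigma**2) * (-3 + 4 * cos_2sigma_m**2)
        )
    )
    s = WGS84_B * A * (sigma - delta_sigma)
    az = np.degrees(
        np.arctan2(cosU2 * np.sin(lam), cosU1 * sinU2 - sinU1 * cosU2 * np.cos(lam))
    )
    return float(s), float(az % 360.0)


def geodesic_direct(lon1, lat1, azimuth_deg, distance_m):
    """Vincenty direct problem: destination from start, bearing and distance."""
    if distance_m == 0.0:
        return float(lon1), float(lat1)
    phi1 = np.radians(lat1)
    alpha1 = np.radians(azimuth_deg)
    sin_a1, cos_a1 = np.sin(alpha1), np.cos(alpha1)

    tanU1 = (1 - WGS84_F) * np.tan(phi1)
    cosU1 = 1.0 / np.hypot(1.0, tanU1)
    sinU1 = tanU1 * cosU1
    sigma1 = np.arctan2(tanU1, cos_a1)
    sin_alpha = cosU1 * sin_a1
    cos2_alpha = 1 - sin_alpha**2
    u2 = cos2_alpha * (WGS84_A**2 - WGS84_B**2) / WGS84_B**2
    A = 1 + u2 / 16384 * (4096 + u2 * (-768 + u2 * (320 - 175 * u2)))
    B = u2 / 1024 * (256 + u2 * (-128 + u2 * (74 - 47 * u2)))

    sigma = distance_m / (WGS84_B * A)
    for _ in range(_MAX_ITER):
        cos_2sigma_m = np.cos(2 * sigma1 + sigma)
        sin_sigma, cos_sigma = np.sin(sigma), np.cos(sigma)
        delta_sigma = B * sin_sigma * (
            cos_2sigma_m
            + B / 4 * (
                cos_sigma * (-1 + 2 * cos_2sigma_m**2)
                - B / 6 * cos_2sigma_m * (-3 + 4 * sin_sigma**2) * (-3 + 4 * cos_2sigma_m**2)
            )
        )
        sigma_prev = sigma
        sigma = distance_m / (WGS84_B * A) + delta_sigma
        if abs(sigma - sigma_prev) < _TOL:
            break

    sin_sigma, cos_sigma = np.sin(sigma), np.cos(sigma)
    cos_2sigma_m = np.cos(2 * sigma1 + sigma)
    phi2 = np.arctan2(
        sinU1 * cos_sigma + cosU1 * sin_sigma * cos_a1,
        (1 - WGS84_F) * np.hypot(sin_alpha, sinU1 * sin_sigma - cosU1 * cos_sigma * cos_a1),
    )
    lam = np.arctan2(sin_sigma * sin_a1, cosU1 * cos_sigma - sinU1 * sin_sigma * cos_a1)
    C = WGS84_F / 16 * cos2_alpha * (4 + WGS84_F * (4 - 3 * cos2_alpha))
    L = lam - (1 - C) * WGS84_F * sin_alpha * (
        sigma
        + C * sin_sigma * (cos_2sigma_m + C * cos_sigma * (-1 + 2 * cos_2sigma_m**2))
    )
    lon2 = (np.degrees(np.radians(lon1) + L) + 540.0) % 360.0 - 180.0
    return float(lon2), float(np.degrees(phi2))


def geodesic_distance(p1, p2) -> float:
    """Ellipsoidal distance in metres between two ``(lon, lat)`` points."""
    return geodesic_inverse(p1[0], p1[1], p2[0], p2[1])[0]


def cumulative_distance(lons, lats) -> np.ndarray:
    """Cumulative along-track geodesic distance (m), first element 0."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    d = np.zeros(len(lons))
    for i in range(1, len(lons)):
        d[i] = d[i - 1] + geodesic_inverse(lons[i - 1], lats[i - 1], lons[i], lats[i])[0]
    return d


class AzimuthalEquidistant:
    """Azimuthal equidistant projection about a centre ``(lon0, lat0)``.

    Forward maps lon/lat to planar metres with true geodesic distance (and
    azimuth) from the centre; inverse recovers lon/lat via the direct geodesic.
    """

    def __init__(self, lon0: float, lat0: float):
        if not (np.isfinite(lon0) and np.isfinite(lat0)):
            raise ProjectionError("projection centre must be finite")
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)

    def forward(self, lon, lat):
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        x = np.empty_like(lon)
        y = np.empty_like(lon)
        for i in range(lon.size):
            d, az = geodesic_inverse(self.lon0, self.lat0, lon[i], lat[i])
            a = np.radians(az)
            x[i] = d * np.sin(a)
            y[i] = d * np.cos(a)
        if x.size == 1:
            return float(x[0]), float(y[0])
        return x, y

    def inverse(self, x, y):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        lon = np.empty_like(x)
        lat = np.empty_like(x)
        for i in range(x.size):
            d = float(np.hypot(x[i], y[i]))
            az = float(np.degrees(np.arctan2(x[i], y[i])))
            lon[i], lat[i] = geodesic_direct(self.lon0, self.lat0, az, d)
        if lon.size == 1:
            return float(lon[0]), float(lat[0])
        return lon, lat
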