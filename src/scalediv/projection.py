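"""Equal-area map projection used for gridding and route coordinates.

A Lambert cylindrical equal-area projection on a spherical Earth: squares of
side ``s`` km in the projected plane all map to regions of identical area
``s**2`` km^2 on the sphere, which is the property the nested analysis grids
rely on.  Forward/inverse are closed form, so projected kilometre coordinates
and geographic (lon, lat) round-trip exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class EqualAreaProjection:
    """Lambert cylindrical equal-area projection.

    Parameters
    ----------
    central_lon : float
        Central meridian (degrees); maps to x = 0.
    standard_lat : float
        Standard parallel (degrees); controls the x/y aspect but not the
        equal-area property.
    """

    central_lon: float = -100.0
    standard_lat: float = 40.0

    def forward(self, lon, lat):
        """(lon, lat) degrees -> (x, y) km."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        cos_s = np.cos(np.deg2rad(self.standard_lat))
        x = EARTH_RADIUS_KM * np.deg2rad(lon - self.central_lon) * cos_s
        y = EARTH_RADIUS_KM * np.sin(np.deg2rad(lat)) / cos_s
        return x, y

    def inverse(self, x, y):
        """(x, y) km -> (lon, lat) degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        cos_s = np.cos(np.deg2rad(self.standard_lat))
        lon = np.rad2deg(x / (EARTH_RADIUS_KM * cos_s)) + self.central_lon
        lat = np.rad2deg(np.arcsin(np.clip(y * cos_s / EARTH_RADIUS_KM, -1.0, 1.0)))
        return lon, lat


DEFAULT_PROJECTION = EqualAreaProjection()
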