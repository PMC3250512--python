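"""Alternative longitude encodings for the constraint table.

Treating latitude/longitude as Cartesian coordinates makes the tree
sensitive to where the longitude axis is cut; these schemes express the
choices compared in the sensitivity analysis.  Latitude is never re-encoded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .community import SiteRecord

__all__ = [
    "EncodingScheme",
    "SCHEMES",
    "get_scheme",
    "encode_longitude",
    "decode_longitude",
    "build_constraints",
]


@dataclass(frozen=True)
class EncodingScheme:
    """A named placement of the longitude axis origin.

    ``origin_deg`` is the standard longitude at which the encoded axis has
    its 0; ``wrap360`` selects a [0, 360) range instead of [-180, 180).
    """

    name: str
    origin_deg: float
    wrap360: bool


SCHEMES: dict[str, EncodingScheme] = {
    "greenwich_pm180": EncodingScheme("greenwich_pm180", 0.0, wrap360=False),
    "east_of_greenwich": EncodingScheme("east_of_greenwich", 0.0, wrap360=True),
    "east_of_60W": EncodingScheme("east_of_60W", -60.0, wrap360=True),
}


def get_scheme(name: str | EncodingScheme) -> EncodingScheme:
    if isinstance(name, EncodingScheme):
        return name
    try:
        return SCHEMES[name]
    except KeyError:
        raise ValueError(
            f"unknown encoding scheme {name!r}; choose from {sorted(SCHEMES)}"
        ) from None


def encode_longitude(longitude_deg, scheme: str | EncodingScheme = "greenwich_pm180"):
    """Map standard longitude in [-180, 180) onto the scheme's axis.

    The mapping is a bijection on the circle: [-180, 180) for
    ``greenwich_pm180``, [0, 360) measured east of the origin otherwise.
    Accepts scalars or arrays.
    """
    scheme = get_scheme(scheme)
    lon = np.asarray(longitude_deg, dtype=float)
    if np.any(lon < -180.0) or np.any(lon >= 180.0):
        raise ValueError("longitude outside [-180, 180)")
    if scheme.wrap360:
        out = np.mod(lon - scheme.origin_deg, 360.0)
    else:
        out = np.mod(lon - scheme.origin_deg + 180.0, 360.0) - 180.0
    return out if out.ndim else float(out)


def decode_longitude(encoded, scheme: str | EncodingScheme):
    """Inverse of :func:`encode_longitude`, back to [-180, 180)."""
    scheme = get_scheme(scheme)
    val = np.asarray(encoded, dtype=float)
    out = np.mod(val + scheme.origin_deg + 180.0, 360.0) - 180.0
    return out if out.ndim else float(out)


def build_constraints(
    sites: Sequence[SiteRecord], scheme: str | EncodingScheme = "greenwich_pm180"
) -> pd.DataFrame:
    """Site x 2 table of (latitude_deg, encoded longitude), in site order."""
    scheme = get_scheme(scheme)
    for s in sites:
        if s.latitude_deg is None or s.longitude_deg is None:
            raise ValueError(f"site {s.site_id!r} is missing coordinates")
    lons = np.array([s.longitude_deg for s in sites], dtype=float)
    return pd.DataFrame(
        {
            "latitude_deg": [s.latitude_deg for s in sites],
            "longitude_encoded": encode_longitude(lons, scheme)
            if len(sites)
            else np.array([], dtype=float),
        },
        index=[s.site_id for s in sites],
    )
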