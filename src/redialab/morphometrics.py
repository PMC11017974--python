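"""Derived morphometric quantities for rediae.

Body volume treats the redia as a cylinder of the measured length and width;
pharynx volume treats the pharynx as a sphere of the measured diameter.
Relative pharynx volume (pharynx volume / body volume) is the key
division-of-labor morphometric: soldier-like small rediae are expected to
carry disproportionately large pharynges.  Standard linear size (SLS) is the
cube root of body volume, a linearised size measure.
"""

from __future__ import annotations

import math

from .datamodel import Colony, RediaRecord

__all__ = [
    "body_volume",
    "pharynx_volume",
    "relative_pharynx",
    "standard_linear_size",
    "enrich_record",
    "enrich_colony",
]


def body_volume(length_um: float, width_um: float) -> float:
    """Cylindrical body volume pi * (w/2)^2 * L in um^3."""
    if not (length_um > 0 and width_um > 0):
        raise ValueError("length_um and width_um must be positive")
    return math.pi * (width_um / 2.0) ** 2 * length_um


def pharynx_volume(pharynx_um: float) -> float:
    """Spherical pharynx volume (4/3) pi (d/2)^3 in um^3."""
    if not pharynx_um > 0:
        raise ValueError("pharynx_um must be positive")
    return (4.0 / 3.0) * math.pi * (pharynx_um / 2.0) ** 3


def relative_pharynx(pharynx_volume_um3: float, body_volume_um3: float) -> float:
    """Dimensionless ratio of pharynx volume to body volume.

    Ratios above 1 are geometrically implausible (the pharynx cannot exceed
    the body) but are returned as-is; callers flag them on the record.
    """
    if not body_volume_um3 > 0:
        raise ValueError("body_volume_um3 must be positive")
    if pharynx_volume_um3 < 0:
        raise ValueError("pharynx_volume_um3 must be nonnegative")
    return pharynx_volume_um3 / body_volume_um3


def standard_linear_size(body_volume_um3: float) -> float:
    """SLS = cube root of body volume (proportionality constant 1)."""
    if not body_volume_um3 > 0:
        raise ValueError("body_volume_um3 must be positive")
    return body_volume_um3 ** (1.0 / 3.0)


def enrich_record(record: RediaRecord) -> RediaRecord:
    """Fill the derived fields of a record in place and return it."""
    if record.length_um is not None and record.width_um is not None:
        record.body_volume_um3 = body_volume(record.length_um, record.width_um)
        record.sls_um = standard_linear_size(record.body_volume_um3)
    if record.pharynx_um is not None:
        record.pharynx_volume_um3 = pharynx_volume(record.pharynx_um)
        if record.body_volume_um3 is not None:
            record.relative_pharynx = relative_pharynx(
                record.pharynx_volume_um3, record.body_volume_um3
            )
            record.implausible_pharynx = record.relative_pharynx > 1.0
    return record


def enrich_colony(colony: Colony) -> Colony:
    for r in colony.records:
        enrich_record(r)
    return colony
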