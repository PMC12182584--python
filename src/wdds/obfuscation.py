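"""Coordinate obfuscation for sensitive records.

Sharing precise coordinates of, e.g., a bat roost where viruses were
detected can put animals and people at risk.  Two documented,
reproducible generalizations are provided: decimal truncation and
uniform-disk jitter.  Both propagate the information loss into the
spatial-uncertainty field (which the standard defines to cover exactly
such systematic alterations) and append an entry to the dataset's
provenance log, so the obfuscation is documented rather than silent.

Conventions: truncation is toward zero, so published values never imply
precision beyond the retained decimals; jitter uses an equirectangular
local approximation, valid away from the poles; one degree of latitude is
taken as 111,320 m.
"""

from __future__ import annotations

import copy
import math
from decimal import ROUND_DOWN, Decimal

import numpy as np

from .io import Dataset, ProvenanceEntry
from .report import ValidationIssue

__all__ = ["truncate_coordinates", "jitter_coordinates", "displacement_m",
           "truncation_uncertainty_m", "has_obfuscation_provenance"]

#: Meters per degree of latitude (spherical approximation).
M_PER_DEG = 111320.0
#: Earth mean radius for great-circle distances, meters.
EARTH_RADIUS_M = 6_371_000.0


def _trunc_toward_zero(value: float, decimals: int) -> float:
    # Decimal on the shortest repr avoids binary-float edge cases such as
    # trunc(0.29 * 100) == 28.
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_DOWN))


def truncation_uncertainty_m(decimals: int, latitude: float) -> float:
    """Half-cell diagonal, in meters, of the truncation grid at a given
    latitude: sqrt((d*M)^2 + (d*M*cos(lat))^2) with d = 0.5*10^-decimals."""
    delta = 0.5 * 10 ** (-decimals)
    north = delta * M_PER_DEG
    east = delta * M_PER_DEG * math.cos(math.radians(latitude))
    return math.hypot(north, east)


def _skip(rec, reason: str) -> ValidationIssue:
    return ValidationIssue(rule_id="FIELD_TYPE", severity="warning",
                           record=rec.source_row, field="latitude",
                           message=reason)


def truncate_coordinates(dataset: Dataset, decimals: int):
    """Truncate all coordinates toward zero to ``decimals`` decimals.

    Spatial uncertainty is raised to at least the half-cell diagonal of
    the truncation grid (it never decreases), and a provenance entry is
    appended.  Returns ``(new_dataset, findings)``; the input is not
    modified.
    """
    if not 0 <= int(decimals) <= 6:
        raise ValueError("decimals must be in [0, 6]")
    decimals = int(decimals)
    out = copy.deepcopy(dataset)
    findings = []
    n_changed = 0
    for rec in out.records:
        if not isinstance(rec.latitude, (int, float)) or \
                not isinstance(rec.longitude, (int, float)) or \
                isinstance(rec.latitude, bool) or \
                isinstance(rec.longitude, bool):
            findings.append(_skip(rec, "non-numeric or missing "
                                       "coordinates: record skipped"))
            continue
        rec.latitude = _trunc_toward_zero(float(rec.latitude), decimals)
        rec.longitude = _trunc_toward_zero(float(rec.longitude), decimals)
        unc = truncation_uncertainty_m(decimals, rec.latitude)
        rec.spatial_uncertainty = max(rec.spatial_uncertainty or 0.0, unc)
        n_changed += 1
    out.provenance.append(ProvenanceEntry.now(
        "truncate_coordinates",
        {"decimals": decimals, "records_affected": n_changed}))
    return out, findings


def jitter_coordinates(dataset: Dataset, radius_m: float, seed: int,
                       record_seed: bool = False):
    """Displace every record by a uniform draw on the disk of radius
    ``radius_m`` meters.

    The displacement is sampled as ``r = radius_m * sqrt(u)``, ``theta``
    uniform on [0, 2*pi), converted to degrees with the equirectangular
    local approximation.  Records within 0.1 degree of a pole are skipped
    (the longitude conversion degenerates there); longitudes are wrapped
    into (-180, 180].  Spatial uncertainty is raised to at least
    ``radius_m``.  The seed is a mandatory argument — identical seeds give
    identical outputs — and is recorded in provenance only when
    ``record_seed`` is true, so a data owner can keep it private while
    still documenting the method and radius.

    Returns ``(new_dataset, findings)``; the input is not modified.
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    if seed is None:
        raise ValueError("a seed is required; jitter must be reproducible")
    rng = np.random.default_rng(int(seed))
    out = copy.deepcopy(dataset)
    findings = []
    n_changed = 0
    for rec in out.records:
        if not isinstance(rec.latitude, (int, float)) or \
                not isinstance(rec.longitude, (int, float)) or \
                isinstance(rec.latitude, bool) or \
                isinstance(rec.longitude, bool):
            findings.append(_skip(rec, "non-numeric or missing "
                                       "coordinates: record skipped"))
            continue
        lat = float(rec.latitude)
        if abs(lat) > 89.9:
            findings.append(_skip(rec, f"latitude {lat!r} too close to a "
                                       f"pole: record skipped"))
            continue
        r = radius_m * math.sqrt(rng.random())
        theta = rng.uniform(0.0, 2.0 * math.pi)
        rec.latitude = lat + r * math.cos(theta) / M_PER_DEG
        lon = float(rec.longitude) + \
            r * math.sin(theta) / (M_PER_DEG * math.cos(math.radians(lat)))
        rec.longitude = ((lon + 180.0) % 360.0) - 180.0
        if rec.longitude == -180.0:
            rec.longitude = 180.0
        rec.spatial_uncertainty = max(rec.spatial_uncertainty or 0.0,
                                      float(radius_m))
        n_changed += 1
    params = {"radius_m": float(radius_m), "records_affected": n_changed,
              "seed": int(seed) if record_seed else "withheld"}
    out.provenance.append(ProvenanceEntry.now("jitter_coordinates", params))
    return out, findings


def displacement_m(a, b) -> float:
    """Haversine great-circle distance in meters between two points given
    as objects with ``latitude``/``longitude`` or as (lat, lon) pairs."""
    lat1, lon1 = _coords(a)
    lat2, lon2 = _coords(b)
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + \
        math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2.0 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(h)))


def _coords(p):
    if hasattr(p, "latitude"):
        return float(p.latitude), float(p.longitude)
    lat, lon = p
    return float(lat), float(lon)


def has_obfuscation_provenance(dataset: Dataset) -> bool:
    """True when the provenance log documents any coordinate obfuscation
    (used by the CLI's raw-coordinates assertion)."""
    return any(e.method in ("truncate_coordinates", "jitter_coordinates")
               for e in dataset.provenance)
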