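"""Standardised Cartesian and (hyper)spherical coordinates for lipid panels.

The three transformed lipid features — 1/HDLC (x), ln TG (y) and non-HDLC
(z) — are z-scored against population means and standard deviations,
bounded to ±z_bound, and shifted by +shift into the first (+,+,+) octant.
The resulting point is then expressed in spherical coordinates:

    r     = sqrt(x^2 + y^2 + z^2)      overall severity of dyslipidemia
    theta = arccos(z / r)              polar angle: tilt away from non-HDLC
    phi   = arctan(y / x)              azimuth: balance of ln TG vs 1/HDLC

Because all coordinates are non-negative, theta and phi both lie in
[0, 90] degrees. The transform generalises to n features through the
standard hyperspherical recursion.

Angle units matter: logistic-model coefficients trained on degrees are
meaningless applied to radians, so every angle-bearing object carries an
explicit unit tag and consumers check it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import DegenerateDistributionError, DomainError
from .lipid_model import CohortTable, LipidPanel

AngleUnit = Literal["degrees", "radians"]

DEFAULT_SHIFT = 5.0
DEFAULT_Z_BOUND = 5.0


@dataclass(frozen=True)
class StandardizationParams:
    """Population moments and octant-shift constants for the transform.

    Means/SDs are on the transformed scale (1/HDLC in dL/mg, ln TG in
    ln(mg/dL), non-HDLC in mg/dL). ``shift`` >= ``z_bound`` guarantees all
    shifted coordinates are non-negative.
    """

    mean_inv_h: float
    sd_inv_h: float
    mean_ln_tg: float
    sd_ln_tg: float
    mean_nhdlc: float
    sd_nhdlc: float
    shift: float = DEFAULT_SHIFT
    z_bound: float = DEFAULT_Z_BOUND

    def __post_init__(self) -> None:
        for name in ("sd_inv_h", "sd_ln_tg", "sd_nhdlc"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be positive")
        if not self.z_bound > 0:
            raise DomainError("z_bound must be positive")
        if self.shift < self.z_bound:
            raise DomainError(
                "shift must be >= z_bound so octant coordinates stay non-negative"
            )


@dataclass(frozen=True)
class CartesianPoint:
    """Shifted z-scores: x = 1/HDLC axis, y = ln TG axis, z = non-HDLC axis."""

    x: float
    y: float
    z: float
    clipped: bool = False


@dataclass(frozen=True)
class SphericalCoords:
    r: float
    theta: float
    phi: float
    angle_unit: AngleUnit = "degrees"
    degenerate: bool = False


def fit_standardization(
    cohort: CohortTable,
    shift: float = DEFAULT_SHIFT,
    z_bound: float = DEFAULT_Z_BOUND,
) -> StandardizationParams:
    """Estimate feature means and sample SDs (n-1 denominator) from a cohort."""
    if len(cohort) < 2:
        raise DomainError("standardization requires at least 2 records")
    arr = cohort.feature_array(["inv_h", "ln_tg", "nhdlc"])
    means = arr.mean(axis=0)
    sds = arr.std(axis=0, ddof=1)
    for j, name in enumerate(("inv_h", "ln_tg", "nhdlc")):
        if sds[j] == 0:
            raise DegenerateDistributionError(
                f"feature {name!r} is constant; cannot standardize"
            )
    return StandardizationParams(
        mean_inv_h=float(means[0]),
        sd_inv_h=float(sds[0]),
        mean_ln_tg=float(means[1]),
        sd_ln_tg=float(sds[1]),
        mean_nhdlc=float(means[2]),
        sd_nhdlc=float(sds[2]),
        shift=shift,
        z_bound=z_bound,
    )


TransformMode = Literal["training_filter", "scoring_clip"]


def transform_to_cartesian(
    panel: LipidPanel,
    params: StandardizationParams,
    mode: TransformMode = "scoring_clip",
) -> CartesianPoint | None:
    """Z-score, bound and octant-shift one panel.

    ``training_filter`` mode drops points with any |z| > z_bound (returns
    ``None``), matching how out-of-range rows are removed when developing
    a model. ``scoring_clip`` mode instead clips z to ±z_bound and flags
    the point, because a deployed score must be computable for every
    patient.
    """
    zs = np.array(
        [
            (panel.inv_h - params.mean_inv_h) / params.sd_inv_h,
            (panel.ln_tg - params.mean_ln_tg) / params.sd_ln_tg,
            (panel.nhdlc - params.mean_nhdlc) / params.sd_nhdlc,
        ]
    )
    out_of_range = bool(np.any(np.abs(zs) > params.z_bound))
    if mode == "training_filter":
        if out_of_range:
            return None
    elif mode == "scoring_clip":
        zs = np.clip(zs, -params.z_bound, params.z_bound)
    else:
        raise DomainError(f"unknown transform mode {mode!r}")
    x, y, z = zs + params.shift
    return CartesianPoint(x=x, y=y, z=z, clipped=out_of_range and mode == "scoring_clip")


def transform_cohort(
    cohort: CohortTable,
    params: StandardizationParams,
    mode: TransformMode = "scoring_clip",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised :func:`transform_to_cartesian` over a cohort.

    Returns ``(points, kept, clipped)``: an (m, 3) array of octant
    coordinates for the kept records, a boolean mask over the cohort of
    which records were kept, and a boolean clip flag per kept record (all
    False in training_filter mode).
    """
    arr = cohort.feature_array(["inv_h", "ln_tg", "nhdlc"])
    means = np.array([params.mean_inv_h, params.mean_ln_tg, params.mean_nhdlc])
    sds = np.array([params.sd_inv_h, params.sd_ln_tg, params.sd_nhdlc])
    zs = (arr - means) / sds
    out = np.any(np.abs(zs) > params.z_bound, axis=1)
    if mode == "training_filter":
        kept = ~out
        return zs[kept] + params.shift, kept, np.zeros(kept.sum(), dtype=bool)
    if mode == "scoring_clip":
        zs = np.clip(zs, -params.z_bound, params.z_bound)
        kept = np.ones(len(zs), dtype=bool)
        return zs + params.shift, kept, out
    raise DomainError(f"unknown transform mode {mode!r}")


def _to_unit(angle_rad: float, unit: AngleUnit) -> float:
    if unit == "degrees":
        return math.degrees(angle_rad)
    if unit == "radians":
        return angle_rad
    raise DomainError(f"unknown angle unit {unit!r}")


def cartesian_to_spherical(
    point: CartesianPoint | tuple[float, float, float],
    angle_unit: AngleUnit = "degrees",
) -> SphericalCoords:
    """Convert a first-octant Cartesian point to (r, theta, phi).

    theta = arccos(z/r) is the polar angle from the +z (non-HDLC) axis;
    phi = atan2(y, x) is the azimuth in the x-y plane (equal to
    arctan(y/x) for x > 0 and 90 deg for x = 0, y > 0). The origin has no
    defined angles: r = 0 returns theta = phi = 0 with ``degenerate=True``.
    """
    if isinstance(point, CartesianPoint):
        x, y, z = point.x, point.y, point.z
    else:
        x, y, z = point
    if x < 0 or y < 0 or z < 0:
        raise DomainError(f"coordinates must be non-negative, got {(x, y, z)}")
    r = math.sqrt(x * x + y * y + z * z)
    if r == 0.0:
        return SphericalCoords(0.0, 0.0, 0.0, angle_unit, degenerate=True)
    theta = math.acos(min(1.0, max(-1.0, z / r)))
    phi = math.atan2(y, x)
    return SphericalCoords(
        r, _to_unit(theta, angle_unit), _to_unit(phi, angle_unit), angle_unit
    )


def spherical_to_cartesian(coords: SphericalCoords) -> tuple[float, float, float]:
    """Inverse of :func:`cartesian_to_spherical`."""
    theta, phi = coords.theta, coords.phi
    if coords.angle_unit == "degrees":
        theta, phi = math.radians(theta), math.radians(phi)
    st = math.sin(theta)
    return (
        coords.r * st * math.cos(phi),
        coords.r * st * math.sin(phi),
        coords.r * math.cos(theta),
    )


def spherical_batch(
    points: np.ndarray, angle_unit: AngleUnit = "degrees"
) -> np.ndarray:
    """Vectorised first-octant conversion: (m, 3) points -> (m, 3) of
    (r, theta, phi). Zero-radius rows get angles 0."""
    points = np.asarray(points, dtype=float)
    if np.any(points < 0):
        raise DomainError("coordinates must be non-negative")
    r = np.linalg.norm(points, axis=1)
    safe_r = np.where(r == 0, 1.0, r)
    theta = np.arccos(np.clip(points[:, 2] / safe_r, -1.0, 1.0))
    phi = np.arctan2(points[:, 1], points[:, 0])
    theta = np.where(r == 0, 0.0, theta)
    phi = np.where(r == 0, 0.0, phi)
    if angle_unit == "degrees":
        theta, phi = np.degrees(theta), np.degrees(phi)
    return np.column_stack([r, theta, phi])


def cartesian_to_hyperspherical(
    v: np.ndarray, angle_unit: AngleUnit = "degrees"
) -> tuple[float, np.ndarray]:
    """Convert an n-vector (n >= 2) of non-negative coordinates to
    (r, n-1 angles) by the standard hyperspherical recursion.

    angle_k = arccos(v_k / ||(v_k, ..., v_n)||) for k = 1..n-2 and the
    final angle is atan2(v_n, v_{n-1}). With the 3-vector ordered
    (z, x, y) this reproduces :func:`cartesian_to_spherical`. The zero
    vector returns all angles 0 (degenerate convention).
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise DomainError("hyperspherical conversion needs a 1-D vector with n >= 2")
    if np.any(v < 0):
        raise DomainError("coordinates must be non-negative")
    n = v.size
    r = float(np.linalg.norm(v))
    angles = np.zeros(n - 1)
    if r == 0.0:
        return 0.0, angles if angle_unit == "radians" else np.degrees(angles)
    # tail norms ||(v_k, ..., v_n)||
    tail = np.sqrt(np.cumsum(v[::-1] ** 2)[::-1])
    for k in range(n - 2):
        angles[k] = 0.0 if tail[k] == 0 else math.acos(
            min(1.0, max(-1.0, v[k] / tail[k]))
        )
    angles[n - 2] = math.atan2(v[n - 1], v[n - 2])
    if angle_unit == "degrees":
        angles = np.degrees(angles)
    return r, angles


def hyperspherical_to_cartesian(
    r: float, angles: np.ndarray, angle_unit: AngleUnit = "degrees"
) -> np.ndarray:
    """Inverse of :func:`cartesian_to_hyperspherical`."""
    angles = np.asarray(angles, dtype=float)
    if angle_unit == "degrees":
        angles = np.radians(angles)
    n = angles.size + 1
    v = np.empty(n)
    sin_prod = 1.0
    for k in range(n - 1):
        v[k] = r * sin_prod * math.cos(angles[k])
        sin_prod *= math.sin(angles[k])
    v[n - 1] = r * sin_prod
    return v
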