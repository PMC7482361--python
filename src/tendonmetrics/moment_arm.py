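"""Achilles tendon moment arm from a talar-dome cylinder fit.

The ankle's rotation axis is modelled as the axis of a cylinder fitted to a
point cloud sampled on the dome of the talus.  The moment arm is the minimum
distance between that axis and the tendon's line of action (the centroid line
of the free tendon), both represented as cubic-spline curves; the minimum is
located by dense sampling followed by bounded local refinement.

The cylinder fit minimises the sum of squared orthogonal residuals
``(distance to axis - radius)^2`` by nonlinear least squares.  Because the
dome is only a partial cylindrical patch, the axis is initialised from the
PCA direction whose orthogonal-distance residual is lowest (the naive
smallest-eigenvalue choice is unreliable on partial arcs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import least_squares, minimize
from scipy.spatial.distance import cdist

__all__ = [
    "CylinderFit",
    "Curve3D",
    "MomentArmResult",
    "fit_cylinder",
    "min_distance_between_curves",
    "compute_moment_arm",
]


class CylinderFitError(RuntimeError):
    """Cylinder fit failed to converge."""

    def __init__(self, message: str, best_residual: float):
        super().__init__(message)
        self.best_residual = best_residual


@dataclass(frozen=True)
class CylinderFit:
    """Axis + radius model of the talar dome.

    ``axis_point`` is a point on the axis (mm), ``axis_direction`` a unit
    vector, ``radius`` in mm, ``rms_residual`` the root-mean-square orthogonal
    residual of the fit in mm.
    """

    axis_point: np.ndarray
    axis_direction: np.ndarray
    radius: float
    rms_residual: float
    n_points: int

    def __post_init__(self) -> None:
        d = np.asarray(self.axis_direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("axis_direction must be a unit vector")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be non-negative")
        object.__setattr__(self, "axis_point", np.asarray(self.axis_point, float))
        object.__setattr__(self, "axis_direction", d)


@dataclass(frozen=True)
class Curve3D:
    """An ordered 3D polyline with cumulative-arc-length parameterization,
    interpolated with a natural cubic spline when evaluated."""

    samples: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 4:
            raise ValueError("Curve3D needs >= 4 ordered 3D points")
        seg = np.linalg.norm(np.diff(s, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("curve parameter must strictly increase")
        object.__setattr__(self, "samples", s)

    @property
    def parameterization(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.samples, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def spline(self) -> CubicSpline:
        return CubicSpline(self.parameterization, self.samples, axis=0)


@dataclass(frozen=True)
class MomentArmResult:
    """Moment arm in cm with the closest point pair (mm) that realises it."""

    moment_arm: float  # cm
    closest_point_axis: np.ndarray
    closest_point_tendon: np.ndarray
    cylinder: CylinderFit

    def __post_init__(self) -> None:
        if self.moment_arm < 0:
            raise ValueError("moment arm must be non-negative")

    def to_dict(self) -> dict:
        return {
            "moment_arm_cm": self.moment_arm,
            "radius_mm": self.cylinder.radius,
            "rms_residual_mm": self.cylinder.rms_residual,
            "closest_points": {
                "axis_mm": self.closest_point_axis.tolist(),
                "tendon_mm": self.closest_point_tendon.tolist(),
            },
        }


# ---------------------------------------------------------------------------
# cylinder fitting


def _direction(theta: float, phi: float) -> np.ndarray:
    return np.array(
        [
            np.sin(theta) * np.cos(phi),
            np.sin(theta) * np.sin(phi),
            np.cos(theta),
        ]
    )


def _axis_residuals(points: np.ndarray, point: np.ndarray, direction: np.ndarray):
    rel = points - point
    perp = rel - np.outer(rel @ direction, direction)
    return np.linalg.norm(perp, axis=1)


def fit_cylinder(points: np.ndarray, max_restarts: int = 3) -> CylinderFit:
    """Orthogonal least-squares cylinder fit to a 3D point cloud.

    Minimises ``sum((distance to axis - radius)^2)`` over axis orientation
    (two spherical angles), axis offset (two components perpendicular to the
    axis) and radius.  Initialisation: for each of the three PCA directions
    of the cloud, a candidate cylinder uses that direction as axis and the
    median axis distance as radius; the direction with the lowest residual
    seeds the optimiser.  Up to ``max_restarts`` seeded restarts with
    perturbed initial orientations are attempted before giving up.

    Raises
    ------
    CylinderFitError
        If no restart converges; carries the best residual seen.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 8:
        raise ValueError("cylinder fit needs >= 8 3D points")
    center = pts.mean(axis=0)
    svals, vt = np.linalg.svd(pts - center, full_matrices=False)[1:]
    if svals[1] < 1e-9 * max(svals[0], 1.0):
        raise ValueError("cylinder fit needs non-collinear points")
    # pick the PCA direction with the lowest orthogonal-distance spread
    best_dir, best_cost = None, np.inf
    for cand in vt:
        d = _axis_residuals(pts, center, cand)
        cost = np.sum((d - np.median(d)) ** 2)
        if cost < best_cost:
            best_dir, best_cost = cand, cost
    theta0 = float(np.arccos(np.clip(best_dir[2], -1.0, 1.0)))
    phi0 = float(np.arctan2(best_dir[1], best_dir[0]))

    def residuals(p):
        th, ph, ox, oy, r = p
        direction = _direction(th, ph)
        u, v = _plane_basis_of(direction)
        axis_point = center + ox * u + oy * v
        return _axis_residuals(pts, axis_point, direction) - r

    rng = np.random.default_rng(12345)
    best_sol, best_rms = None, np.inf
    for attempt in range(max_restarts):
        if attempt == 0:
            theta, phi = theta0, phi0
        else:
            theta = theta0 + rng.normal(scale=0.3)
            phi = phi0 + rng.normal(scale=0.3)
        ox0, oy0, r0 = _circle_init(pts, center, _direction(theta, phi))
        x0 = np.array([theta, phi, ox0, oy0, r0])
        sol = None
        for _ in range(2):  # second pass restarts the trust region (polish)
            sol = least_squares(
                residuals, x0=x0, method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14
            )
            x0 = sol.x
        rms = float(np.sqrt(np.mean(sol.fun**2)))
        if sol.success and sol.x[4] > 0 and rms < best_rms:
            best_sol, best_rms = sol, rms
    if best_sol is None:
        raise CylinderFitError(
            f"cylinder fit did not converge after {max_restarts} restarts "
            f"(best RMS residual {best_rms:.3g} mm)",
            best_residual=best_rms,
        )
    th, ph, ox, oy, r = best_sol.x
    direction = _direction(th, ph)
    u, v = _plane_basis_of(direction)
    axis_point = center + ox * u + oy * v
    # canonical representation: axis point = projection of the cloud mean
    # onto the axis
    axis_point = axis_point + np.dot(center - axis_point, direction) * direction
    return CylinderFit(
        axis_point=axis_point,
        axis_direction=direction,
        radius=float(r),
        rms_residual=best_rms,
        n_points=len(pts),
    )


def _circle_init(
    pts: np.ndarray, center: np.ndarray, direction: np.ndarray
) -> tuple[float, float, float]:
    """Algebraic (Kasa) circle fit to the points projected onto the plane
    perpendicular to a candidate axis direction.

    Robust initialiser for partial arcs, where the cloud mean is far from
    the true axis and a naive median-distance radius badly underestimates.
    Returns the in-plane axis offset (relative to the cloud mean) and radius.
    """
    u, v = _plane_basis_of(direction)
    rel = pts - center
    x, y = rel @ u, rel @ v
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    sol, *_ = np.linalg.lstsq(A, x**2 + y**2, rcond=None)
    a, b, c = sol
    r = float(np.sqrt(max(c + a**2 + b**2, 1e-12)))
    return float(a), float(b), r


def _plane_basis_of(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(direction)))] = 1.0
    u = ref - np.dot(ref, direction) * direction
    u /= np.linalg.norm(u)
    return u, np.cross(direction, u)


# ---------------------------------------------------------------------------
# curve-to-curve minimum distance


def min_distance_between_curves(
    a: Curve3D, b: Curve3D, n_samples: int = 2000
) -> tuple[float, np.ndarray, np.ndarray]:
    """Minimum distance between two cubic-spline-interpolated space curves.

    Both curves are densely sampled (``n_samples`` each); the minimising
    sample pair seeds a bounded 2D local minimisation of the inter-point
    distance over the two arc-length parameters.  Ties in the dense scan are
    broken toward the smallest parameter pair.

    Returns
    -------
    (distance_mm, point_on_a, point_on_b)
    """
    sa, sb = a.spline(), b.spline()
    ta = np.linspace(0.0, a.parameterization[-1], n_samples)
    tb = np.linspace(0.0, b.parameterization[-1], n_samples)
    pa, pb = sa(ta), sb(tb)
    d = cdist(pa, pb)
    i, j = np.unravel_index(int(np.argmin(d)), d.shape)

    def objective(x):
        return float(np.sum((sa(x[0]) - sb(x[1])) ** 2))

    res = minimize(
        objective,
        x0=[ta[i], tb[j]],
        bounds=[(0.0, ta[-1]), (0.0, tb[-1])],
        method="L-BFGS-B",
    )
    refined = float(np.sqrt(res.fun))
    dense_min = float(d[i, j])
    if refined <= dense_min:
        return refined, np.asarray(sa(res.x[0])), np.asarray(sb(res.x[1]))
    return dense_min, pa[i], pb[j]


def compute_moment_arm(
    dome_points: np.ndarray, tendon_centroids: Curve3D, n_axis_samples: int = 10
) -> MomentArmResult:
    """Moment arm (cm) between the talar-dome cylinder axis and the tendon
    centroid line.

    The fitted axis is represented as a line segment spanning the orthogonal
    projections of the dome points onto the axis, sampled at
    ``n_axis_samples`` stations, splined, and matched against the splined
    tendon centroid curve by :func:`min_distance_between_curves`.  The
    distance is converted from mm to cm (the conventional reporting unit).
    """
    fit = fit_cylinder(dome_points)
    pts = np.asarray(dome_points, dtype=float)
    t = (pts - fit.axis_point) @ fit.axis_direction
    stations = np.linspace(t.min(), t.max(), n_axis_samples)
    axis_curve = Curve3D(
        samples=fit.axis_point + np.outer(stations, fit.axis_direction)
    )
    dist_mm, p_axis, p_tendon = min_distance_between_curves(
        axis_curve, tendon_centroids
    )
    return MomentArmResult(
        moment_arm=dist_mm / 10.0,
        closest_point_axis=p_axis,
        closest_point_tendon=p_tendon,
        cylinder=fit,
    )
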