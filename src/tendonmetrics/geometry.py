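"""Tendon geometry from sparse transverse contour stacks.

A tendon is represented as an ordered stack of planar polygons (transverse
cross-sections with 3D vertex coordinates, distal end first).  Sparse manual
segmentations (typically 6–8 slices) are densified by shape interpolation
between adjacent contours, after which volume, centroid-path length, average
cross-sectional area (CSA = volume / length) and a regional CSA profile at 1%
increments of tendon length are computed.

Conventions
-----------
* All coordinates are in millimetres.
* Tendon length is the cumulative sum of distances between the centroids of
  consecutive slices (a polyline through the centroid chain), so curved
  tendons are measured along their path.
* Volume uses the trapezoidal rule between consecutive slice areas along the
  same centroid path, keeping volume and length mutually consistent.
* The CSA profile is sampled on a fixed 101-point grid, 0% = distal
  (calcaneal) end, 100% = proximal (soleus muscle-tendon junction) end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "Contour",
    "ContourStack",
    "GeometryMetrics",
    "CSAProfile",
    "polygon_area_centroid",
    "densify_stack",
    "compute_metrics",
    "read_contours_csv",
    "write_contours_csv",
    "read_contours_json",
    "write_contours_json",
]

PERCENT_GRID = np.arange(101, dtype=float)

_COPLANARITY_TOL = 1e-6  # mm, max vertex distance from best-fit plane
_DEGENERATE_AREA = 1e-9  # mm^2


class ContourError(ValueError):
    """Invalid contour or contour stack."""


def _best_fit_plane(vertices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through a vertex cloud.

    Returns (point_on_plane, unit_normal); the point is the vertex mean and
    the normal is the singular vector of the centred cloud with the smallest
    singular value.
    """
    center = vertices.mean(axis=0)
    _, _, vt = np.linalg.svd(vertices - center, full_matrices=False)
    normal = vt[-1]
    return center, normal / np.linalg.norm(normal)


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Right-handed in-plane basis (u, v) with u x v = normal.

    The reference direction is the canonical axis least aligned with the
    normal, so nearby slices of a stack receive consistent frames.
    """
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(normal)))] = 1.0
    u = ref - np.dot(ref, normal) * normal
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return u, v


@dataclass(frozen=True)
class Contour:
    """A planar transverse cross-section polygon in 3D.

    Parameters
    ----------
    vertices : (n, 3) array
        Ordered polygon vertices in mm.  The polygon is implicitly closed
        (no repeated final vertex).
    slice_index : int
        Position of the slice in its stack (strictly increasing distal to
        proximal).
    plane_normal : (3,) array, optional
        Unit normal of the slice plane; recomputed from the vertices when
        omitted.
    """

    vertices: np.ndarray
    slice_index: int
    plane_normal: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ContourError(
                f"slice {self.slice_index}: vertices must be (n, 3), got {v.shape}"
            )
        if v.shape[0] < 3:
            raise ContourError(
                f"slice {self.slice_index}: a contour needs >= 3 vertices"
            )
        object.__setattr__(self, "vertices", v)
        center, normal = _best_fit_plane(v)
        dist = np.abs((v - center) @ normal)
        if dist.max() > _COPLANARITY_TOL:
            raise ContourError(
                f"slice {self.slice_index}: vertices deviate "
                f"{dist.max():.3g} mm from the best-fit plane"
            )
        if self.plane_normal is None:
            object.__setattr__(self, "plane_normal", normal)
        else:
            n = np.asarray(self.plane_normal, dtype=float)
            object.__setattr__(self, "plane_normal", n / np.linalg.norm(n))
        u, w = _plane_basis(normal)
        xy = np.column_stack([(v - center) @ u, (v - center) @ w])
        if not _ShapelyPolygon(xy).is_valid:
            raise ContourError(
                f"slice {self.slice_index}: polygon is self-intersecting"
            )

    def __len__(self) -> int:
        return len(self.vertices)


def polygon_area_centroid(contour: Contour) -> tuple[float, np.ndarray]:
    """Planar area (mm^2) and 3D area centroid (mm) of a contour.

    The polygon is projected onto its best-fit plane; the area comes from the
    shoelace formula (absolute value, so vertex winding is irrelevant) and the
    centroid is the standard polygon area centroid mapped back to 3D.
    """
    v = contour.vertices
    center, normal = _best_fit_plane(v)
    u, w = _plane_basis(normal)
    x = (v - center) @ u
    y = (v - center) @ w
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    signed_area = 0.5 * cross.sum()
    area = abs(signed_area)
    if area < _DEGENERATE_AREA:
        raise ContourError(
            f"slice {contour.slice_index}: degenerate polygon (area "
            f"{area:.3g} mm^2)"
        )
    cx = ((x + x1) * cross).sum() / (6.0 * signed_area)
    cy = ((y + y1) * cross).sum() / (6.0 * signed_area)
    centroid = center + cx * u + cy * w
    return float(area), centroid


@dataclass
class ContourStack:
    """Ordered stack of contours, distal end first.

    ``provenance`` distinguishes sparse manual segmentations from densified
    stacks; ``slice_spacing`` is the uniform centroid-chord spacing of a
    dense stack (``nan`` for sparse input).
    """

    contours: list[Contour]
    slice_spacing: float = float("nan")
    provenance: Literal["sparse", "dense"] = "sparse"

    def __post_init__(self) -> None:
        idx = [c.slice_index for c in self.contours]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ContourError(f"slice indices must strictly increase, got {idx}")

    def __len__(self) -> int:
        return len(self.contours)

    def centroids(self) -> np.ndarray:
        return np.array([polygon_area_centroid(c)[1] for c in self.contours])

    def areas(self) -> np.ndarray:
        return np.array([polygon_area_centroid(c)[0] for c in self.contours])


@dataclass(frozen=True)
class CSAProfile:
    """Regional CSA resampled at 1% increments of tendon length.

    0% is the distal (calcaneal) end.  Exactly 101 samples.
    """

    percent_grid: np.ndarray
    csa: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.percent_grid, dtype=float)
        a = np.asarray(self.csa, dtype=float)
        if g.shape != (101,) or a.shape != (101,):
            raise ValueError("CSA profile must have exactly 101 samples")
        if not np.allclose(g, PERCENT_GRID):
            raise ValueError("percent grid must be 0,1,...,100")
        if np.any(a <= 0):
            raise ValueError("all CSA values must be positive")
        object.__setattr__(self, "percent_grid", g)
        object.__setattr__(self, "csa", a)


@dataclass(frozen=True)
class GeometryMetrics:
    """Scalar morphometry of a dense stack plus its regional CSA profile."""

    volume: float  # mm^3
    length: float  # mm
    average_csa: float  # mm^2
    csa_profile: CSAProfile

    def __post_init__(self) -> None:
        if self.volume <= 0 or self.length <= 0:
            raise ValueError("volume and length must be positive")
        if abs(self.average_csa * self.length - self.volume) > 1e-9 * self.volume:
            raise ValueError("average_csa must equal volume / length")

    def to_dict(self) -> dict:
        return {
            "volume_mm3": self.volume,
            "length_mm": self.length,
            "average_csa_mm2": self.average_csa,
            "csa_profile": [
                [float(p), float(a)]
                for p, a in zip(self.csa_profile.percent_grid, self.csa_profile.csa)
            ],
        }


# ---------------------------------------------------------------------------
# densification


def _resample_closed(vertices: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polygon to n vertices uniformly spaced by perimeter
    arc length, keeping the original starting phase."""
    closed = np.vstack([vertices, vertices[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    targets = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.interp(targets, s, closed[:, k])
    return out


def _orient_and_phase(vertices: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Order vertices counter-clockwise about ``normal`` and roll the cycle so
    the first vertex sits at polar angle >= 0 closest to 0 in the plane frame."""
    center, _ = _best_fit_plane(vertices)
    u, w = _plane_basis(normal)
    x = (vertices - center) @ u
    y = (vertices - center) @ w
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    v = vertices if signed >= 0 else vertices[::-1]
    x2 = (v - center) @ u
    y2 = (v - center) @ w
    ang = np.mod(np.arctan2(y2, x2), 2 * np.pi)
    return np.roll(v, -int(np.argmin(ang)), axis=0)


def _best_roll(prev: np.ndarray, cur: np.ndarray) -> np.ndarray:
    """Cyclic shift of ``cur`` minimising the summed squared vertex distance to
    ``prev`` (translation removed, so the alignment is about shape phase)."""
    p = prev - prev.mean(axis=0)
    c = cur - cur.mean(axis=0)
    n = len(cur)
    costs = [np.sum((np.roll(c, -k, axis=0) - p) ** 2) for k in range(n)]
    return np.roll(cur, -int(np.argmin(costs)), axis=0)


def _project_to_plane(vertices: np.ndarray) -> np.ndarray:
    center, normal = _best_fit_plane(vertices)
    return vertices - np.outer((vertices - center) @ normal, normal)


def densify_stack(
    sparse: ContourStack, target_spacing: float, n_vertices: int = 96
) -> ContourStack:
    """Interpolate a sparse contour stack to a dense, uniformly spaced one.

    Each contour is resampled to ``n_vertices`` points by perimeter arc
    length, oriented counter-clockwise about a stack-consistent normal,
    phase-aligned by polar angle about its planar centroid, and cyclically
    rolled to minimise the squared vertex distance to its distal neighbour.
    Vertex-correspondent linear interpolation then fills planes spaced
    ``target_spacing`` apart along the centroid chord path (the spacing is
    adjusted to divide each total chord length evenly, so original contours
    fall exactly on stations).

    Parameters
    ----------
    sparse : ContourStack
        At least two contours, distal first.
    target_spacing : float
        Requested station spacing in mm (e.g. 0.27 for MRI reslicing, 0.063
        for freehand 3D ultrasound).
    n_vertices : int
        Common vertex count used for correspondence (default 96).

    Returns
    -------
    ContourStack with ``provenance='dense'``.
    """
    if len(sparse) < 2:
        raise ContourError("densification needs >= 2 sparse contours")
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")

    centroids = sparse.centroids()
    path = np.diff(centroids, axis=0)

    aligned: list[np.ndarray] = []
    normals: list[np.ndarray] = []
    for i, contour in enumerate(sparse.contours):
        _, normal = _best_fit_plane(contour.vertices)
        # orient every slice normal along the distal->proximal path direction
        direction = path[min(i, len(path) - 1)]
        if np.dot(normal, direction) < 0:
            normal = -normal
        res = _resample_closed(contour.vertices, n_vertices)
        res = _orient_and_phase(res, normal)
        if aligned:
            res = _best_roll(aligned[-1], res)
        aligned.append(res)
        normals.append(normal)

    chord = np.linalg.norm(path, axis=1)
    if np.any(chord <= 0):
        raise ContourError("coincident consecutive centroids in sparse stack")
    stations = np.concatenate([[0.0], np.cumsum(chord)])
    total = stations[-1]
    n_seg = max(1, int(round(total / target_spacing)))
    spacing = total / n_seg

    dense: list[Contour] = []
    for j in range(n_seg + 1):
        s = min(j * spacing, total)
        k = min(int(np.searchsorted(stations, s, side="right")) - 1, len(chord) - 1)
        w = (s - stations[k]) / chord[k]
        if w <= 1e-12:
            verts = aligned[k]
        elif w >= 1.0 - 1e-12:
            verts = aligned[k + 1]
        else:
            verts = (1.0 - w) * aligned[k] + w * aligned[k + 1]
            verts = _project_to_plane(verts)
        nrm = (1.0 - w) * normals[k] + w * normals[k + 1]
        nrm /= np.linalg.norm(nrm)
        dense.append(Contour(vertices=verts, slice_index=j, plane_normal=nrm))

    return ContourStack(contours=dense, slice_spacing=spacing, provenance="dense")


def compute_metrics(dense: ContourStack) -> GeometryMetrics:
    """Volume, centroid-path length, average CSA and regional CSA profile.

    length  = sum of distances between consecutive slice centroids
    volume  = trapezoidal rule over slice areas along the same centroid path
    average = volume / length
    profile = slice area linearly interpolated against cumulative centroid
              arc length at 0, 1, ..., 100% of tendon length
    """
    if len(dense) < 2:
        raise ContourError("metrics need >= 2 slices")
    areas = dense.areas()
    centroids = dense.centroids()
    seg = np.linalg.norm(np.diff(centroids, axis=0), axis=1)
    length = float(seg.sum())
    volume = float(np.sum(0.5 * (areas[:-1] + areas[1:]) * seg))
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    csa = np.interp(PERCENT_GRID / 100.0 * length, arc, areas)
    profile = CSAProfile(percent_grid=PERCENT_GRID.copy(), csa=csa)
    return GeometryMetrics(
        volume=volume,
        length=length,
        average_csa=volume / length,
        csa_profile=profile,
    )


# ---------------------------------------------------------------------------
# file interchange


def write_contours_csv(stack: ContourStack, path: str | Path) -> None:
    """CSV with columns slice_index,x_mm,y_mm,z_mm, one row per vertex."""
    rows = []
    for c in stack.contours:
        for x, y, z in c.vertices:
            rows.append((c.slice_index, repr(float(x)), repr(float(y)), repr(float(z))))
    pd.DataFrame(rows, columns=["slice_index", "x_mm", "y_mm", "z_mm"]).to_csv(
        path, index=False
    )


def read_contours_csv(path: str | Path) -> ContourStack:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"slice_index", "x_mm", "y_mm", "z_mm"}
    if not required.issubset(df.columns):
        raise ContourError(
            f"{path}: contour CSV needs columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    contours = [
        Contour(
            vertices=grp[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
            slice_index=int(idx),
        )
        for idx, grp in df.groupby("slice_index", sort=True)
    ]
    return ContourStack(contours=contours)


def write_contours_json(stack: ContourStack, path: str | Path) -> None:
    payload = {
        "provenance": stack.provenance,
        "slice_spacing_mm": None
        if np.isnan(stack.slice_spacing)
        else stack.slice_spacing,
        "contours": [
            {"slice_index": c.slice_index, "vertices_mm": c.vertices.tolist()}
            for c in stack.contours
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_contours_json(path: str | Path) -> ContourStack:
    payload = json.loads(Path(path).read_text())
    contours = [
        Contour(
            vertices=np.asarray(c["vertices_mm"], dtype=float),
            slice_index=int(c["slice_index"]),
        )
        for c in payload["contours"]
    ]
    spacing = payload.get("slice_spacing_mm")
    return ContourStack(
        contours=contours,
        slice_spacing=float("nan") if spacing is None else float(spacing),
        provenance=payload.get("provenance", "sparse"),
    )
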