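"""Synthetic inputs with known ground truth for every pipeline stage.

Real tendon scans behind the measurement chain (MRI contour stacks, talar
dome surfaces, multi-echo UTE stacks, staged isometric load tables) are not
publicly deposited, so this module generates seeded stand-ins with
closed-form truth records:

* tapered, optionally curved tendon phantoms sliced into sparse transverse
  contours (truth: frustum-type volume integral, arc length, area profile);
* cylindrical talar-dome patches under arbitrary rigid poses;
* voxelwise mono-exponential-with-bias multi-echo signal with Gaussian or
  Rician noise;
* staged force-elongation series with a quadratic toe region followed by a
  linear region of known stiffness, and isovolumetric CSA reduction under
  load;
* two-group cohorts whose per-subject parameters are drawn from group-level
  means/SDs, with a Gaussian-copula correlation between T2* and Young's
  modulus.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from tendonmetrics.geometry import (
    PERCENT_GRID,
    Contour,
    ContourStack,
    CSAProfile,
    GeometryMetrics,
)
from tendonmetrics.mechanics import LOAD_LEVELS, SubjectRecord
from tendonmetrics.relaxometry import ECHO_TIMES_QLD_MS, EchoSeries

__all__ = [
    "TendonPhantomSpec",
    "GroupSpec",
    "CohortSpec",
    "Subject",
    "Cohort",
    "make_tendon_phantom",
    "make_dome_points",
    "make_multiecho_stack",
    "make_load_series",
    "make_cohort",
    "random_rigid_pose",
    "apply_pose",
    "RUNNER_DEFAULTS",
    "CONTROL_DEFAULTS",
]


# ---------------------------------------------------------------------------
# rigid poses


def random_rigid_pose(seed: int | np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random rotation matrix and a translation in [-50, 50] mm."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return rot, rng.uniform(-50.0, 50.0, size=3)


def apply_pose(points: np.ndarray, pose: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    rot, trans = pose
    return points @ rot.T + trans


# ---------------------------------------------------------------------------
# tendon phantom


@dataclass(frozen=True)
class TendonPhantomSpec:
    """Parameters of a tapered elliptical-tube tendon phantom.

    The cross-section at fraction ``t`` of the path (0 = distal) is an
    ellipse of semi-axes ``r(t)*sqrt(ellipticity)`` and
    ``r(t)/sqrt(ellipticity)`` with ``r`` linear from ``distal_radius`` to
    ``proximal_radius``, so the area is ``pi * r(t)^2`` independent of
    ellipticity.  ``centroid_path`` is ``"straight"`` or ``("arc", R)`` for a
    circular arc of radius R mm.  ``contour_noise_sd`` perturbs vertices
    within their slice plane (transverse segmentation error).
    """

    length: float = 45.0  # mm
    distal_radius: float = 5.2  # mm
    proximal_radius: float = 4.4  # mm
    ellipticity: float = 1.4
    centroid_path: str | tuple[str, float] = "straight"
    contour_noise_sd: float = 0.0  # mm, in-plane
    slice_spacing: float = 0.27  # mm, densification default (MRI reslice)
    n_sparse_slices: int = 7
    n_vertices: int = 48
    seed: int = 0

    def __post_init__(self) -> None:
        if self.distal_radius <= 0 or self.proximal_radius <= 0:
            raise ValueError("radii must be positive")
        if self.n_sparse_slices < 2:
            raise ValueError("need >= 2 sparse slices")

    def radius_at(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.distal_radius + (self.proximal_radius - self.distal_radius) * t

    def area_at(self, t: np.ndarray | float) -> np.ndarray | float:
        return np.pi * self.radius_at(t) ** 2

    def truth_volume(self) -> float:
        """Closed-form volume of the tapered tube: L * pi * (rd^2 + rd*dr +
        dr^2 / 3) with dr = rp - rd (conical-frustum integral)."""
        rd, rp = self.distal_radius, self.proximal_radius
        dr = rp - rd
        return float(self.length * np.pi * (rd**2 + rd * dr + dr**2 / 3.0))


def _path_frame(spec: TendonPhantomSpec, s: np.ndarray):
    """Centroid position and in-plane basis (u, v) at arc lengths ``s``."""
    if spec.centroid_path == "straight":
        centers = np.column_stack([np.zeros_like(s), np.zeros_like(s), s])
        u = np.tile([1.0, 0.0, 0.0], (len(s), 1))
        v = np.tile([0.0, 1.0, 0.0], (len(s), 1))
        return centers, u, v
    kind, radius = spec.centroid_path
    if kind != "arc":
        raise ValueError(f"unknown centroid path {spec.centroid_path!r}")
    phi = s / radius
    centers = np.column_stack(
        [radius * np.sin(phi), np.zeros_like(s), radius * (1.0 - np.cos(phi))]
    )
    # tangent (cos phi, 0, sin phi); u fixed out of plane, v completes frame
    u = np.tile([0.0, 1.0, 0.0], (len(s), 1))
    v = np.column_stack([-np.sin(phi), np.zeros_like(phi), np.cos(phi)])
    return centers, u, v


def make_tendon_phantom(
    spec: TendonPhantomSpec,
) -> tuple[ContourStack, GeometryMetrics]:
    """Sparse contour stack sampled from the phantom surface plus its
    analytic ground-truth metrics (computed before noise)."""
    truth_volume = spec.truth_volume()
    truth = GeometryMetrics(
        volume=truth_volume,
        length=spec.length,
        average_csa=truth_volume / spec.length,
        csa_profile=CSAProfile(
            percent_grid=PERCENT_GRID.copy(),
            csa=np.asarray(spec.area_at(PERCENT_GRID / 100.0)),
        ),
    )

    rng = np.random.default_rng(spec.seed)
    stations = np.linspace(0.0, spec.length, spec.n_sparse_slices)
    centers, u, v = _path_frame(spec, stations)
    theta = np.linspace(0.0, 2.0 * np.pi, spec.n_vertices, endpoint=False)
    sq = np.sqrt(spec.ellipticity)
    contours = []
    for i, t in enumerate(stations / spec.length):
        r = spec.radius_at(t)
        radial = np.zeros_like(theta)
        if spec.contour_noise_sd > 0:
            # smooth radial perturbation (low-order Fourier series): emulates
            # segmentation error without creating self-intersecting polygons
            for k in range(1, 5):
                a, b = rng.normal(scale=spec.contour_noise_sd / 2.0, size=2)
                radial += a * np.cos(k * theta) + b * np.sin(k * theta)
        x_local = (r * sq + radial) * np.cos(theta)
        y_local = (r / sq + radial) * np.sin(theta)
        verts = centers[i] + np.outer(x_local, u[i]) + np.outer(y_local, v[i])
        contours.append(Contour(vertices=verts, slice_index=i))
    return ContourStack(contours=contours), truth


# ---------------------------------------------------------------------------
# talar dome


def make_dome_points(
    radius: float = 10.0,
    arc_deg: float = 120.0,
    axial_extent: float = 25.0,
    noise_sd: float = 0.0,
    n: int = 500,
    pose: tuple[np.ndarray, np.ndarray] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Points on a cylindrical patch emulating the talar dome.

    In the canonical frame the cylinder axis is the x-axis; points cover an
    ``arc_deg`` angular sector centred on +z (the dome top) over an axial
    extent of ``axial_extent`` mm, with isotropic Gaussian noise added before
    the optional rigid ``pose`` is applied.
    """
    if n < 8:
        raise ValueError("need n >= 8 dome points")
    rng = np.random.default_rng(seed)
    half = np.deg2rad(arc_deg) / 2.0
    theta = rng.uniform(np.pi / 2.0 - half, np.pi / 2.0 + half, size=n)
    x = rng.uniform(-axial_extent / 2.0, axial_extent / 2.0, size=n)
    pts = np.column_stack([x, radius * np.cos(theta), radius * np.sin(theta)])
    if noise_sd > 0:
        pts = pts + rng.normal(scale=noise_sd, size=pts.shape)
    if pose is not None:
        pts = apply_pose(pts, pose)
    return pts


# ---------------------------------------------------------------------------
# multi-echo signal


def make_multiecho_stack(
    t2star_map: np.ndarray,
    s0_map: np.ndarray,
    bias: float | np.ndarray,
    echo_times: np.ndarray = np.asarray(ECHO_TIMES_QLD_MS),
    noise_sd: float = 0.0,
    noise_model: Literal["gaussian", "rician"] = "gaussian",
    seed: int = 0,
) -> EchoSeries:
    """Voxelwise ``S(TE) = S0 exp(-TE/T2*) + bias`` plus noise.

    Gaussian noise is added to the magnitude and clipped at zero; Rician
    noise applies independent Gaussian perturbations to the two quadrature
    channels (``sqrt((S + n1)^2 + n2^2)``), the physically correct magnitude
    model at low signal-to-noise ratio.
    """
    t2 = np.asarray(t2star_map, dtype=float)
    s0 = np.asarray(s0_map, dtype=float)
    if t2.shape != s0.shape:
        raise ValueError("t2star and s0 maps must share a shape")
    te = np.asarray(echo_times, dtype=float)
    clean = s0[..., None] * np.exp(-te / t2[..., None]) + np.asarray(bias)[..., None] \
        if np.ndim(bias) else s0[..., None] * np.exp(-te / t2[..., None]) + bias
    rng = np.random.default_rng(seed)
    if noise_sd == 0:
        signal = clean
    elif noise_model == "gaussian":
        signal = np.clip(clean + rng.normal(scale=noise_sd, size=clean.shape), 0, None)
    elif noise_model == "rician":
        n1 = rng.normal(scale=noise_sd, size=clean.shape)
        n2 = rng.normal(scale=noise_sd, size=clean.shape)
        signal = np.sqrt((clean + n1) ** 2 + n2**2)
    else:
        raise ValueError(f"unknown noise model {noise_model!r}")
    return EchoSeries(echo_times=te, signal=signal)


# ---------------------------------------------------------------------------
# staged isometric loading


def _elongation_at_force(
    force: np.ndarray, stiffness: float, toe_elongation: float
) -> np.ndarray:
    """Invert the piecewise toe-then-linear force-elongation curve.

    F(e) = k e^2 / (2 e_toe) for e <= e_toe (slope grows linearly to k),
    then F = F_toe + k (e - e_toe).  toe_elongation = 0 gives F = k e.
    """
    f = np.asarray(force, dtype=float)
    if toe_elongation <= 0:
        return f / stiffness
    f_toe = stiffness * toe_elongation / 2.0
    toe = np.sqrt(2.0 * np.clip(f, 0, None) * toe_elongation / stiffness)
    lin = toe_elongation + (f - f_toe) / stiffness
    return np.where(f <= f_toe, toe, lin)


def make_load_series(
    true_stiffness: float,
    toe_strain_limit: float = 0.005,
    L0: float = 45.0,
    csa0: float = 75.0,
    moment_arm: float = 5.0,
    mvc_torque: float = 95.1,
    torque_noise_sd: float = 0.0,
    length_noise_sd: float = 0.0,
    rest_torque: float = 2.0,
    n_trials: int = 3,
    level_jitter_sd: float = 2.0,
    subject_id: str = "S00",
    group: Literal["runner", "control"] = "runner",
    seed: int = 0,
) -> tuple[SubjectRecord, dict]:
    """Staged isometric measurement table for one subject, plus a truth dict.

    Torque levels target 25/50/70% of MVC within a +-5% window (Gaussian
    jitter of ``level_jitter_sd`` %MVC, truncated); the net torque maps to
    force through the moment arm, force to elongation through the toe/linear
    model, and the loaded CSA shrinks isovolumetrically
    (``csa = csa0 * L0 / L``).  Measurement noise applies to recorded torque
    and length.
    """
    if min(true_stiffness, L0, csa0, moment_arm, mvc_torque) <= 0:
        raise ValueError("all physical parameters must be positive")
    rng = np.random.default_rng(seed)
    toe_elong = toe_strain_limit * L0
    rows = []
    # resting trials: no net load, resting length
    for _ in range(n_trials):
        rows.append(
            {
                "level": "rest",
                "torque_load_Nm": rest_torque,
                "torque_rest_Nm": rest_torque,
                "length_mm": L0 + rng.normal(scale=length_noise_sd)
                if length_noise_sd > 0
                else L0,
                "csa_mm2": csa0,
            }
        )
    for level in LOAD_LEVELS:
        for _ in range(n_trials):
            pct = level + np.clip(rng.normal(scale=level_jitter_sd), -5.0, 5.0) \
                if level_jitter_sd > 0 else float(level)
            net = pct / 100.0 * mvc_torque
            force = net / (moment_arm / 100.0)
            elong = float(_elongation_at_force(force, true_stiffness, toe_elong))
            length = L0 + elong
            rows.append(
                {
                    "level": level,
                    "torque_load_Nm": rest_torque
                    + net
                    + (rng.normal(scale=torque_noise_sd) if torque_noise_sd > 0 else 0.0),
                    "torque_rest_Nm": rest_torque,
                    "length_mm": length
                    + (rng.normal(scale=length_noise_sd) if length_noise_sd > 0 else 0.0),
                    "csa_mm2": csa0 * L0 / length,
                }
            )
    record = SubjectRecord(
        subject_id=subject_id,
        group=group,
        moment_arm=moment_arm,
        mvc_torque=mvc_torque,
        measurements=pd.DataFrame(rows),
    )
    truth = {
        "stiffness_N_per_mm": true_stiffness,
        "resting_length_mm": L0,
        "csa0_mm2": csa0,
        "moment_arm_cm": moment_arm,
        "toe_strain_limit": toe_strain_limit,
    }
    return record, truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class GroupSpec:
    """Group-level means and SDs for one cohort arm.

    ``stiffness_mean/sd`` of ``None`` derives per-subject stiffness from the
    drawn modulus and geometry (``k = 1000 E A / L0``), keeping modulus,
    stiffness, CSA and length mutually consistent within a subject.
    ``distal_csa_excess`` is the fractional CSA surplus of the distal over
    the proximal end.
    """

    name: Literal["runner", "control"]
    n: int = 16
    length_mean: float = 45.0
    length_sd: float = 7.0
    csa_mean: float = 75.0
    csa_sd: float = 11.0
    distal_excess_mean: float = 0.40
    distal_excess_sd: float = 0.10
    moment_arm_mean: float = 5.0
    moment_arm_sd: float = 0.3
    modulus_mean: float = 0.38  # GPa
    modulus_sd: float = 0.11
    t2star_mean: float = 12.0  # ms
    t2star_sd: float = 2.0
    mvc_mean: float = 95.1  # Nm
    mvc_sd: float = 21.4
    stiffness_mean: float | None = None
    stiffness_sd: float | None = None
    t2star_modulus_corr: float = -0.25


RUNNER_DEFAULTS = GroupSpec(name="runner")
CONTROL_DEFAULTS = GroupSpec(
    name="control",
    length_mean=57.0,
    length_sd=9.0,
    csa_mean=65.0,
    csa_sd=10.0,
    distal_excess_mean=0.20,
    distal_excess_sd=0.08,
    moment_arm_mean=4.9,
    moment_arm_sd=0.5,
    modulus_mean=0.39,
    modulus_sd=0.12,
    t2star_mean=8.0,
    t2star_sd=1.5,
    mvc_mean=81.7,
    mvc_sd=19.9,
)


@dataclass(frozen=True)
class CohortSpec:
    """Two-arm cohort description with acquisition noise settings."""

    runners: GroupSpec = RUNNER_DEFAULTS
    controls: GroupSpec = CONTROL_DEFAULTS
    contour_noise_sd: float = 0.1  # mm
    dome_noise_sd: float = 0.1  # mm
    echo_snr: float = 50.0
    echo_times: tuple = ECHO_TIMES_QLD_MS
    torque_noise_sd: float = 1.0  # Nm
    length_noise_sd: float = 0.05  # mm
    toe_strain_limit: float = 0.005
    seed: int = 0


@dataclass
class Subject:
    """All generated inputs plus the truth record for one subject."""

    subject_id: str
    group: Literal["runner", "control"]
    sparse_contours: ContourStack
    geometry_truth: GeometryMetrics
    dome_points: np.ndarray
    tendon_centroid_points: np.ndarray
    echo_series: EchoSeries
    echo_mask: np.ndarray
    mechanics: SubjectRecord
    truth: dict


@dataclass
class Cohort:
    spec: CohortSpec
    subjects: list[Subject]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"subject_id": s.subject_id, "group": s.group, **s.truth}
                             for s in self.subjects])


def _draw_group(gspec: GroupSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Per-subject parameter draws for one arm (truncated to physical
    ranges; T2* and modulus share a Gaussian copula)."""
    n = gspec.n
    rho = gspec.t2star_modulus_corr
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    df = pd.DataFrame(
        {
            "length_mm": np.clip(
                rng.normal(gspec.length_mean, gspec.length_sd, n), 20.0, None
            ),
            "csa_mm2": np.clip(rng.normal(gspec.csa_mean, gspec.csa_sd, n), 25.0, None),
            "distal_excess": np.clip(
                rng.normal(gspec.distal_excess_mean, gspec.distal_excess_sd, n),
                0.0,
                None,
            ),
            "moment_arm_cm": np.clip(
                rng.normal(gspec.moment_arm_mean, gspec.moment_arm_sd, n), 2.0, None
            ),
            "t2star_ms": np.clip(gspec.t2star_mean + gspec.t2star_sd * z[:, 0], 1.0, None),
            "modulus_GPa": np.clip(
                gspec.modulus_mean + gspec.modulus_sd * z[:, 1], 0.08, None
            ),
            "mvc_Nm": np.clip(rng.normal(gspec.mvc_mean, gspec.mvc_sd, n), 30.0, None),
        }
    )
    if gspec.stiffness_mean is None:
        df["stiffness_N_per_mm"] = (
            1000.0 * df["modulus_GPa"] * df["csa_mm2"] / df["length_mm"]
        )
    else:
        df["stiffness_N_per_mm"] = np.clip(
            rng.normal(gspec.stiffness_mean, gspec.stiffness_sd, n), 50.0, None
        )
    return df


def _phantom_radii(avg_csa: float, distal_excess: float) -> tuple[float, float]:
    """Distal/proximal radii of a linear-taper tube whose mean area is
    ``avg_csa`` and whose distal area exceeds the proximal by the given
    fraction."""
    shrink = (1.0 + distal_excess) ** -0.5  # proximal/distal radius ratio
    c = 1.0 - shrink
    # mean area = pi r0^2 (1 - c + c^2/3)
    r0 = np.sqrt(avg_csa / (np.pi * (1.0 - c + c**2 / 3.0)))
    return float(r0), float(r0 * shrink)


def make_cohort(spec: CohortSpec = CohortSpec()) -> Cohort:
    """Generate a full two-arm cohort: every module input plus truth.

    The talar dome is built in a canonical frame (axis = x-axis) with the
    tendon phantom translated so the constructed moment arm is exact, then
    both are mapped through a per-subject random rigid pose, so the
    moment-arm stage sees realistically oriented data with known truth.
    """
    root = np.random.SeedSequence(spec.seed)
    subjects: list[Subject] = []
    for gspec in (spec.runners, spec.controls):
        gseed = root.spawn(1)[0]
        rng = np.random.default_rng(gseed)
        params = _draw_group(gspec, rng)
        for i, row in params.iterrows():
            sid = f"{gspec.name[0].upper()}{i:02d}"
            sub_rng = np.random.default_rng(gseed.spawn(1)[0])
            seed_of = lambda: int(sub_rng.integers(0, 2**31 - 1))

            rd, rp = _phantom_radii(row["csa_mm2"], row["distal_excess"])
            phantom_spec = TendonPhantomSpec(
                length=row["length_mm"],
                distal_radius=rd,
                proximal_radius=rp,
                ellipticity=1.4,
                contour_noise_sd=spec.contour_noise_sd,
                n_sparse_slices=int(sub_rng.integers(6, 9)),
                seed=seed_of(),
            )
            sparse, truth_geom = make_tendon_phantom(phantom_spec)

            # canonical frame: dome axis along x, tendon line along z at the
            # constructed moment-arm offset in y
            pose = random_rigid_pose(seed_of())
            arm_mm = row["moment_arm_cm"] * 10.0
            dome = make_dome_points(
                radius=10.0,
                arc_deg=120.0,
                axial_extent=25.0,
                noise_sd=spec.dome_noise_sd,
                n=400,
                seed=seed_of(),
            )
            t_line = np.linspace(-truth_geom.length / 2.0, truth_geom.length / 2.0, 25)
            centroid_line = np.column_stack(
                [np.zeros_like(t_line), np.full_like(t_line, arm_mm), t_line]
            )
            dome = apply_pose(dome, pose)
            centroid_line = apply_pose(centroid_line, pose)

            grid = np.zeros((12, 12))
            yy, xx = np.mgrid[:12, :12]
            mask2d = (yy - 5.5) ** 2 + (xx - 5.5) ** 2 <= 4.0**2
            s0 = 100.0
            echo = make_multiecho_stack(
                t2star_map=np.full(grid.shape, row["t2star_ms"]),
                s0_map=np.full(grid.shape, s0),
                bias=5.0,
                echo_times=np.asarray(spec.echo_times),
                noise_sd=s0 / spec.echo_snr,
                seed=seed_of(),
            )

            record, mech_truth = make_load_series(
                true_stiffness=row["stiffness_N_per_mm"],
                toe_strain_limit=spec.toe_strain_limit,
                L0=row["length_mm"],
                csa0=row["csa_mm2"],
                moment_arm=row["moment_arm_cm"],
                mvc_torque=row["mvc_Nm"],
                torque_noise_sd=spec.torque_noise_sd,
                length_noise_sd=spec.length_noise_sd,
                subject_id=sid,
                group=gspec.name,
                seed=seed_of(),
            )

            subjects.append(
                Subject(
                    subject_id=sid,
                    group=gspec.name,
                    sparse_contours=sparse,
                    geometry_truth=truth_geom,
                    dome_points=dome,
                    tendon_centroid_points=centroid_line,
                    echo_series=echo,
                    echo_mask=mask2d,
                    mechanics=record,
                    truth={
                        **{k: float(v) for k, v in row.items()},
                        **mech_truth,
                        "truth_volume_mm3": truth_geom.volume,
                    },
                )
            )
    return Cohort(spec=spec, subjects=subjects)
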