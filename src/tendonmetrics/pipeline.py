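"""End-to-end orchestration: geometry -> moment arm -> T2* -> mechanics ->
group statistics, over an on-disk cohort tree or an in-memory synthetic
cohort.

Cohort directory layout (written by ``tendonmetrics simulate`` and consumed
by ``tendonmetrics run``)::

    <dir>/
      subjects.csv            subject_id, group, moment_arm_cm, mvc_torque_Nm
      truth.json              generator ground truth (synthetic cohorts only)
      contours/<sid>.csv      sparse tendon contours (slice_index,x_mm,y_mm,z_mm)
      dome/<sid>.csv          talar dome point cloud (x_mm,y_mm,z_mm)
      tendon_line/<sid>.csv   tendon centroid line in the dome's frame
      echo/<sid>.nii(.json)   4D multi-echo stack + echo-time sidecar
      echo/<sid>_mask.nii     binary ROI mask
      mechanics/<sid>.csv     level,torque_load_Nm,torque_rest_Nm,length_mm,csa_mm2

The moment-arm stage uses ``tendon_line/`` when present (tendon centroids
expressed in the same frame as the dome scan); otherwise it falls back to
the centroid line of the densified contour stack.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from tendonmetrics import __version__
from tendonmetrics.geometry import (
    compute_metrics,
    densify_stack,
    read_contours_csv,
    write_contours_csv,
)
from tendonmetrics.mechanics import SubjectRecord, build_load_cases, stiffness_and_modulus
from tendonmetrics.moment_arm import Curve3D, compute_moment_arm
from tendonmetrics.relaxometry import map_roi, read_mask_nifti, read_multiecho_nifti
from tendonmetrics.stats import gated_group_test, pearson_correlation, spm_ttest_profiles
from tendonmetrics.synthetic import Cohort

__all__ = [
    "PipelineConfig",
    "StageError",
    "run_pipeline",
    "write_cohort",
    "analyze_cohort",
]

log = logging.getLogger("tendonmetrics")

ALL_STAGES = ("geometry", "momentarm", "t2star", "mechanics", "compare")

SCALAR_ENDPOINTS = (
    "volume_mm3",
    "length_mm",
    "average_csa_mm2",
    "moment_arm_cm",
    "t2star_ms",
    "stiffness_N_per_mm",
    "youngs_modulus_GPa",
    "normalized_stiffness_kN_per_strain",
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for attribution."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (YAML-loadable)."""

    input_dir: str
    output_dir: str
    stages: tuple[str, ...] = ALL_STAGES
    dense_spacing_mm: float = 0.27
    n_permutations: int = 2000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; valid: {ALL_STAGES}")
        if self.dense_spacing_mm <= 0:
            raise ValueError("dense_spacing_mm must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        self.stages = tuple(self.stages)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        payload.update({k: v for k, v in overrides.items() if v is not None})
        try:
            return cls(**payload)
        except TypeError as exc:
            raise ValueError(f"invalid config {path}: {exc}") from None


# ---------------------------------------------------------------------------
# cohort tree I/O


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write every input file a synthetic cohort provides (see module
    docstring for the layout)."""
    import nibabel as nib

    out = Path(out_dir)
    for sub in ("contours", "dome", "tendon_line", "echo", "mechanics"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    rows = []
    for s in cohort.subjects:
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "moment_arm_cm": s.mechanics.moment_arm,
                "mvc_torque_Nm": s.mechanics.mvc_torque,
            }
        )
        write_contours_csv(s.sparse_contours, out / "contours" / f"{s.subject_id}.csv")
        pd.DataFrame(s.dome_points, columns=["x_mm", "y_mm", "z_mm"]).to_csv(
            out / "dome" / f"{s.subject_id}.csv", index=False
        )
        pd.DataFrame(
            s.tendon_centroid_points, columns=["x_mm", "y_mm", "z_mm"]
        ).to_csv(out / "tendon_line" / f"{s.subject_id}.csv", index=False)
        vol = s.echo_series.signal.reshape(
            s.echo_series.voxel_grid + (1,) * (3 - len(s.echo_series.voxel_grid))
            + (len(s.echo_series.echo_times),)
        )
        nib.save(
            nib.Nifti1Image(vol.astype(np.float64), np.eye(4)),
            str(out / "echo" / f"{s.subject_id}.nii"),
        )
        (out / "echo" / f"{s.subject_id}.json").write_text(
            json.dumps({"echo_times_ms": s.echo_series.echo_times.tolist()})
        )
        mask_vol = np.atleast_3d(s.echo_mask.astype(np.uint8))
        nib.save(
            nib.Nifti1Image(mask_vol, np.eye(4)),
            str(out / "echo" / f"{s.subject_id}_mask.nii"),
        )
        s.mechanics.measurements.to_csv(
            out / "mechanics" / f"{s.subject_id}.csv", index=False
        )
    pd.DataFrame(rows).to_csv(out / "subjects.csv", index=False)
    (out / "truth.json").write_text(
        cohort.truth_frame().to_json(orient="records", indent=2)
    )
    return out


# ---------------------------------------------------------------------------
# in-memory cohort analysis (used by the synthetic end-to-end checks)


def analyze_cohort(
    cohort: Cohort,
    dense_spacing_mm: float = 0.27,
    n_permutations: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Run every measurement stage on an in-memory synthetic cohort.

    Returns the per-subject endpoint table and a statistics dict (gated
    group tests per scalar endpoint, SPM over CSA profiles, and the Pearson
    correlation between T2* and Young's modulus).
    """
    rows = []
    profiles: dict[str, list] = {"runner": [], "control": []}
    for s in cohort.subjects:
        dense = densify_stack(s.sparse_contours, dense_spacing_mm)
        geom = compute_metrics(dense)
        arm = compute_moment_arm(s.dome_points, Curve3D(s.tendon_centroid_points))
        t2 = map_roi(s.echo_series, s.echo_mask)
        mech = stiffness_and_modulus(build_load_cases(s.mechanics))
        profiles[s.group].append(geom.csa_profile)
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "volume_mm3": geom.volume,
                "length_mm": geom.length,
                "average_csa_mm2": geom.average_csa,
                "moment_arm_cm": arm.moment_arm,
                "t2star_ms": t2.roi_mean_t2star,
                "t2star_n_excluded": t2.n_excluded,
                "stiffness_N_per_mm": mech.stiffness,
                "youngs_modulus_GPa": mech.youngs_modulus,
                "normalized_stiffness_kN_per_strain": mech.normalized_stiffness,
            }
        )
    table = pd.DataFrame(rows)
    stats = _compare_groups(table, profiles, n_permutations, alpha, seed)
    return table, stats


def _compare_groups(table, profiles, n_permutations, alpha, seed) -> dict:
    runners = table[table["group"] == "runner"]
    controls = table[table["group"] == "control"]
    results: dict = {"endpoints": {}}
    for endpoint in SCALAR_ENDPOINTS:
        if endpoint not in table.columns:
            continue
        res = gated_group_test(
            runners[endpoint].to_numpy(), controls[endpoint].to_numpy(), alpha=alpha
        )
        diff = float(runners[endpoint].mean() - controls[endpoint].mean())
        results["endpoints"][endpoint] = {
            **res.to_dict(),
            "runner_mean": float(runners[endpoint].mean()),
            "control_mean": float(controls[endpoint].mean()),
            "difference": diff,
        }
    if profiles["runner"] and profiles["control"]:
        spm = spm_ttest_profiles(
            profiles["runner"],
            profiles["control"],
            n_permutations=n_permutations,
            alpha=alpha,
            seed=seed,
        )
        results["spm_regional_csa"] = {
            "critical_threshold": spm.critical_threshold,
            "clusters": [
                {"start_percent": s, "end_percent": e, "p": p}
                for s, e, p in spm.clusters
            ],
            "method": spm.method,
        }
        results["_spm_result"] = spm
    if {"t2star_ms", "youngs_modulus_GPa"}.issubset(table.columns):
        r, p = pearson_correlation(
            table["t2star_ms"].to_numpy(), table["youngs_modulus_GPa"].to_numpy()
        )
        results["pearson_t2star_vs_modulus"] = {"r": r, "p": p}
    return results


# ---------------------------------------------------------------------------
# file-based pipeline


def _load_subject_frame(input_dir: Path) -> pd.DataFrame:
    path = input_dir / "subjects.csv"
    if not path.exists():
        raise StageError("inputs", f"missing subject table {path}")
    df = pd.read_csv(path)
    required = {"subject_id", "group", "moment_arm_cm"}
    if not required.issubset(df.columns):
        raise StageError("inputs", f"{path} needs columns {sorted(required)}")
    return df


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages over an on-disk cohort tree.

    Writes per-subject JSON reports, a cohort CSV, a statistics JSON and an
    SPM curve CSV under ``config.output_dir``, plus a log with versions and
    the full parameter echo.  Raises :class:`StageError` on any stage
    failure (nothing partial is left in the cohort CSV).
    """
    input_dir = Path(config.input_dir)
    out = Path(config.output_dir)
    (out / "subjects").mkdir(parents=True, exist_ok=True)
    _setup_log(out)
    log.info(
        "tendonmetrics %s | stages=%s spacing=%.4g perms=%d alpha=%.3g seed=%d",
        __version__, ",".join(config.stages), config.dense_spacing_mm,
        config.n_permutations, config.alpha, config.seed,
    )

    subjects = _load_subject_frame(input_dir)
    rows = []
    profiles: dict[str, list] = {"runner": [], "control": []}
    for _, meta in subjects.iterrows():
        sid = str(meta["subject_id"])
        row: dict = {"subject_id": sid, "group": meta["group"]}
        geom = None
        if "geometry" in config.stages:
            try:
                stack = read_contours_csv(input_dir / "contours" / f"{sid}.csv")
                dense = densify_stack(stack, config.dense_spacing_mm)
                geom = compute_metrics(dense)
            except Exception as exc:
                raise StageError("geometry", f"subject {sid}: {exc}") from exc
            row.update(
                volume_mm3=geom.volume,
                length_mm=geom.length,
                average_csa_mm2=geom.average_csa,
            )
            profiles.setdefault(str(meta["group"]), []).append(geom.csa_profile)
        if "momentarm" in config.stages:
            try:
                dome = pd.read_csv(input_dir / "dome" / f"{sid}.csv").to_numpy(float)
                line_path = input_dir / "tendon_line" / f"{sid}.csv"
                if line_path.exists():
                    line = Curve3D(pd.read_csv(line_path).to_numpy(float))
                elif geom is not None:
                    dense = densify_stack(
                        read_contours_csv(input_dir / "contours" / f"{sid}.csv"),
                        config.dense_spacing_mm,
                    )
                    line = Curve3D(dense.centroids())
                else:
                    raise FileNotFoundError(f"no tendon line for {sid}")
                arm = compute_moment_arm(dome, line)
            except StageError:
                raise
            except Exception as exc:
                raise StageError("momentarm", f"subject {sid}: {exc}") from exc
            row["moment_arm_cm"] = arm.moment_arm
        if "t2star" in config.stages:
            try:
                series = read_multiecho_nifti(
                    input_dir / "echo" / f"{sid}.nii",
                    input_dir / "echo" / f"{sid}.json",
                )
                mask = read_mask_nifti(input_dir / "echo" / f"{sid}_mask.nii")
                t2 = map_roi(series, mask)
            except Exception as exc:
                raise StageError("t2star", f"subject {sid}: {exc}") from exc
            row["t2star_ms"] = t2.roi_mean_t2star
            row["t2star_n_excluded"] = t2.n_excluded
        if "mechanics" in config.stages:
            try:
                meas = pd.read_csv(input_dir / "mechanics" / f"{sid}.csv")
                record = SubjectRecord(
                    subject_id=sid,
                    group=meta["group"],
                    moment_arm=float(meta["moment_arm_cm"]),
                    mvc_torque=float(meta.get("mvc_torque_Nm", np.nan)),
                    measurements=meas,
                )
                mech = stiffness_and_modulus(build_load_cases(record))
            except Exception as exc:
                raise StageError("mechanics", f"subject {sid}: {exc}") from exc
            row.update(
                stiffness_N_per_mm=mech.stiffness,
                youngs_modulus_GPa=mech.youngs_modulus,
                normalized_stiffness_kN_per_strain=mech.normalized_stiffness,
            )
        rows.append(row)
        (out / "subjects" / f"{sid}.json").write_text(
            json.dumps(row, indent=2, sort_keys=True)
        )
        log.info("subject %s done", sid)

    table = pd.DataFrame(rows)
    table.to_csv(out / "cohort.csv", index=False)
    report: dict = {"n_subjects": len(table)}
    if "compare" in config.stages:
        try:
            stats = _compare_groups(
                table, profiles, config.n_permutations, config.alpha, config.seed
            )
        except Exception as exc:
            raise StageError("compare", str(exc)) from exc
        spm = stats.pop("_spm_result", None)
        if spm is not None:
            spm.to_dataframe().to_csv(out / "spm_regional_csa.csv", index=False)
        (out / "statistics.json").write_text(
            json.dumps(stats, indent=2, sort_keys=True)
        )
        report["statistics"] = stats
    report["cohort_csv"] = str(out / "cohort.csv")
    log.info("pipeline complete: %d subjects", len(table))
    return report


def _setup_log(out: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers = [
        logging.StreamHandler(sys.stderr),
        logging.FileHandler(out / "pipeline.log", mode="w"),
    ]
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in log.handlers:
        h.setFormatter(fmt)
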