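"""UTE T2* relaxometry: two-stage mono-exponential-with-bias fitting.

Tendon has a very short effective transverse relaxation time, so magnitude
signal is sampled at ultrashort echo times and modelled per pixel as

    S(TE) = S0 * exp(-TE / T2*) + bias

where the additive ``bias`` absorbs the noise floor/offset.  Fitting is in
two stages, mirroring standard relaxometry practice: a log-linear plain
exponential fit supplies initial parameters, then a Levenberg–Marquardt-style
bounded nonlinear least squares (via lmfit) estimates all three parameters.
ROI summaries average converged, in-bounds pixels only and report how many
pixels were excluded.

Units: echo times and T2* in milliseconds; signal in arbitrary magnitude
units (S0 and bias share the signal scale).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
from lmfit import Model

__all__ = [
    "EchoSeries",
    "PlainFit",
    "T2StarFit",
    "T2StarMap",
    "fit_plain_exponential",
    "fit_biased_exponential",
    "map_roi",
    "read_multiecho_nifti",
    "write_t2star_maps",
    "ECHO_TIMES_ACT_MS",
    "ECHO_TIMES_QLD_MS",
]

# echo-time sets of the two UTE protocols this pipeline targets (ms)
ECHO_TIMES_ACT_MS = (0.18, 2.50, 4.82, 7.14, 9.46)
ECHO_TIMES_QLD_MS = (0.21, 1.86, 3.51, 5.15, 6.80, 8.45, 10.09)

T2STAR_BOUNDS_MS = (0.01, 200.0)


@dataclass(frozen=True)
class EchoSeries:
    """A multi-echo magnitude stack.

    ``signal`` has the echo dimension last (spatial dims + echo); for a
    single pixel a 1D array of per-echo values is fine.
    """

    echo_times: np.ndarray  # ms, strictly increasing
    signal: np.ndarray

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times, dtype=float)
        sig = np.asarray(self.signal, dtype=float)
        if te.ndim != 1 or len(te) < 4:
            raise ValueError("need >= 4 echo times for a 3-parameter fit")
        if np.any(np.diff(te) <= 0):
            raise ValueError("echo times must strictly increase")
        if sig.shape[-1] != len(te):
            raise ValueError(
                f"signal last axis ({sig.shape[-1]}) must match the number of "
                f"echoes ({len(te)})"
            )
        if np.any(sig < 0):
            raise ValueError("magnitude signal must be non-negative")
        object.__setattr__(self, "echo_times", te)
        object.__setattr__(self, "signal", sig)

    @property
    def voxel_grid(self) -> tuple[int, ...]:
        return self.signal.shape[:-1]


class PlainFit(NamedTuple):
    s0: float
    t2star: float
    decaying: bool  # False when the log-linear slope is non-negative


@dataclass(frozen=True)
class T2StarFit:
    """Single-pixel biased-exponential fit result."""

    s0: float
    t2star: float  # ms
    bias: float
    rmse: float
    converged: bool

    @property
    def at_bound(self) -> bool:
        lo, hi = T2STAR_BOUNDS_MS
        return self.t2star <= lo * (1 + 1e-6) or self.t2star >= hi * (1 - 1e-6)


@dataclass(frozen=True)
class T2StarMap:
    """Per-pixel fits over a masked grid, with the ROI mean T2*.

    ``roi_mean_t2star`` averages converged, in-bounds pixels only;
    ``n_excluded`` counts pixels dropped for non-convergence or a T2* pinned
    at a bound.  Map arrays hold ``nan`` outside the mask.
    """

    t2star: np.ndarray  # ms
    s0: np.ndarray
    bias: np.ndarray
    rmse: np.ndarray
    mask: np.ndarray
    roi_mean_t2star: float
    n_excluded: int

    def summary(self) -> dict:
        return {
            "roi_mean_t2star_ms": self.roi_mean_t2star,
            "n_pixels": int(self.mask.sum()),
            "n_excluded": self.n_excluded,
        }


def _model(te, s0, t2star, bias):
    return s0 * np.exp(-te / t2star) + bias


_BIASED_MODEL = Model(_model, independent_vars=["te"])


def fit_plain_exponential(
    signal: np.ndarray, echo_times: np.ndarray
) -> PlainFit:
    """Log-linear least-squares fit of ``S = S0 exp(-TE/T2*)``.

    Used to initialise the biased fit.  Regresses ``ln S`` on TE over echoes
    with positive signal; S0 is the exponentiated intercept and T2* is
    ``-1/slope``.  A non-negative slope (no decay) is flagged via
    ``decaying=False``; T2* is then reported as ``inf``.
    """
    sig = np.asarray(signal, dtype=float)
    te = np.asarray(echo_times, dtype=float)
    if sig.shape != te.shape or sig.ndim != 1 or len(sig) < 3:
        raise ValueError("need matching 1D signal/echo arrays with >= 3 echoes")
    pos = sig > 0
    if not np.any(pos):
        raise ValueError("all-zero signal: nothing to fit")
    if pos.sum() < 2:
        return PlainFit(s0=float(sig.max()), t2star=np.inf, decaying=False)
    slope, intercept = np.polyfit(te[pos], np.log(sig[pos]), 1)
    if slope >= -1e-10:  # flat within float error: no measurable decay
        return PlainFit(s0=float(np.exp(intercept)), t2star=np.inf, decaying=False)
    return PlainFit(
        s0=float(np.exp(intercept)), t2star=float(-1.0 / slope), decaying=True
    )


def fit_biased_exponential(
    signal: np.ndarray,
    echo_times: np.ndarray,
    init: tuple[float, float] | PlainFit | None = None,
) -> T2StarFit:
    """Bounded nonlinear fit of ``S = S0 exp(-TE/T2*) + bias``.

    ``init`` supplies (S0, T2*) starting values, normally from
    :func:`fit_plain_exponential`; when omitted, that plain fit is run first.
    Bounds: T2* in (0.01, 200] ms, S0 > 0, bias >= 0.  ``converged`` reflects
    the optimiser status; parameters are returned best-effort either way.
    """
    sig = np.asarray(signal, dtype=float)
    te = np.asarray(echo_times, dtype=float)
    if init is None:
        init = fit_plain_exponential(sig, te)
    s0_init, t2_init = float(init[0]), float(init[1])
    lo, hi = T2STAR_BOUNDS_MS
    if not np.isfinite(t2_init):
        t2_init = te[-1]  # non-decaying start: slowest plausible decay
    t2_init = float(np.clip(t2_init, lo * 1.01, hi))
    s0_init = max(s0_init, 1e-9)

    # start the bias at the long-TE signal floor: initialising exactly at the
    # zero bound can stall the bounded Levenberg-Marquardt transform
    bias_init = max(float(sig.min()) * 0.5, 1e-6)
    params = _BIASED_MODEL.make_params(
        s0=dict(value=s0_init, min=1e-12),
        t2star=dict(value=t2_init, min=lo, max=hi),
        bias=dict(value=bias_init, min=0.0),
    )
    try:
        result = _BIASED_MODEL.fit(sig, params, te=te)
    except Exception:
        return T2StarFit(
            s0=s0_init, t2star=t2_init, bias=0.0, rmse=np.inf, converged=False
        )
    p = result.params
    rmse = float(np.sqrt(np.mean(result.residual**2)))
    return T2StarFit(
        s0=float(p["s0"].value),
        t2star=float(p["t2star"].value),
        bias=float(p["bias"].value),
        rmse=rmse,
        converged=bool(result.success),
    )


def map_roi(series: EchoSeries, mask: np.ndarray) -> T2StarMap:
    """Two-stage T2* fit at every in-mask pixel of a multi-echo stack.

    The ROI mean averages converged pixels whose T2* is strictly inside the
    fit bounds; other in-mask pixels are excluded and counted in
    ``n_excluded``.
    """
    m = np.asarray(mask).astype(bool)
    if m.shape != series.voxel_grid:
        raise ValueError(
            f"mask shape {m.shape} does not match voxel grid {series.voxel_grid}"
        )
    if not m.any():
        raise ValueError("empty ROI mask")

    shape = series.voxel_grid
    maps = {k: np.full(shape, np.nan) for k in ("t2star", "s0", "bias", "rmse")}
    kept: list[float] = []
    n_excluded = 0
    for idx in zip(*np.nonzero(m)):
        fit = fit_biased_exponential(series.signal[idx], series.echo_times)
        maps["t2star"][idx] = fit.t2star
        maps["s0"][idx] = fit.s0
        maps["bias"][idx] = fit.bias
        maps["rmse"][idx] = fit.rmse
        if fit.converged and not fit.at_bound:
            kept.append(fit.t2star)
        else:
            n_excluded += 1
    if not kept:
        raise ValueError("no pixel in the ROI produced a usable fit")
    return T2StarMap(
        t2star=maps["t2star"],
        s0=maps["s0"],
        bias=maps["bias"],
        rmse=maps["rmse"],
        mask=m,
        roi_mean_t2star=float(np.mean(kept)),
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# NIfTI interchange


def read_multiecho_nifti(
    image_path: str | Path, sidecar_path: str | Path
) -> EchoSeries:
    """Load a 4D (x, y, z, echo) NIfTI plus a JSON sidecar with
    ``{"echo_times_ms": [...]}``."""
    import nibabel as nib

    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{image_path}: expected a 4D multi-echo stack")
    sidecar = json.loads(Path(sidecar_path).read_text())
    return EchoSeries(echo_times=np.asarray(sidecar["echo_times_ms"]), signal=data)


def read_mask_nifti(path: str | Path) -> np.ndarray:
    import nibabel as nib

    return np.asarray(nib.load(str(path)).dataobj) > 0.5


def write_t2star_maps(t2map: T2StarMap, out_dir: str | Path) -> dict:
    """Write t2star/s0/bias/rmse as 3D NIfTI volumes plus a JSON summary.

    Returns the summary dict that was written.
    """
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    for name, arr in (
        ("t2star", t2map.t2star),
        ("s0", t2map.s0),
        ("bias", t2map.bias),
        ("rmse", t2map.rmse),
    ):
        vol = np.atleast_3d(arr).astype(np.float64)
        nib.save(nib.Nifti1Image(vol, affine), str(out / f"{name}.nii"))
    summary = t2map.summary()
    (out / "t2star_summary.json").write_text(json.dumps(summary, indent=2))
    return summary
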