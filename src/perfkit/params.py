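"""Perfusion parameters from deconvolved residues and raw curves.

Deconvolution-based: CBF = max(k)/rho (the maximum, not k(0), so bolus
delay does not bias the estimate), CBV = integral of k / rho, MTT =
integral / max (the central volume theorem holds exactly because the same
max and integral are reused), TMAX = argmax_t k(t).  Curve-based
(nondeconvolution): TTP, c_max, first moment, BAT, the maximum-slope CBF
and the AUC-ratio / peak-ratio CBV estimators.  ``map_volume`` applies a
chosen method voxelwise to produce parameter maps.

Clinical units: CBF in mL/100 g/min, CBV in mL/100 g, times in seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional

import numpy as np

from . import deconv
from .deconv import RegularizationSpec, SystemMatrix, build_system_matrix
from .kinetics import (
    CBF_UNIT_FACTOR,
    ConcentrationCurve,
    FlowScaledResidue,
    TimeGrid,
)
from .preprocess import VoxelMask, detect_bat

__all__ = [
    "PerfusionParameterSet",
    "ParameterMap",
    "MapConfig",
    "cbf_from_k",
    "cbv_from_k",
    "mtt_from_k",
    "tmax_of_k",
    "curve_params",
    "max_slope_cbf",
    "cbv_auc_ratio",
    "cbv_peak_ratio",
    "blood_volume_fraction",
    "map_volume",
]

#: controlled vocabulary of map units
UNITS = {
    "cbf": "mL/100g/min",
    "cbv": "mL/100g",
    "mtt": "s",
    "tmax": "s",
    "ttp": "s",
    "bat": "s",
    "fm": "s",
    "cmax": "concentration",
}


@dataclass
class PerfusionParameterSet:
    """All per-voxel perfusion parameters; NaN marks an invalid estimate."""

    cbf: float = float("nan")
    cbv: float = float("nan")
    mtt: float = float("nan")
    ttp: float = float("nan")
    tmax: float = float("nan")
    bat: float = float("nan")
    fm: float = float("nan")
    c_max: float = float("nan")

    def as_dict(self) -> Dict[str, float]:
        return {
            "cbf": self.cbf,
            "cbv": self.cbv,
            "mtt": self.mtt,
            "ttp": self.ttp,
            "tmax": self.tmax,
            "bat": self.bat,
            "fm": self.fm,
            "cmax": self.c_max,
        }


@dataclass
class ParameterMap:
    """One named 3D parameter volume with units, mask and provenance."""

    name: str
    values: np.ndarray
    units: str
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("parameter map must be 3D")
        if self.units not in set(UNITS.values()):
            raise ValueError(f"unit {self.units!r} not in controlled vocabulary")


def _k_stats(k: FlowScaledResidue, clip_negative: bool) -> tuple[float, float]:
    """(max, trapezoid integral) of k, with optional clipping of negative
    regularization artifacts in the integral only."""
    v = k.values
    kmax = float(v.max())
    vi = np.clip(v, 0.0, None) if clip_negative else v
    integral = float(np.trapezoid(vi, dx=k.grid.dt))
    return kmax, integral


def cbf_from_k(k: FlowScaledResidue, rho: float = 1.04) -> float:
    """CBF = max(k)/rho, converted to mL/100 g/min; NaN when max(k) <= 0.

    The first index attaining the maximum defines TMAX on plateaus."""
    kmax = float(k.values.max())
    if kmax <= 0:
        return float("nan")
    return kmax / rho * CBF_UNIT_FACTOR


def cbv_from_k(
    k: FlowScaledResidue, rho: float = 1.04, clip_negative: bool = True
) -> float:
    """CBV = integral of k / rho in mL/100 g (trapezoid rule; negative
    regularization ripples are clipped from the integral by default).
    Warns when k has not decayed by the grid end (truncated integral)."""
    kmax, integral = _k_stats(k, clip_negative)
    if kmax > 0 and k.values[-1] > 0.05 * kmax:
        warnings.warn("k not decayed at grid end; CBV integral truncated", stacklevel=2)
    if integral < 0:
        return float("nan")
    return integral / rho * 100.0


def mtt_from_k(k: FlowScaledResidue, clip_negative: bool = True) -> float:
    """MTT = integral of k / max(k) in seconds (same integral and maximum
    as the CBV/CBF estimates, so CBF = CBV/MTT holds exactly)."""
    kmax, integral = _k_stats(k, clip_negative)
    if kmax <= 0:
        return float("nan")
    return integral / kmax


def tmax_of_k(k: FlowScaledResidue) -> float:
    """TMAX = argmax_t k(t); first index on plateaus; NaN for max(k) <= 0."""
    v = k.values
    if v.max() <= 0:
        return float("nan")
    return float(k.grid.times[int(np.argmax(v))])


def curve_params(
    c: ConcentrationCurve,
    noise_sd: float = 0.0,
    z: float = 3.0,
    m: int = 2,
) -> tuple[float, float, float, float]:
    """Nondeconvolution curve descriptors (ttp, c_max, fm, bat).

    TTP is the time of the (first) maximum, FM the first moment of the
    curve (AUC centroid projected on the time axis; NaN when the AUC is
    not positive), BAT via the threshold detector.
    """
    v = c.values
    t = c.grid.times
    ttp = float(t[int(np.argmax(v))])
    c_max = float(v.max())
    auc = float(np.trapezoid(v, t))
    fm = float(np.trapezoid(v * t, t) / auc) if auc > 0 else float("nan")
    bat = detect_bat(c, noise_sd, z=z, m=m)
    return ttp, c_max, fm, bat


def _moving_average3(v: np.ndarray) -> np.ndarray:
    kernel = np.ones(3) / 3.0
    return np.convolve(np.pad(v, 1, mode="edge"), kernel, mode="valid")


def max_slope_cbf(
    c_voi: ConcentrationCurve,
    c_art: ConcentrationCurve,
    rho: float = 1.04,
    smooth: bool = False,
) -> float:
    """Maximum-slope CBF: max d(c_voi)/dt divided by rho * max(c_art),
    in mL/100 g/min.  Central differences, optional 3-point pre-smoothing.

    Valid under a no-venous-outflow assumption (fast injection, short
    observation); with realistic transit times it underestimates the
    deconvolution CBF.
    """
    if c_voi.grid != c_art.grid:
        raise ValueError("curves must share one grid")
    peak_a = float(c_art.values.max())
    if peak_a <= 0:
        raise ValueError("max of the arterial curve must be positive")
    v = _moving_average3(c_voi.values) if smooth else c_voi.values
    slope = float(np.gradient(v, c_voi.grid.dt).max())
    return slope / (rho * peak_a) * CBF_UNIT_FACTOR


def cbv_auc_ratio(
    c_voi: ConcentrationCurve, c_ref: ConcentrationCurve, rho: float = 1.04
) -> float:
    """AUC-ratio CBV = (AUC of tissue / AUC of arterial-or-venous
    reference) / rho, in mL/100 g.  Mass conservation makes arterial and
    venous references equivalent on fully decayed curves."""
    auc_ref = c_ref.auc()
    if auc_ref <= 0:
        raise ValueError("reference curve AUC must be positive")
    return c_voi.auc() / auc_ref / rho * 100.0


def cbv_peak_ratio(c_voi: ConcentrationCurve, c_ven: ConcentrationCurve) -> float:
    """Peak-ratio blood-volume approximation max(c_voi)/max(c_ven)
    (dimensionless, mL/mL-like).  A coarser stand-in for the AUC ratio
    that avoids integration; not unit-matched to cbv_auc_ratio."""
    peak_v = float(c_ven.values.max())
    if peak_v <= 0:
        raise ValueError("max of the venous curve must be positive")
    return float(c_voi.values.max()) / peak_v


def blood_volume_fraction(cbv: float, rho: float = 1.0) -> float:
    """Blood (vascular) volume fraction in percent: CBV [mL/100 g] times
    tissue density [g/mL] gives mL of blood per 100 mL of tissue; grey
    matter at CBV = 4 mL/100 g and rho = 1 g/mL yields the typical 4%."""
    return cbv * rho


@dataclass(frozen=True)
class MapConfig:
    """Voxelwise mapping configuration: system-matrix kind, regularization,
    tissue density and noise level for BAT detection."""

    matrix: str = "toeplitz"  # "toeplitz" | "circulant"
    spec: RegularizationSpec = RegularizationSpec()
    rho: float = 1.04
    noise_sd: float = 0.0
    clip_negative: bool = True


def map_volume(
    conc: np.ndarray,
    aif: ConcentrationCurve,
    mask: VoxelMask,
    grid: TimeGrid,
    cfg: MapConfig = MapConfig(),
) -> Dict[str, ParameterMap]:
    """Apply deconvolution + parameter extraction per masked voxel.

    The system matrix and its SVD are factorized once per volume; with a
    fixed regularization parameter the filtered solve is a dense matrix
    product over all voxels at once.  Per-voxel failures (invalid k,
    non-finite curves) become NaN in the maps and are counted in the
    provenance, never silently dropped.
    """
    if not mask.values.any():
        raise ValueError("empty mask")
    if conc.shape[:3] != mask.values.shape or conc.shape[3] != grid.n:
        raise ValueError("concentration array, mask and grid shapes disagree")
    A = build_system_matrix(aif, cfg.matrix)
    curves = conc[mask.values]  # (n_vox, n_t)
    finite = np.all(np.isfinite(curves), axis=1)

    names = list(UNITS)
    out_flat = {p: np.full(curves.shape[0], np.nan) for p in names}
    n_failed = 0
    lambdas = []
    for i in range(curves.shape[0]):
        if not finite[i]:
            n_failed += 1
            continue
        c = ConcentrationCurve(grid, curves[i], "tissue")
        k = deconv.regularized_solution(A, c, cfg.spec)
        lambdas.append(k.diagnostics["lambda_rel_used"])
        out_flat["cbf"][i] = cbf_from_k(k, cfg.rho)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out_flat["cbv"][i] = cbv_from_k(k, cfg.rho, cfg.clip_negative)
        out_flat["mtt"][i] = mtt_from_k(k, cfg.clip_negative)
        out_flat["tmax"][i] = tmax_of_k(k)
        ttp, cmx, fm, bat = curve_params(c, cfg.noise_sd)
        out_flat["ttp"][i] = ttp
        out_flat["cmax"][i] = cmx
        out_flat["fm"][i] = fm
        out_flat["bat"][i] = bat
        if np.isnan(out_flat["cbf"][i]):
            n_failed += 1

    provenance = {
        "method": cfg.spec.method,
        "matrix": cfg.matrix,
        "selection": cfg.spec.selection,
        "lambda_rel": cfg.spec.lambda_rel,
        "rho": cfg.rho,
        "n_voxels": int(curves.shape[0]),
        "n_failed": int(n_failed),
    }
    maps: Dict[str, ParameterMap] = {}
    for p in names:
        vol = np.full(mask.values.shape, np.nan)
        vol[mask.values] = out_flat[p]
        maps[p] = ParameterMap(p, vol, UNITS[p], mask.values.copy(), dict(provenance))
    return maps
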