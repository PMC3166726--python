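"""Raw CT/MR dynamic series -> time-concentration curves, plus AIF handling.

Conversion of attenuation (HU) or MR signal to contrast-agent
concentration with baseline subtraction, hematocrit correction, per-frame
Gaussian smoothing, threshold tissue masking, bolus-arrival-time
detection, automatic AIF selection and partial-volume rescaling of the
AIF against a venous reference, and removal of artifact-ridden frames.

Baseline convention: the conversion formulas consume the first B frames
as baseline and index the output as c(t_j) = f(signal(t_{j+B-1})), i.e.
the first B-1 frames are dropped and t = 0 sits at the last baseline
frame, where c = 0 by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .kinetics import ConcentrationCurve, TimeGrid

__all__ = [
    "AcquisitionSeries",
    "ConversionConfig",
    "ConversionResult",
    "VoxelMask",
    "ct_to_concentration",
    "mr_to_concentration",
    "hematocrit_correct",
    "detect_bat",
    "spatial_smooth",
    "tissue_mask",
    "auto_aif",
    "pvc_rescale_aif",
    "drop_frames",
]


@dataclass
class AcquisitionSeries:
    """4D dynamic acquisition (x, y, z, frame): HU for CT, positive signal
    for MR; ``baseline_frames`` frames precede the bolus; MR needs the
    echo time ``te`` (s)."""

    modality: str  # "CT" | "MR"
    data: np.ndarray
    grid: TimeGrid
    baseline_frames: int = 1
    te: Optional[float] = None

    def __post_init__(self) -> None:
        if self.modality not in ("CT", "MR"):
            raise ValueError(f"modality must be CT or MR, got {self.modality!r}")
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 4:
            raise ValueError(f"data must be 4D (x,y,z,frame), got shape {d.shape}")
        if d.shape[3] != self.grid.n:
            raise ValueError("frame count does not match grid.n")
        if not 1 <= self.baseline_frames < self.grid.n:
            raise ValueError("baseline_frames must satisfy 1 <= B < n frames")
        if self.modality == "MR" and (self.te is None or self.te <= 0):
            raise ValueError("MR series needs echo time te > 0")
        self.data = d

    @property
    def n_frames(self) -> int:
        return self.grid.n


@dataclass(frozen=True)
class ConversionConfig:
    """Signal-to-concentration constants: k_ct (g/mL/HU, default 1), k_mr
    (proportionality, default 1; separate blood/tissue knobs default
    equal), hematocrit factor kappa (default 0.73, applied to tissue
    curves only), and per-frame smoothing sigma in voxels."""

    k_ct: float = 1.0
    k_mr: float = 1.0
    k_mr_blood: Optional[float] = None
    kappa: float = 0.73
    apply_hct: bool = True
    smoothing_sigma_vox: float = 0.0

    def __post_init__(self) -> None:
        if self.k_ct <= 0 or self.k_mr <= 0:
            raise ValueError("k_ct and k_mr must be > 0")
        if not 0 < self.kappa <= 1:
            raise ValueError("kappa must lie in (0, 1]")
        if self.smoothing_sigma_vox < 0:
            raise ValueError("smoothing sigma must be >= 0")


@dataclass
class VoxelMask:
    """3D boolean mask aligned with an acquisition's spatial grid."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=bool)
        if v.ndim != 3:
            raise ValueError("mask must be 3D")
        self.values = v

    @property
    def count(self) -> int:
        return int(self.values.sum())


@dataclass
class ConversionResult:
    """Output of the signal-to-concentration conversion: 4D concentration
    (n - B + 1 frames, t = 0 at the last baseline frame), the per-voxel
    baseline map, the output time grid, and a validity mask (MR voxels
    with nonpositive signal are flagged invalid, not clamped)."""

    data: np.ndarray
    baseline: np.ndarray
    grid: TimeGrid
    valid: np.ndarray


def _output_grid(series: AcquisitionSeries) -> TimeGrid:
    return TimeGrid(series.grid.dt, series.grid.n - series.baseline_frames + 1)


def ct_to_concentration(
    series: AcquisitionSeries, cfg: ConversionConfig = ConversionConfig()
) -> ConversionResult:
    """c(t_j) = k_ct * (mu(t_{j+B-1}) - mu0), mu0 = mean of the first B frames."""
    if series.modality != "CT":
        raise ValueError("ct_to_concentration expects a CT series")
    b = series.baseline_frames
    mu0 = series.data[..., :b].mean(axis=3)
    conc = cfg.k_ct * (series.data[..., b - 1 :] - mu0[..., None])
    valid = np.ones(series.data.shape[:3], dtype=bool)
    return ConversionResult(conc, mu0, _output_grid(series), valid)


def mr_to_concentration(
    series: AcquisitionSeries, cfg: ConversionConfig = ConversionConfig()
) -> ConversionResult:
    """c(t_j) = -(k_mr / TE) * ln(s(t_{j+B-1}) / s0), s0 = mean of the
    first B frames.  Voxels with nonpositive signal anywhere in the
    series are flagged invalid (NaN concentration) rather than clamped."""
    if series.modality != "MR":
        raise ValueError("mr_to_concentration expects an MR series")
    b = series.baseline_frames
    s = series.data
    valid = np.all(s > 0, axis=3)
    s0 = s[..., :b].mean(axis=3)
    with np.errstate(divide="ignore", invalid="ignore"):
        conc = -(cfg.k_mr / series.te) * np.log(s[..., b - 1 :] / s0[..., None])
    conc[~valid] = np.nan
    return ConversionResult(conc, s0, _output_grid(series), valid)


def hematocrit_correct(
    curve: ConcentrationCurve, cfg: ConversionConfig = ConversionConfig()
) -> ConcentrationCurve:
    """Multiply tissue curves by the hematocrit factor kappa; arterial and
    venous curves pass through unchanged (the correction compensates the
    artery-vs-capillary plasma-fraction difference, so it applies to
    tissue only)."""
    if curve.label != "tissue" or not cfg.apply_hct:
        return curve
    return ConcentrationCurve(curve.grid, curve.values * cfg.kappa, curve.label)


def detect_bat(
    curve: ConcentrationCurve,
    noise_sd: float = 0.0,
    z: float = 3.0,
    m: int = 2,
) -> float:
    """Bolus arrival time: the last sample before the curve exceeds
    z * noise_sd for m consecutive samples.

    Returns grid-aligned seconds, or NaN when the threshold is never
    exceeded (flat / sub-noise curve).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if m < 1:
        raise ValueError("m must be >= 1")
    v = curve.values
    thr = z * noise_sd
    above = v > thr
    n = v.size
    for j in range(n - m + 1):
        if above[j : j + m].all():
            return float(curve.grid.times[max(j - 1, 0)])
    return float("nan")


def spatial_smooth(data: np.ndarray, sigma_vox: float) -> np.ndarray:
    """Per-frame isotropic Gaussian smoothing of a 4D series; sigma = 0 is
    the identity.  Each time frame is filtered independently, so temporal
    dynamics are untouched."""
    if sigma_vox < 0:
        raise ValueError("sigma must be >= 0")
    data = np.asarray(data, dtype=float)
    if sigma_vox == 0:
        return data.copy()
    out = np.empty_like(data)
    for f in range(data.shape[3]):
        out[..., f] = ndimage.gaussian_filter(data[..., f], sigma=sigma_vox)
    return out


def tissue_mask(
    series: AcquisitionSeries, lo: float = 0.0, hi: float = 100.0
) -> VoxelMask:
    """Voxels whose baseline mean lies in [lo, hi] (CT defaults 0..100 HU
    exclude air, bone and calcifications)."""
    if not lo < hi:
        raise ValueError("lo must be < hi")
    b = series.baseline_frames
    base = series.data[..., :b].mean(axis=3)
    m = (base >= lo) & (base <= hi)
    if not m.any():
        raise ValueError("no tissue voxels within the threshold window")
    return VoxelMask(m)


def auto_aif(
    conc: np.ndarray,
    mask: VoxelMask,
    grid: TimeGrid,
    noise_sd: float = 0.0,
    top_fraction: float = 0.01,
) -> Tuple[ConcentrationCurve, List[Tuple[int, int, int]]]:
    """Heuristic global-AIF selection.

    Scores masked voxels by peak concentration, bolus arrival and first
    moment: a top-decile-by-peak candidate pool is narrowed to its
    earliest-first-moment cluster (arteries lead veins and tissue by
    roughly one mean transit time, so FM separates a partial-volume
    attenuated artery from a brighter vein), then to the brightest
    voxels with BAT at or below the masked median.  The mean curve of
    that cluster is returned.  Deterministic given the input.  Raises
    when fewer than 50 voxels are masked or when no voxel stands out
    against the median peak (no distinguishable artery).
    """
    if mask.count < 50:
        raise ValueError("auto_aif needs at least 50 masked voxels")
    idx = np.argwhere(mask.values)
    curves = conc[mask.values]  # (n_vox, n_t)
    cmax = np.nanmax(curves, axis=1)
    med_peak = float(np.nanmedian(cmax))
    if not np.nanmax(cmax) > 2.0 * max(med_peak, 0.0) or np.nanmax(cmax) <= 0:
        raise ValueError(
            "no distinguishable artery in the field of view; provide the AIF manually"
        )
    order = np.argsort(cmax)[::-1]
    n_pool = max(5, int(np.ceil(0.10 * curves.shape[0])))
    pool = order[:n_pool]
    # earliest-FM cluster of the pool (one-sample tolerance)
    t = grid.times
    fm = np.full(curves.shape[0], np.nan)
    for i in pool:
        auc = np.trapezoid(curves[i], t)
        if auc > 0:
            fm[i] = np.trapezoid(curves[i] * t, t) / auc
    fm_min = np.nanmin(fm[pool])
    early = pool[fm[pool] <= fm_min + grid.dt]
    # brightest of the early cluster; a lone bright artery voxel should
    # not be diluted by dimmer companions
    n_top = max(1, int(np.ceil(top_fraction * curves.shape[0])))
    early = early[np.argsort(cmax[early])[::-1]]
    top = early[:n_top]
    top = top[cmax[top] >= 0.5 * cmax[top[0]]]
    bats = np.array(
        [
            detect_bat(ConcentrationCurve(grid, curves[i], "tissue"), noise_sd)
            for i in range(curves.shape[0])
        ]
    )
    med_bat = np.nanmedian(bats)
    if np.isfinite(med_bat):
        sel = top[np.array([np.isfinite(bats[i]) and bats[i] <= med_bat for i in top])]
        if sel.size == 0:
            sel = top
    else:
        sel = top
    aif_vals = curves[sel].mean(axis=0)
    voxels = [tuple(int(x) for x in idx[i]) for i in sel]
    return ConcentrationCurve(grid, aif_vals, label="arterial"), voxels


def pvc_rescale_aif(
    aif: ConcentrationCurve, vof: ConcentrationCurve
) -> ConcentrationCurve:
    """Partial-volume correction: rescale the AIF so its area matches the
    area under a large venous vessel's curve (mass conservation makes the
    two true areas equal; the venous voxel is assumed free of partial
    volume)."""
    if aif.grid != vof.grid:
        raise ValueError("aif and vof must share one grid")
    auc_a = aif.auc()
    if auc_a <= 0:
        raise ValueError("AIF area under the curve must be positive")
    return ConcentrationCurve(aif.grid, aif.values * (vof.auc() / auc_a), "arterial")


def drop_frames(
    series: AcquisitionSeries, bad_frames: Sequence[int]
) -> AcquisitionSeries:
    """Remove artifact-ridden frames and re-grid onto the uniform grid.

    Interior gaps are filled by linear interpolation in time (the
    deconvolution requires uniform sampling); bad frames at either end
    truncate the series instead of extrapolating.  Baseline-frame count
    is reduced by any truncated leading frames (kept >= 1).
    """
    bad = sorted(set(int(b) for b in bad_frames))
    if not bad:
        return series
    n = series.grid.n
    if any(b < 0 or b >= n for b in bad):
        raise ValueError("bad frame index out of range")
    keep = np.setdiff1d(np.arange(n), bad)
    if keep.size < 4:
        raise ValueError("fewer than 4 frames would remain")
    t = series.grid.times
    t_keep = t[keep]
    # target: original uniform times restricted to the retained range
    first = int(np.searchsorted(t, t_keep[0]))
    last = int(np.searchsorted(t, t_keep[-1], side="right"))
    t_new = t[first:last]
    flat = series.data.reshape(-1, n)
    out = np.empty((flat.shape[0], t_new.size))
    for i in range(flat.shape[0]):
        out[i] = np.interp(t_new, t_keep, flat[i, keep])
    new_data = out.reshape(series.data.shape[:3] + (t_new.size,))
    new_b = max(1, series.baseline_frames - first)
    return AcquisitionSeries(
        modality=series.modality,
        data=new_data,
        grid=TimeGrid(series.grid.dt, t_new.size),
        baseline_frames=new_b,
        te=series.te,
    )
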