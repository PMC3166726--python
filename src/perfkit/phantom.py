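"""Digital perfusion phantom: 4D CT/MR acquisitions with known kinetics.

A gamma-variate bolus model provides the arterial input; each labelled
region carries either tissue kinetics (tissue curve = AIF convolved with
the region's flow-scaled residue), or a vessel role (artery voxels show
the AIF itself, vein voxels the venous outflow, optionally attenuated by
a scalar partial-volume factor).  Region curves are converted to native
scanner signal by inverting the concentration formulas (CT: baseline +
c/k_ct; MR: s0 * exp(-TE c / k_mr)), flat baseline frames are prepended
and seeded Gaussian noise is added in the native signal domain, where
scanner noise actually lives.  Ground-truth parameter maps come along,
so every stage of the analysis pipeline is verifiable without clinical
data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import gamma as gamma_fn
from typing import Dict, Optional

import numpy as np

from .kinetics import (
    ConcentrationCurve,
    TimeGrid,
    TissueKinetics,
    TransitTimeDistribution,
    flow_scaled_residue,
    forward_convolve,
    venous_outflow,
)
from .preprocess import AcquisitionSeries

__all__ = [
    "AIFSpec",
    "RegionSpec",
    "PhantomSpec",
    "GroundTruth",
    "make_aif",
    "make_tissue_curve",
    "render_acquisition",
    "reference_phantom",
]


@dataclass(frozen=True)
class AIFSpec:
    """Gamma-variate bolus c_art(t) = A (t - t0)^alpha exp(-(t - t0)/beta)
    for t > t0, else 0.  The mode sits at t0 + alpha*beta; the analytic
    area is A beta^(alpha+1) Gamma(alpha+1)."""

    amplitude: float = 1.0
    onset: float = 5.0
    shape: float = 3.0
    timescale: float = 1.5

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.timescale <= 0:
            raise ValueError("shape and timescale must be > 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.onset < 0:
            raise ValueError("onset must be >= 0")

    @classmethod
    def with_peak(
        cls, peak: float, onset: float = 5.0, shape: float = 3.0, timescale: float = 1.5
    ) -> "AIFSpec":
        """Amplitude chosen so the curve's maximum equals ``peak``."""
        mode_val = (shape * timescale) ** shape * np.exp(-shape)
        return cls(peak / mode_val, onset, shape, timescale)

    @property
    def analytic_auc(self) -> float:
        return self.amplitude * self.timescale ** (self.shape + 1) * gamma_fn(
            self.shape + 1
        )


@dataclass(frozen=True)
class RegionSpec:
    """One labelled phantom region: either tissue kinetics or a vessel
    role ('artery' | 'vein') with a partial-volume factor in (0, 1]."""

    kinetics: Optional[TissueKinetics] = None
    vessel: Optional[str] = None
    pv_factor: float = 1.0

    def __post_init__(self) -> None:
        if (self.kinetics is None) == (self.vessel is None):
            raise ValueError("region needs exactly one of kinetics or vessel role")
        if self.vessel is not None and self.vessel not in ("artery", "vein"):
            raise ValueError("vessel role must be 'artery' or 'vein'")
        if not 0 < self.pv_factor <= 1:
            raise ValueError("pv_factor must lie in (0, 1]")


@dataclass
class PhantomSpec:
    """Complete description of one synthetic 4D acquisition.

    ``labels`` is a 3D integer volume; ``regions`` maps each label to a
    :class:`RegionSpec`.  ``grid`` is the concentration-time grid (the
    rendered acquisition prepends B - 1 flat baseline frames so the
    conversion recovers these N samples exactly).  ``noise_sd`` is in HU
    for CT and fractional signal units for MR; a seed is mandatory when
    noise is on.
    """

    labels: np.ndarray
    regions: Dict[int, RegionSpec]
    grid: TimeGrid
    aif: AIFSpec = AIFSpec()
    modality: str = "CT"
    baseline: float = 40.0
    baseline_frames: int = 4
    noise_sd: float = 0.0
    te: Optional[float] = None
    k_ct: float = 1.0
    k_mr: float = 1.0
    seed: Optional[int] = None
    venous_dist: TransitTimeDistribution = field(
        default_factory=lambda: TransitTimeDistribution("gamma", shape=4.0, scale=1.0)
    )

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise ValueError("labels must be a 3D volume")
        present = set(np.unique(lab).tolist())
        if not present <= set(self.regions):
            raise ValueError("labels contain ids without a RegionSpec")
        if self.noise_sd > 0 and self.seed is None:
            raise ValueError("seed is mandatory when noise_sd > 0")
        if self.modality not in ("CT", "MR"):
            raise ValueError("modality must be CT or MR")
        if self.modality == "MR" and (self.te is None or self.te <= 0):
            raise ValueError("MR phantom needs te > 0")
        if self.baseline_frames < 1:
            raise ValueError("baseline_frames must be >= 1")
        self.labels = lab


@dataclass
class GroundTruth:
    """Per-region kinetics, per-voxel true parameter maps, and the true
    arterial / venous curves (unattenuated by partial volume)."""

    regions: Dict[int, RegionSpec]
    labels: np.ndarray
    cbf: np.ndarray
    cbv: np.ndarray
    mtt: np.ndarray
    delay: np.ndarray
    aif: ConcentrationCurve
    vof: ConcentrationCurve
    region_curves: Dict[int, ConcentrationCurve]


def make_aif(spec: AIFSpec, grid: TimeGrid) -> ConcentrationCurve:
    """Sample the gamma-variate bolus on the grid (zero before onset)."""
    if spec.onset >= grid.span:
        raise ValueError("AIF onset lies beyond the time grid")
    t = grid.times
    dt_on = t - spec.onset
    with np.errstate(invalid="ignore"):
        v = np.where(
            dt_on > 0,
            spec.amplitude * np.power(np.maximum(dt_on, 0.0), spec.shape)
            * np.exp(-dt_on / spec.timescale),
            0.0,
        )
    return ConcentrationCurve(grid, v, label="arterial")


def make_tissue_curve(
    aif: ConcentrationCurve, tk: TissueKinetics, grid: Optional[TimeGrid] = None
) -> ConcentrationCurve:
    """Tissue curve = AIF convolved with the region's flow-scaled residue
    (the forward direction of the indicator-dilution model)."""
    grid = grid or aif.grid
    if grid != aif.grid:
        raise ValueError("aif and grid disagree")
    return forward_convolve(aif, flow_scaled_residue(tk, grid))


def _to_signal(spec: PhantomSpec, conc: np.ndarray) -> np.ndarray:
    if spec.modality == "CT":
        return spec.baseline + conc / spec.k_ct
    return spec.baseline * np.exp(-spec.te * conc / spec.k_mr)


def render_acquisition(spec: PhantomSpec) -> tuple[AcquisitionSeries, GroundTruth]:
    """Render the 4D native-signal acquisition plus its ground truth.

    Frames 1..B-1 are flat baseline; frame B coincides with t = 0 of the
    concentration grid (where every region curve is 0 because the bolus
    onset is after t = 0), so the signal-to-concentration conversion is
    the exact inverse of this rendering on noiseless data.  Fully
    deterministic given the seed.
    """
    grid = spec.grid
    aif = make_aif(spec.aif, grid)
    vof = venous_outflow(aif, spec.venous_dist)

    region_curves: Dict[int, ConcentrationCurve] = {}
    for lab, reg in spec.regions.items():
        if reg.vessel == "artery":
            region_curves[lab] = aif.scaled(reg.pv_factor)
        elif reg.vessel == "vein":
            curve = vof.scaled(reg.pv_factor)
            curve.label = "venous"
            region_curves[lab] = curve
        else:
            region_curves[lab] = make_tissue_curve(aif, reg.kinetics, grid)

    shape = spec.labels.shape
    b = spec.baseline_frames
    n_frames = b - 1 + grid.n
    conc4d = np.zeros(shape + (grid.n,))
    cbf = np.full(shape, np.nan)
    cbv = np.full(shape, np.nan)
    mtt = np.full(shape, np.nan)
    delay = np.full(shape, np.nan)
    for lab, reg in spec.regions.items():
        m = spec.labels == lab
        conc4d[m] = region_curves[lab].values
        if reg.kinetics is not None:
            cbf[m] = reg.kinetics.cbf
            cbv[m] = reg.kinetics.cbv
            mtt[m] = reg.kinetics.mtt
            delay[m] = reg.kinetics.delay

    signal = np.empty(shape + (n_frames,))
    signal[..., : b - 1] = _to_signal(spec, np.zeros(shape))[..., None]
    signal[..., b - 1 :] = _to_signal(spec, conc4d)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise_sd, size=signal.shape)
        if spec.modality == "CT":
            signal = signal + noise
        else:
            factor = 1.0 + noise
            bad = signal * factor <= 0
            tries = 0
            while bad.any() and tries < 30:
                noise[bad] *= 0.5
                factor = 1.0 + noise
                bad = signal * factor <= 0
                tries += 1
            if bad.any():
                warnings.warn("MR noise clipped to keep signal positive", stacklevel=2)
                factor[bad] = 0.5
            signal = signal * factor

    series = AcquisitionSeries(
        modality=spec.modality,
        data=signal,
        grid=TimeGrid(grid.dt, n_frames),
        baseline_frames=b,
        te=spec.te,
    )
    truth = GroundTruth(
        regions=dict(spec.regions),
        labels=spec.labels.copy(),
        cbf=cbf,
        cbv=cbv,
        mtt=mtt,
        delay=delay,
        aif=aif,
        vof=vof,
        region_curves=region_curves,
    )
    return series, truth


#: canonical region labels of the reference phantom
GREY, WHITE, LESION, ARTERY, VEIN = 1, 2, 3, 4, 5


def reference_phantom(
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    modality: str = "CT",
    aif_pv_factor: float = 1.0,
) -> PhantomSpec:
    """Canonical 8 x 8 x 2 phantom with 40 one-second frames.

    Regions follow textbook adult-brain physiology: grey matter CBF 60
    mL/100 g/min with CBV 4 mL/100 g (MTT 4 s), white matter CBF 25 /
    CBV 2 (MTT 4.8 s), an ischemic lesion CBF 15 / CBV 3 with 2 s bolus
    delay and 1.5 s dispersion, plus artery and vein voxel columns.  Four
    baseline frames, CT baseline 40 HU, arterial peak enhancement 100 HU
    (tissue enhancements then land in the clinical few-HU range).
    """
    labels = np.full((8, 8, 2), GREY, dtype=int)
    labels[:, :3, :] = WHITE
    labels[5:8, 5:8, :] = LESION
    labels[0, 0, :] = ARTERY
    labels[7, 7, :] = VEIN
    regions = {
        GREY: RegionSpec(kinetics=TissueKinetics(cbf=60.0, cbv=4.0)),
        WHITE: RegionSpec(kinetics=TissueKinetics(cbf=25.0, cbv=2.0)),
        LESION: RegionSpec(
            kinetics=TissueKinetics(cbf=15.0, cbv=3.0, delay=2.0, dispersion_tau=1.5)
        ),
        ARTERY: RegionSpec(vessel="artery", pv_factor=aif_pv_factor),
        VEIN: RegionSpec(vessel="vein"),
    }
    te = 0.03 if modality == "MR" else None
    baseline = 40.0 if modality == "CT" else 100.0
    return PhantomSpec(
        labels=labels,
        regions=regions,
        grid=TimeGrid(1.0, 40),
        aif=AIFSpec.with_peak(100.0),
        modality=modality,
        baseline=baseline,
        baseline_frames=4,
        noise_sd=noise_sd,
        te=te,
        seed=seed,
    )
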