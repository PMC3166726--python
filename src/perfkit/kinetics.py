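"""Tracer-kinetic primitives for dynamic contrast perfusion analysis.

This module implements the indicator-dilution building blocks: transit-time
distributions h(t), residue functions r(t), the flow-scaled residue
k(t) = CBF * rho_voi * r(t), and the discrete forward convolution
c_voi(t) = (c_art * k)(t) that links the arterial input function to the
tissue time-concentration curve.  Everything downstream (the digital
phantom, the deconvolution solvers, the parameter extractors) is built on
these primitives.

Units
-----
Time is in seconds throughout.  CBF is stored in the clinical unit
mL/100 g/min and converted internally to mL g^-1 s^-1 (divide by 6000);
CBV is in mL/100 g; tissue density rho_voi in g/mL; k(t) carries 1/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy import stats
from scipy.integrate import cumulative_trapezoid
from scipy.signal import fftconvolve

__all__ = [
    "CBF_UNIT_FACTOR",
    "TimeGrid",
    "TransitTimeDistribution",
    "ResidueFunction",
    "TissueKinetics",
    "ConcentrationCurve",
    "FlowScaledResidue",
    "residue_from_distribution",
    "mtt_of_residue",
    "flow_scaled_residue",
    "forward_convolve",
    "venous_outflow",
]

#: mL/100 g/min -> mL g^-1 s^-1 (divide), i.e. 100 g * 60 s.
CBF_UNIT_FACTOR = 100.0 * 60.0

CurveLabel = Literal["arterial", "venous", "tissue"]


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time grid t_j = (j - 1) * dt, j = 1..n, origin at t = 0."""

    dt: float
    n: int

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) * self.dt

    @property
    def span(self) -> float:
        """Duration covered by the grid, (n - 1) * dt."""
        return (self.n - 1) * self.dt


@dataclass(frozen=True)
class TransitTimeDistribution:
    """Probability density h(t) of capillary transit times.

    Families: ``gamma`` (shape alpha, scale theta; mean = alpha * theta),
    ``exponential`` (scale tau; mean = tau), or ``tabulated`` (non-negative
    samples on a :class:`TimeGrid`, normalized to unit area at
    construction).
    """

    family: Literal["gamma", "exponential", "tabulated"]
    shape: Optional[float] = None
    scale: Optional[float] = None
    table: Optional[np.ndarray] = None
    table_grid: Optional[TimeGrid] = None

    def __post_init__(self) -> None:
        if self.family == "gamma":
            if self.shape is None or self.scale is None:
                raise ValueError("gamma distribution needs shape and scale")
            if not (self.shape > 0 and self.scale > 0):
                raise ValueError("gamma shape and scale must be > 0")
        elif self.family == "exponential":
            if self.scale is None or not self.scale > 0:
                raise ValueError("exponential distribution needs scale > 0")
        elif self.family == "tabulated":
            if self.table is None or self.table_grid is None:
                raise ValueError("tabulated distribution needs table and table_grid")
            tab = np.asarray(self.table, dtype=float)
            if tab.shape != (self.table_grid.n,):
                raise ValueError("table length must match table_grid.n")
            if np.any(tab < 0):
                raise ValueError("density must be non-negative")
            area = np.trapezoid(tab, dx=self.table_grid.dt)
            if area <= 0:
                raise ValueError("tabulated density has non-positive area")
            if abs(area - 1.0) > 1e-3:
                tab = tab / area
            object.__setattr__(self, "table", tab)
        else:  # pragma: no cover - guarded by Literal
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def mean(self) -> float:
        """First moment of h(t) -- the mean transit time it encodes."""
        if self.family == "gamma":
            return self.shape * self.scale
        if self.family == "exponential":
            return self.scale
        t = self.table_grid.times
        return float(np.trapezoid(t * self.table, t))

    def pdf(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.family == "gamma":
            return stats.gamma.pdf(t, a=self.shape, scale=self.scale)
        if self.family == "exponential":
            return stats.expon.pdf(t, scale=self.scale)
        return np.interp(t, self.table_grid.times, self.table, left=0.0, right=0.0)

    def cdf(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.family == "gamma":
            return stats.gamma.cdf(t, a=self.shape, scale=self.scale)
        if self.family == "exponential":
            return stats.expon.cdf(t, scale=self.scale)
        tg = self.table_grid.times
        cum = cumulative_trapezoid(self.table, tg, initial=0.0)
        return np.interp(t, tg, cum, left=0.0, right=cum[-1])


@dataclass(frozen=True)
class ResidueFunction:
    """Sampled residue function r(t_j): fraction of an instantaneous bolus
    still inside the tissue volume at time t_j; r(0) = 1, non-increasing."""

    grid: TimeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.grid.n,):
            raise ValueError("values length must match grid.n")
        if abs(v[0] - 1.0) > 1e-9:
            raise ValueError(f"r(0) must be 1, got {v[0]}")
        if np.any(v < -1e-12) or np.any(v > 1.0 + 1e-12):
            raise ValueError("residue values must lie in [0, 1]")
        if np.any(np.diff(v) > 1e-10):
            raise ValueError("residue function must be non-increasing")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class TissueKinetics:
    """Ground-truth (or estimated) kinetics of one tissue compartment.

    Exactly two of (cbf, cbv, mtt) are free; the third is filled in from
    the central volume theorem CBF = CBV / MTT (in consistent units,
    cbf [mL/100 g/min] = 60 * cbv [mL/100 g] / mtt [s]).  Pass ``None``
    for the derived one, or pass all three consistently (1e-9 relative).
    """

    cbf: Optional[float] = None
    cbv: Optional[float] = None
    mtt: Optional[float] = None
    rho_voi: float = 1.04
    delay: float = 0.0
    dispersion_tau: float = 0.0
    residue_family: Literal["gamma", "exponential"] = "exponential"
    residue_shape: float = 4.0

    def __post_init__(self) -> None:
        given = [x is not None for x in (self.cbf, self.cbv, self.mtt)]
        if sum(given) < 2:
            raise ValueError("at least two of cbf, cbv, mtt must be given")
        cbf, cbv, mtt = self.cbf, self.cbv, self.mtt
        if cbf is None:
            cbf = 60.0 * cbv / mtt
        elif cbv is None:
            cbv = cbf * mtt / 60.0
        elif mtt is None:
            mtt = 60.0 * cbv / cbf
        else:
            if abs(cbf - 60.0 * cbv / mtt) > 1e-9 * abs(cbf):
                raise ValueError(
                    "cbf, cbv, mtt violate the central volume theorem "
                    f"(cbf={cbf}, 60*cbv/mtt={60.0 * cbv / mtt})"
                )
        if not (cbf > 0 and cbv > 0 and mtt > 0):
            raise ValueError("cbf, cbv, mtt must be positive")
        if self.delay < 0 or self.dispersion_tau < 0:
            raise ValueError("delay and dispersion_tau must be >= 0")
        if not self.rho_voi > 0:
            raise ValueError("rho_voi must be > 0")
        object.__setattr__(self, "cbf", float(cbf))
        object.__setattr__(self, "cbv", float(cbv))
        object.__setattr__(self, "mtt", float(mtt))

    def transit_distribution(self) -> TransitTimeDistribution:
        """h(t) of the chosen family, scaled so its mean equals MTT."""
        if self.residue_family == "exponential":
            return TransitTimeDistribution("exponential", scale=self.mtt)
        return TransitTimeDistribution(
            "gamma", shape=self.residue_shape, scale=self.mtt / self.residue_shape
        )


@dataclass
class ConcentrationCurve:
    """Uniformly sampled time-concentration curve (g/mL for CT; MR uses
    proportional units).  Baseline-subtracted curves may contain small
    negative noise values."""

    grid: TimeGrid
    values: np.ndarray
    label: CurveLabel = "tissue"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.grid.n,):
            raise ValueError(
                f"curve length {v.shape} does not match grid n={self.grid.n}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("curve values must be finite")
        if self.label not in ("arterial", "venous", "tissue"):
            raise ValueError(f"unknown label {self.label!r}")
        self.values = v

    def scaled(self, factor: float) -> "ConcentrationCurve":
        return ConcentrationCurve(self.grid, self.values * factor, self.label)

    def auc(self) -> float:
        """Trapezoidal area under the curve."""
        return float(np.trapezoid(self.values, dx=self.grid.dt))


@dataclass
class FlowScaledResidue:
    """Deconvolved (or forward-modelled) flow-scaled residue k(t_j) in 1/s,
    with regularization diagnostics when produced by a solver."""

    grid: TimeGrid
    values: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.grid.n,):
            raise ValueError("k length must match grid.n")
        if not np.all(np.isfinite(v)):
            raise ValueError("k values must be finite")
        self.values = v


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def residue_from_distribution(
    dist: TransitTimeDistribution, grid: TimeGrid
) -> ResidueFunction:
    """Residue function r(t_j) = 1 - integral_0^{t_j} h(tau) dtau.

    Uses the closed-form CDF for the gamma and exponential families and a
    cumulative trapezoid for tabulated densities.  Raises if the grid does
    not cover the bulk of the distribution (CDF at the grid end < 0.5).
    """
    t = grid.times
    cdf_end = float(dist.cdf(np.array([t[-1]]))[0])
    if cdf_end < 0.5:
        raise ValueError("grid does not cover distribution support")
    r = 1.0 - dist.cdf(t)
    r = np.clip(r, 0.0, 1.0)
    r[0] = 1.0  # cdf(0) = 0 for any causal transit-time density
    return ResidueFunction(grid, r)


def mtt_of_residue(r: ResidueFunction) -> float:
    """Mean transit time as the trapezoidal integral of r(t) (seconds).

    Warns when the residue has not decayed below 0.01 at the grid end,
    in which case the truncated integral underestimates the MTT.
    """
    if r.values[-1] > 0.01:
        warnings.warn("truncated residue; MTT underestimated", stacklevel=2)
    return float(np.trapezoid(r.values, dx=r.grid.dt))


def _dispersion_kernel(tau: float, grid: TimeGrid) -> np.ndarray:
    """Causal exponential vascular transport kernel e^{-t/tau}/tau,
    discretely normalized so that dt * sum(w) = 1 (area-preserving)."""
    w = np.exp(-grid.times / tau)
    w /= w.sum() * grid.dt
    return w


def flow_scaled_residue(tk: TissueKinetics, grid: TimeGrid) -> FlowScaledResidue:
    """k(t_j) = CBF * rho_voi * r(t_j) in 1/s, with optional bolus delay
    (right shift by whole samples) and dispersion (convolution with a
    unit-area causal exponential kernel, which lowers the maximum of k
    while conserving its area, i.e. CBV)."""
    if tk.delay >= grid.span:
        raise ValueError("delay exceeds the time-grid span")
    r = residue_from_distribution(tk.transit_distribution(), grid)
    cbf_si = tk.cbf / CBF_UNIT_FACTOR  # mL g^-1 s^-1
    k = cbf_si * tk.rho_voi * r.values
    if tk.dispersion_tau > 0:
        w = _dispersion_kernel(tk.dispersion_tau, grid)
        k = grid.dt * fftconvolve(k, w)[: grid.n]
    if tk.delay > 0:
        shift = int(round(tk.delay / grid.dt))
        k = np.concatenate([np.zeros(shift), k[: grid.n - shift]])
    return FlowScaledResidue(grid, k, diagnostics={"source": "forward_model"})


def forward_convolve(aif: ConcentrationCurve, k: FlowScaledResidue) -> ConcentrationCurve:
    """Tissue curve via the rectangle-rule discrete convolution
    c_voi(t_j) = dt * sum_i c_art(t_i) k(t_{j-i+1}) (causal)."""
    if aif.grid != k.grid:
        raise ValueError("aif and k must share one time grid")
    n = aif.grid.n
    c = aif.grid.dt * fftconvolve(aif.values, k.values)[:n]
    return ConcentrationCurve(aif.grid, c, label="tissue")


def venous_outflow(
    aif: ConcentrationCurve, dist: TransitTimeDistribution
) -> ConcentrationCurve:
    """Venous outflow c_ven = c_art convolved with the transit-time density
    h(t) on the shared grid.

    The density is discretized by cell averaging, h_j = [H(t_j + dt/2) -
    H(t_j - dt/2)] / dt with H the CDF, so the discrete kernel carries
    exactly the probability mass covered by the grid; the rectangle-rule
    convolution then conserves the area of the AIF (mass conservation)
    even for sharply peaked densities.
    """
    grid = aif.grid
    t = grid.times
    upper = dist.cdf(t + 0.5 * grid.dt)
    lower = dist.cdf(np.maximum(t - 0.5 * grid.dt, 0.0))
    lower[0] = 0.0
    h = (upper - lower) / grid.dt
    c = grid.dt * fftconvolve(aif.values, h)[: grid.n]
    return ConcentrationCurve(grid, c, label="venous")
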