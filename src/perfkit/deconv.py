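"""Regularized deconvolution of the indicator-dilution convolution model.

Solves the discretized system A k = c, where A is the lower-triangular
Toeplitz (or zero-padded block-circulant) matrix built from the arterial
input function, k is the flow-scaled residue and c the tissue curve.
Provides the plain SVD least-squares solution, TSVD and Tikhonov filtered
solutions, the mathematically equivalent Fourier-domain path for the
circulant matrix, a model-based (exponential-residue) fit, and the
standard diagnostics: discrete Picard condition, oscillation index,
L-curve corner and OI-threshold selection of the regularization strength.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import cached_property
from typing import Literal, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .kinetics import ConcentrationCurve, FlowScaledResidue, TimeGrid, forward_convolve

__all__ = [
    "SystemMatrix",
    "SVDFactorization",
    "RegularizationSpec",
    "build_system_matrix",
    "least_squares_solution",
    "regularized_solution",
    "fft_deconvolve",
    "model_fit_deconvolve",
    "picard_diagnostic",
    "oscillation_index",
    "select_lambda_oi",
    "select_lambda_lcurve",
]

#: relative cutoff below which singular values are treated as numerical zero
RANK_TOL = 1e-12

#: default lambda_rel grid for OI / L-curve selection
LAMBDA_GRID_RANGE = (1e-4, 1.0)


@dataclass(frozen=True)
class SVDFactorization:
    """Thin SVD A = U diag(s) V^T truncated to numerical rank
    (s_i > 1e-12 * s_1)."""

    u: np.ndarray
    s: np.ndarray
    vt: np.ndarray

    @classmethod
    def of(cls, a: np.ndarray) -> "SVDFactorization":
        u, s, vt = np.linalg.svd(a, full_matrices=False)
        r = int(np.sum(s > RANK_TOL * s[0])) if s[0] > 0 else 0
        return cls(u[:, :r], s[:r], vt[:r])

    @property
    def rank(self) -> int:
        return self.s.size


@dataclass
class SystemMatrix:
    """Discretized convolution operator built from the AIF.

    ``toeplitz``: N x N lower-triangular with first column dt * c_art.
    ``circulant``: AIF zero-padded to L = 2N; L x L circulant whose every
    column is a circular downshift of dt * padded AIF.  The padding keeps
    the causal convolution free of wrap-around while making the solution
    insensitive to bolus delay.
    """

    kind: Literal["toeplitz", "circulant"]
    source_aif: ConcentrationCurve
    matrix: np.ndarray
    n: int  # number of time samples N of the underlying curves
    n_lz: int  # leading zeros of the AIF

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    @cached_property
    def svd(self) -> SVDFactorization:
        return SVDFactorization.of(self.matrix)


def build_system_matrix(
    aif: ConcentrationCurve, kind: Literal["toeplitz", "circulant"] = "toeplitz"
) -> SystemMatrix:
    """Build the Toeplitz or zero-padded circulant system matrix from an AIF."""
    a = aif.values
    if not np.any(a != 0):
        raise ValueError("all-zero AIF cannot form a system matrix")
    nz = np.nonzero(a)[0]
    n_lz = int(nz[0])
    dt = aif.grid.dt
    n = aif.grid.n
    if kind == "toeplitz":
        col = dt * a
        mat = linalg.toeplitz(col, np.concatenate([[col[0]], np.zeros(n - 1)]))
    elif kind == "circulant":
        padded = np.concatenate([dt * a, np.zeros(n)])
        mat = linalg.circulant(padded)
    else:
        raise ValueError(f"unknown matrix kind {kind!r}")
    return SystemMatrix(kind=kind, source_aif=aif, matrix=mat, n=n, n_lz=n_lz)


@dataclass(frozen=True)
class RegularizationSpec:
    """How to regularize the SVD solution.

    Either a fixed relative parameter ``lambda_rel`` in (0, 1] (absolute
    lambda = lambda_rel * sigma_1) or an automatic selection strategy:
    ``oi`` lowers the oscillation index below ``oi_threshold``; ``lcurve``
    picks the corner of the L-curve.  ``lcurve_grid`` log-spaced lambda_rel
    values in [1e-4, 1] are scanned by either strategy.
    """

    method: Literal["tsvd", "tikhonov"] = "tikhonov"
    lambda_rel: float = 0.2
    selection: Literal["fixed", "oi", "lcurve"] = "fixed"
    oi_threshold: float = 0.1
    lcurve_grid: int = 50

    def __post_init__(self) -> None:
        if self.method not in ("tsvd", "tikhonov"):
            raise ValueError(f"unknown filter method {self.method!r}")
        if self.selection not in ("fixed", "oi", "lcurve"):
            raise ValueError(f"unknown selection {self.selection!r}")
        if self.selection == "fixed" and not (0 < self.lambda_rel <= 1):
            raise ValueError("lambda_rel must lie in (0, 1]")
        if self.oi_threshold <= 0:
            raise ValueError("oi_threshold must be > 0")

    def lambda_grid(self) -> np.ndarray:
        lo, hi = LAMBDA_GRID_RANGE
        return np.logspace(np.log10(lo), np.log10(hi), self.lcurve_grid)


def _filter_factors(
    s: np.ndarray, lam: float, method: Literal["tsvd", "tikhonov"]
) -> np.ndarray:
    if method == "tsvd":
        return (s >= lam).astype(float)
    return s**2 / (s**2 + lam**2)


def _pad_rhs(A: SystemMatrix, c: ConcentrationCurve) -> np.ndarray:
    if c.grid != A.source_aif.grid:
        raise ValueError("tissue curve and system matrix are on different grids")
    b = c.values
    if A.kind == "circulant":
        b = np.concatenate([b, np.zeros(A.dim - b.size)])
    return b


def _filtered_solution(
    A: SystemMatrix,
    c: ConcentrationCurve,
    lam_rel: float,
    method: Literal["tsvd", "tikhonov"],
) -> FlowScaledResidue:
    svd = A.svd
    b = _pad_rhs(A, c)
    beta = svd.u.T @ b
    lam = lam_rel * svd.s[0]
    f = _filter_factors(svd.s, lam, method)
    k_full = svd.vt.T @ (f * beta / svd.s)
    k = k_full[: A.n]
    residual = float(np.linalg.norm(A.matrix @ k_full - b))
    sol_norm = float(np.linalg.norm(k_full))
    out = FlowScaledResidue(
        c.grid,
        k,
        diagnostics={
            "residual_norm": residual,
            "solution_norm": sol_norm,
            "lambda_rel_used": float(lam_rel),
            "method": method,
            "matrix_kind": A.kind,
        },
    )
    out.diagnostics["oscillation_index"] = oscillation_index(out)
    return out


def least_squares_solution(A: SystemMatrix, c: ConcentrationCurve) -> FlowScaledResidue:
    """Unregularized SVD least-squares solution k_ls = sum_i (u_i^T c / s_i) v_i
    over the retained (numerically nonzero) singular triplets."""
    svd = A.svd
    b = _pad_rhs(A, c)
    beta = svd.u.T @ b
    k_full = svd.vt.T @ (beta / svd.s)
    k = k_full[: A.n]
    out = FlowScaledResidue(
        c.grid,
        k,
        diagnostics={
            "residual_norm": float(np.linalg.norm(A.matrix @ k_full - b)),
            "solution_norm": float(np.linalg.norm(k_full)),
            "lambda_rel_used": 0.0,
            "method": "least_squares",
            "matrix_kind": A.kind,
        },
    )
    out.diagnostics["oscillation_index"] = oscillation_index(out)
    return out


def regularized_solution(
    A: SystemMatrix, c: ConcentrationCurve, spec: RegularizationSpec
) -> FlowScaledResidue:
    """TSVD or Tikhonov filtered SVD solution with lambda = lambda_rel * sigma_1.

    If the spec requests automatic selection (``oi`` or ``lcurve``), the
    selection is resolved first; the chosen lambda_rel is recorded in the
    diagnostics.  The Picard flag of the underlying (A, c) pair is
    attached as well.
    """
    if spec.selection == "oi":
        lam_rel = select_lambda_oi(A, c, spec)
    elif spec.selection == "lcurve":
        lam_rel = select_lambda_lcurve(A, c, spec)
    else:
        lam_rel = spec.lambda_rel
    if not (0 < lam_rel <= 1):
        raise ValueError("lambda_rel must lie in (0, 1]")
    out = _filtered_solution(A, c, lam_rel, spec.method)
    _, violated = picard_diagnostic(A.svd, _pad_rhs(A, c))
    out.diagnostics["picard_flag"] = violated
    out.diagnostics["selection"] = spec.selection
    return out


def fft_deconvolve(
    aif: ConcentrationCurve, c: ConcentrationCurve, spec: RegularizationSpec
) -> FlowScaledResidue:
    """Fourier-domain deconvolution, equivalent to the circulant-SVD path.

    Both curves are zero-padded to L = 2N.  The circulant matrix
    diagonalizes in the Fourier basis with eigenvalues dt * A_hat, so its
    singular values are |dt * A_hat| and the Tikhonov-filtered solution is
    the Wiener-type filter k_hat = conj(A_hat) c_hat / (|A_hat|^2 +
    lambda~^2) with lambda~ = lambda_rel * max|A_hat|; TSVD zeroes the
    frequencies with |A_hat| below the threshold instead.
    """
    if aif.grid != c.grid:
        raise ValueError("aif and tissue curve must share one grid")
    n = aif.grid.n
    L = 2 * n
    ahat = aif.grid.dt * np.fft.fft(aif.values, L)
    chat = np.fft.fft(c.values, L)
    mag = np.abs(ahat)
    lam_rel = spec.lambda_rel
    lam = lam_rel * mag.max()
    if lam == 0 and np.any(mag == 0):
        raise ValueError("unregularized division by zero Fourier coefficient")
    if spec.method == "tsvd":
        keep = mag >= lam
        khat = np.zeros(L, dtype=complex)
        khat[keep] = chat[keep] / ahat[keep]
    else:
        khat = np.conj(ahat) * chat / (mag**2 + lam**2)
    k = np.real(np.fft.ifft(khat))[:n]
    out = FlowScaledResidue(
        c.grid,
        k,
        diagnostics={
            "lambda_rel_used": float(lam_rel),
            "method": f"fft_{spec.method}",
            "matrix_kind": "circulant",
        },
    )
    out.diagnostics["oscillation_index"] = oscillation_index(out)
    return out


def model_fit_deconvolve(
    aif: ConcentrationCurve, c: ConcentrationCurve, grid: Optional[TimeGrid] = None
) -> Tuple[float, float]:
    """Model-based deconvolution with an exponential residue.

    Fits k_model(t) = a * exp(-t / b) (a = CBF * rho_voi in 1/s, b = MTT
    in s) by minimizing the squared misfit of the forward-convolved model
    to the tissue curve: a coarse logarithmic scan over b with the optimal
    a obtained in closed form (the model is linear in a), followed by a
    bounded local refinement.  Deterministic.  Returns ``(a, b)``; a
    degenerate fit with b at the search bounds is reported via a warning.
    """
    grid = grid or aif.grid
    if aif.grid != c.grid:
        raise ValueError("aif and tissue curve must share one grid")
    if not np.any(c.values != 0):
        return 0.0, grid.span / 4

    t = grid.times

    def best_a(b: float) -> Tuple[float, float]:
        """Closed-form optimal amplitude and misfit for a given timescale."""
        basis = forward_convolve(
            aif, FlowScaledResidue(grid, np.exp(-t / b))
        ).values
        denom = float(basis @ basis)
        if denom == 0:
            return 0.0, float(c.values @ c.values)
        a = float(basis @ c.values) / denom
        resid = c.values - a * basis
        return a, float(resid @ resid)

    b_lo, b_hi = 0.25 * grid.dt, 2.0 * grid.span
    b_grid = np.logspace(np.log10(b_lo), np.log10(b_hi), 60)
    costs = [best_a(b)[1] for b in b_grid]
    i = int(np.argmin(costs))
    lo = b_grid[max(i - 1, 0)]
    hi = b_grid[min(i + 1, b_grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda b: best_a(b)[1], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6 * grid.dt},
    )
    b = float(res.x)
    a, _ = best_a(b)
    if b <= 1.01 * b_lo or b >= 0.99 * b_hi:
        warnings.warn("model fit degenerate: MTT at search bounds", stacklevel=2)
    return a, b


def picard_diagnostic(
    svd: SVDFactorization, c: np.ndarray
) -> Tuple[pd.DataFrame, bool]:
    """Discrete Picard condition table and violation flag.

    Returns a DataFrame with (sigma_i, |u_i^T c|, ratio |u_i^T c|/sigma_i)
    per retained singular index.  The condition is flagged as violated
    when the geometric mean of the ratios over the trailing window (last
    5 indices) exceeds that over the leading window by more than 10x --
    i.e. the coefficients |u_i^T c| stop decaying faster than the
    singular values, the signature of noise-dominated components.
    """
    c = np.asarray(c, dtype=float)
    utc = np.abs(svd.u.T @ c)
    ratio = utc / svd.s
    table = pd.DataFrame(
        {
            "index": np.arange(1, svd.rank + 1),
            "sigma": svd.s,
            "utc": utc,
            "ratio": ratio,
        }
    )
    w = min(5, max(svd.rank // 2, 1))
    tiny = max(ratio.max(), 1.0) * 1e-300
    lead = np.exp(np.mean(np.log(np.maximum(ratio[:w], tiny))))
    trail = np.exp(np.mean(np.log(np.maximum(ratio[-w:], tiny))))
    violated = bool(trail > 10.0 * lead)
    return table, violated


def oscillation_index(k: FlowScaledResidue) -> float:
    """Normalized mean absolute second difference of k,
    OI = 1/(L * max k) * sum_j |k_j - 2 k_{j-1} + k_{j-2}| / 2.

    Zero for any affine sequence; NaN when max(k) <= 0.
    """
    v = np.asarray(k.values, dtype=float)
    if v.size < 3:
        raise ValueError("oscillation index needs at least 3 samples")
    kmax = v.max()
    if kmax <= 0:
        return float("nan")
    second = np.abs(np.diff(v, 2))
    return float(second.sum() / (2.0 * v.size * kmax))


def select_lambda_oi(
    A: SystemMatrix, c: ConcentrationCurve, spec: RegularizationSpec
) -> float:
    """Smallest lambda_rel on the log grid whose solution has an
    oscillation index below ``spec.oi_threshold``; the grid maximum (with
    a warning) when none qualifies."""
    grid = spec.lambda_grid()
    for lam_rel in grid:
        sol = _filtered_solution(A, c, float(lam_rel), spec.method)
        oi = sol.diagnostics["oscillation_index"]
        if np.isfinite(oi) and oi < spec.oi_threshold:
            return float(lam_rel)
    warnings.warn(
        "no lambda_rel on the grid reaches the OI threshold; using grid max",
        stacklevel=2,
    )
    return float(grid[-1])


def _menger_curvature(p0, p1, p2) -> float:
    """Menger curvature of three points in the plane: 4 * area / product
    of side lengths; 0 for collinear triples."""
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    a, b = p1 - p0, p2 - p0
    area2 = abs(a[0] * b[1] - a[1] * b[0])  # twice the triangle area
    d01 = np.linalg.norm(p1 - p0)
    d12 = np.linalg.norm(p2 - p1)
    d02 = np.linalg.norm(p2 - p0)
    denom = d01 * d12 * d02
    if denom == 0:
        return 0.0
    return float(2.0 * area2 / denom)


def select_lambda_lcurve(
    A: SystemMatrix, c: ConcentrationCurve, spec: RegularizationSpec
) -> float:
    """L-curve corner: the lambda_rel maximizing the Menger curvature of
    consecutive triples on the (log ||A k - c||^2, log ||k||^2) curve.

    Ties break toward smaller lambda.  A degenerate (collinear) curve
    falls back to the fixed default 0.2 with a warning.
    """
    grid = spec.lambda_grid()
    if grid.size < 3:
        raise ValueError("L-curve selection needs at least 3 grid points")
    pts = []
    for lam_rel in grid:
        sol = _filtered_solution(A, c, float(lam_rel), spec.method)
        res = max(sol.diagnostics["residual_norm"], 1e-300)
        nrm = max(sol.diagnostics["solution_norm"], 1e-300)
        pts.append((2.0 * np.log(res), 2.0 * np.log(nrm)))
    curv = np.array(
        [_menger_curvature(pts[i - 1], pts[i], pts[i + 1]) for i in range(1, grid.size - 1)]
    )
    if np.all(curv <= 1e-12):
        warnings.warn("degenerate L-curve; falling back to lambda_rel=0.2", stacklevel=2)
        return 0.2
    best = int(np.argmax(curv))  # argmax returns the first (smallest-lambda) max
    return float(grid[best + 1])
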