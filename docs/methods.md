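# Methods

## Model and scope

`perfkit` implements single-compartment, intravascular-tracer perfusion
analysis. The volume of interest is supplied by one arterial inlet and
drained by one venous outlet; transit times through the capillary bed
follow a stationary density `h(t)`, giving the residue function
`r(t) = 1 − ∫₀ᵗ h(τ)dτ` and the indicator-dilution relation
`c_voi = CBF·ρ_voi·(c_art ∗ r)`. The model assumes an intact
blood-brain barrier (no tracer leakage); permeable-tracer and
multi-compartment models are out of scope, as are the alternative
parenchyma-mass normalizations (CBF*/CBV*). Recirculation needs no
special handling under deconvolution.

Discretization uses the rectangle rule `c_voi(t_j) ≈ Δt Σ_i
c_art(t_i) k(t_{j−i+1})` — this exact rule defines the system matrix,
so the phantom's forward model and the deconvolution operator are one
and the same operator and the delta identity (impulse AIF returns `k`
exactly) holds without discretization error. All AUC-type parameter
integrals use the trapezoid rule instead, which has lower bias for
smooth integrands; the one visible consequence is that the AUC-ratio
CBV estimator inherits the rectangle-rule bias of the forward model
(about `Δt/2MTT`, i.e. ~13% at Δt = 1 s, MTT = 4 s) and is therefore
validated on finer grids, while the k-based CBV does not.

## Key parameters

| parameter | unit | default | why |
|---|---|---|---|
| `k_ct` | g/mL/HU | 1 | conversion constant drops out of linear deconvolution |
| `k_mr` | – | 1 | same argument; separate blood/tissue knobs exposed, equal by default |
| `κ` (hematocrit) | – | 0.73 | standard artery-vs-capillary plasma-fraction correction; applied to tissue curves only |
| `ρ_voi` | g/mL | 1.04 | standard mean brain-tissue density; configurable |
| `λ_rel` | – | 0.2 | typical fixed value in brain perfusion CT software |
| OI threshold | – | 0.1 | oscillation level separating physiological from ringing solutions |
| λ grid | – | 50 points, 10⁻⁴…1 | log-spaced; used by OI and L-curve selection |
| SVD rank cutoff | – | 10⁻¹² σ₁ | machine-precision rank of the Toeplitz/circulant matrix |

## Numerical choices

- **Circulant padding.** AIF and tissue curve are zero-padded to
  L = 2N before building the circulant matrix or FFT, so the causal
  linear convolution cannot wrap around. The construction sits behind
  one constructor and can be swapped.
- **FFT ≡ circulant SVD.** The circulant matrix diagonalizes in the
  Fourier basis with eigenvalues Δt·Â, so its singular values are
  |Δt·Â| and the Wiener-type filter |Â|²/(|Â|²+λ̃²) with
  λ̃ = λ_rel·max|Â| reproduces circulant-SVD Tikhonov exactly (tested
  to 1e-6; measured agreement ~1e-15).
- **Oscillation index.** The mean absolute second difference of `k`,
  normalized by L·max(k), halved: zero for affine sequences, ~2 for an
  alternating sequence. The threshold-based λ selection walks the λ
  grid upward and stops at the first OI below threshold.
- **L-curve corner.** Maximum Menger curvature over consecutive triples
  of (log‖Ak−c‖², log‖k‖²); ties break toward smaller λ; a collinear
  curve falls back to λ_rel = 0.2 with a warning.
- **Picard flag.** Violated when the geometric mean of |u_iᵀc|/σ_i over
  the trailing five indices exceeds the leading five by more than 10×.
- **Delay and dispersion in the forward model.** Delays are rounded to
  whole samples (sub-sample delay via grid refinement, keeping the
  forward model exactly representable by the discrete convolution).
  Dispersion uses a causal exponential kernel e^{−t/τ}/τ, discretely
  normalized to unit rectangle area: it lowers max(k) — hence biases
  CBF low, the qualitative effect delay/dispersion is known for —
  while conserving ∫k (CBV). The exponential form is this package's
  choice of a standard vascular transport kernel; the literature names
  the effect without fixing a kernel.
- **Gamma transit-time density.** Parameterized by (shape α, scale θ),
  mean αθ. Where only a mean is specified, shape defaults to 4 and
  only the mean is pinned in tests.
- **Negative k samples.** Regularization ripple can push `k` below
  zero; negatives are clipped in the CBV/MTT integrals only
  (configurable), never in max(k). CBF/CBV/MTT reuse one max and one
  integral, so CBF = CBV/MTT survives clipping exactly.
- **Ties and truncation.** argmax ties (TMAX, TTP) take the first
  index. Integrals are truncated at the grid end; a warning fires when
  the last sample exceeds 5% of the curve maximum. BAT is the last
  sample before the curve exceeds z·noise_sd for m consecutive samples
  (defaults z = 3, m = 2) — a threshold detector of this package's
  design, since bolus arrival is defined only conceptually.
- **Baseline convention.** Conversion consumes B baseline frames and
  places t = 0 at the last of them, so converted baselines are 0 by
  construction and B = 1 with c(0) = 0 demonstrably produces a
  rank-deficient system matrix.
- **MR validity.** Nonpositive MR signal flags the voxel invalid (NaN
  in maps) rather than clamping, to avoid fabricating concentrations.

## The digital phantom

The phantom emulates a brain perfusion CT (or DSC-MR) acquisition at
the curve level: a gamma-variate bolus `A(t−t0)^α e^{−(t−t0)/β}` as
AIF (peak 100 HU-equivalent, onset 5 s — arterial enhancement an order
of magnitude above tissue, as in clinical data), region-wise tissue
curves from known kinetics via the forward convolution, venous outflow
by convolving the AIF with a gamma transit-time density, inversion of
the concentration formulas into native signal (CT: baseline + c/k_ct;
MR: s0·exp(−TE·c/k_mr)), B−1 prepended flat baseline frames and seeded
Gaussian noise added in the native signal domain, where scanner noise
lives. The reference phantom is 8×8×2 voxels × 40 one-second frames:
grey matter (CBF 60 mL/100 g/min, CBV 4 mL/100 g), white matter
(CBF 25, CBV 2), an ischemic lesion (CBF 15, CBV 3, delay 2 s,
dispersion 1.5 s), and artery/vein columns with an optional
partial-volume factor on the artery. These sizes keep every test and
the acceptance run in seconds while leaving enough voxels for region
medians.

What the phantom does **not** model: anatomy, beam hardening, motion,
streak/ghosting artifacts, nonlinear T2* relaxivity, spatially
correlated noise, and partial volume beyond a scalar factor. Passing
tests therefore demonstrate correctness of the mathematics and the
pipeline plumbing on ideal single-compartment data — not robustness to
real scanner physics.

## Design choices where the design was open

- The AIF auto-selector is a deterministic heuristic: top-decile-by-peak
  candidates, narrowed to the earliest-first-moment cluster (arteries
  lead veins by about one transit time, which separates a
  partial-volume-attenuated artery from a brighter vein), then the
  brightest voxels with BAT at or below the masked median. It errors
  out, recommending a manual AIF, when no voxel's peak stands out
  (≥2× the median).
- Model-based deconvolution fits `k(t) = a·e^{−t/b}` by a coarse log
  scan over `b` with closed-form optimal `a` (the model is linear in
  `a`), then bounded local refinement — deterministic, no random
  starts. With a mismatched (gamma) residue, `b` is biased but the
  product `a·b` (CBV) is preserved to a few percent.
- Frame removal re-grids by linear interpolation in time onto the
  original uniform grid (deconvolution requires uniform Δt); bad end
  frames truncate rather than extrapolate.
- Registration-based motion correction, 4D/edge-preserving filtering,
  gamma-variate curve fitting, local-AIF estimation, ML-EM/Gaussian-
  process/stochastic deconvolution and generalized cross-validation
  are deliberately out of scope.

## Known limitations

- Toeplitz-matrix deconvolution underestimates CBF when the tissue
  curve is delayed relative to the AIF (measured: ~20% drop for a
  3-sample delay at λ_rel = 0.2) — use the circulant matrix when delay
  matters; its max(k) is delay-invariant and TMAX shifts by exactly
  the delay.
- The maximum-slope CBF assumes no venous outflow during the
  observation window; with realistic MTT it underestimates the
  deconvolution CBF (documented property, reproduced in tests).
- The peak-ratio CBV is a dimensionless approximation, not
  unit-matched to the AUC-ratio estimator.
- Fixed λ_rel biases CBF low as λ grows; the OI and L-curve selectors
  mitigate but do not remove this.
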