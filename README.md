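# perfkit

Deconvolution-based brain-perfusion analysis for dynamic contrast CT and
MR series. From a 4D acquisition (x, y, z, time) — or a single pair of
time-concentration curves — `perfkit` computes the standard perfusion
parameter maps used in stroke imaging: CBF, CBV, MTT, TTP, TMAX, BAT,
FM and c_max. A ground-truth digital phantom is included, so the whole
pipeline is testable without any clinical data.

Intended for researchers and engineers building or validating perfusion
post-processing: every stage (signal conversion, AIF handling,
deconvolution, parameter extraction) is an importable function with a
thin CLI on top.

## The model

Indicator-dilution theory links the tissue time-concentration curve
`c_voi(t)` to the arterial input function `c_art(t)` through the
flow-scaled residue function `k(t) = CBF · ρ_voi · r(t)`:

```
c_voi(t) = (c_art ∗ k)(t)
```

where `r(t)` is the residue function (fraction of an instantaneous
bolus still in the tissue at time `t`; `r(0) = 1`, non-increasing) and
`ρ_voi` the tissue density. Sampling at `t_j = (j−1)Δt` turns the
convolution into a lower-triangular Toeplitz system `A k = c` (or a
zero-padded block-circulant system, which is insensitive to bolus
delay). The system is ill-conditioned, so `perfkit` solves it by SVD
with TSVD or Tikhonov filtering:

```
k_λ = Σ_i f_λ,i · (u_iᵀc / σ_i) · v_i,   λ = λ_rel · σ_1
f_λ,i(tsvd) = 1{σ_i ≥ λ},   f_λ,i(tikh) = σ_i²/(σ_i² + λ²)
```

Parameters follow from `k`: `CBF = max(k)/ρ_voi`,
`CBV = ∫k/ρ_voi`, `MTT = ∫k / max(k)` (central volume theorem
`CBF = CBV/MTT` holds exactly), `TMAX = argmax_t k(t)`. The
nondeconvolution estimators (maximum-slope CBF, AUC-ratio and
peak-ratio CBV) and the curve descriptors (TTP, c_max, first moment,
bolus arrival time) are also provided, as are the diagnostics used to
choose `λ_rel`: the discrete Picard condition, the oscillation index
and the L-curve corner.

## Worked example

```python
import numpy as np
import perfkit as pk

grid = pk.TimeGrid(dt=1.0, n=40)                      # 40 frames at 1 s
aif  = pk.make_aif(pk.AIFSpec.with_peak(100.0), grid) # gamma-variate bolus
tk   = pk.TissueKinetics(cbf=60.0, cbv=4.0, rho_voi=1.04)  # grey matter
c    = pk.forward_convolve(aif, pk.flow_scaled_residue(tk, grid))

A   = pk.build_system_matrix(aif, "toeplitz")
sol = pk.regularized_solution(A, c, pk.RegularizationSpec(method="tikhonov",
                                                          lambda_rel=0.01))
print(round(pk.cbf_from_k(sol, rho=1.04), 1),
      round(pk.cbv_from_k(sol, rho=1.04), 2),
      round(pk.mtt_from_k(sol), 2))
```

prints

```
59.7 4.02 4.04
```

i.e. the known grey-matter ground truth (CBF 60 mL/100 g/min, CBV
4 mL/100 g, MTT 4 s) is recovered to about 1% on noiseless data; the
residual error is the discretization and regularization bias at
Δt = 1 s and λ_rel = 0.01.

The same works at volume level from the shell:

```
perfkit phantom --out ph/
perfkit run ph/dynamic.nii --out maps/ --dt 1 --baseline-frames 4
```

which writes one NIfTI per parameter plus `report.json` with the
effective configuration, input hash and per-voxel failure counts.

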