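import numpy as np
import pytest

import perfkit as pk


@pytest.fixture(scope="session")
def grid40():
    """Clinical-style grid: 40 frames at 1 s."""
    return pk.TimeGrid(1.0, 40)


@pytest.fixture(scope="session")
def fine_grid():
    """Dense grid for discretization-sensitive checks."""
    return pk.TimeGrid(0.1, 600)


@pytest.fixture(scope="session")
def aif40(grid40):
    """Gamma-variate AIF peaking at 100 concentration units, onset 5 s."""
    return pk.make_aif(pk.AIFSpec.with_peak(100.0), grid40)


@pytest.fixture(scope="session")
def grey_kinetics():
    """Grey-matter kinetics: CBF 60 mL/100 g/min, CBV 4 mL/100 g (MTT 4 s)."""
    return pk.TissueKinetics(cbf=60.0, cbv=4.0, rho_voi=1.04)


@pytest.fixture(scope="session")
def single_voxel_problem(grid40, aif40, grey_kinetics):
    """Noiseless (aif, k_true, c_voi) triple with exponential residue."""
    k = pk.flow_scaled_residue(grey_kinetics, grid40)
    c = pk.forward_convolve(aif40, k)
    return aif40, k, c


def random_deconv_problem(rng, n):
    """Random smooth Toeplitz deconvolution problem for oracle checks."""
    grid = pk.TimeGrid(1.0, n)
    t = grid.times
    onset = rng.uniform(1.0, n / 4)
    shape = rng.uniform(1.5, 5.0)
    scale = rng.uniform(0.8, 2.5)
    a = np.where(t > onset, np.power(np.maximum(t - onset, 0), shape)
                 * np.exp(-(t - onset) / scale), 0.0)
    peak = a.max()
    if peak == 0:
        a[-1] = 1.0
        peak = 1.0
    aif = pk.ConcentrationCurve(grid, a / peak, "arterial")
    mtt = rng.uniform(2.0, 8.0)
    k_true = 0.01 * np.exp(-t / mtt)
    c = pk.forward_convolve(aif, pk.FlowScaledResidue(grid, k_true))
    noisy = c.values + rng.normal(0, 0.01 * max(c.values.max(), 1e-12), n)
    return aif, k_true, pk.ConcentrationCurve(grid, noisy, "tissue")
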