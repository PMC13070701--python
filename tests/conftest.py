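"""Shared fixtures and independent numerical oracles.

The oracles here are deliberately primitive implementations kept separate
from the package: a fixed-step RK4 integrator of the Bloch-McConnell
equations (checks the matrix-exponential kernel) and the Trott-Palmer
closed-form R1rho (checks the analytical kernel in its slow-exchange
validity domain).

Expensive joint fits of the five-residue benchmark are session-scoped so
the acceptance tests share them.
"""

import time
from dataclasses import replace

import numpy as np
import pytest

from cestfit.model import Acquisition, make_model
from cestfit.fitting import FitSpec, joint_fit
from cestfit.synthetic import generate, paper_validation_spec


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def rk4_propagate(generators, M0s, T, dt=1e-5):
    """Fixed-step 4th-order Runge-Kutta integration of dM/dt = G M.

    ``generators``: (m, d, d) stacked matrices, ``M0s``: (m, d) states;
    integrates all systems simultaneously.  Written independently of the
    package's matrix-exponential machinery.
    """
    G = np.asarray(generators, dtype=float)
    M = np.array(M0s, dtype=float)
    n_steps = int(np.ceil(T / dt))
    if n_steps == 0:
        return M
    h = T / n_steps
    for _ in range(n_steps):
        k1 = np.einsum("mij,mj->mi", G, M)
        k2 = np.einsum("mij,mj->mi", G, M + 0.5 * h * k1)
        k3 = np.einsum("mij,mj->mi", G, M + 0.5 * h * k2)
        k4 = np.einsum("mij,mj->mi", G, M + h * k3)
        M = M + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return M


def trott_palmer_r1rho(model, omega_A, omega_B, omega1):
    """First-order two-site R1rho closed form (average-frame tilt).

    Valid for slow exchange with a small minor population and equal
    transverse rates; used as a literature cross-check of the package's
    eigenvalue-based rate.
    """
    pa, pb = model.p_A, model.p_B
    obar = pa * omega_A + pb * omega_B
    we2 = obar ** 2 + omega1 ** 2
    wae2 = omega_A ** 2 + omega1 ** 2
    wbe2 = omega_B ** 2 + omega1 ** 2
    dw = omega_B - omega_A
    sin2 = omega1 ** 2 / we2
    cos2 = obar ** 2 / we2
    rex = pa * pb * dw ** 2 * model.k_ex / (wae2 * wbe2 / we2
                                            + model.k_ex ** 2)
    return model.R1_A * cos2 + sin2 * (model.R2_A + rex)


@pytest.fixture(scope="session")
def oracles():
    return {"rk4": rk4_propagate, "trott_palmer": trott_palmer_r1rho}


# ---------------------------------------------------------------------------
# benchmark parameters
# ---------------------------------------------------------------------------

BENCHMARK_SEED = 1


@pytest.fixture(scope="session")
def paper_acq():
    return Acquisition(larmor_MHz=80.12, T_sat=0.4, b1_fields=(10.0, 100.0))


@pytest.fixture(scope="session")
def paper_models():
    """Ground-truth models of the five benchmark residues."""
    table = [("A1", 118.0, -5.0), ("A2", 110.0, -1.0), ("A3", 115.0, 2.0),
             ("A4", 120.0, 2.0), ("A5", 125.0, -3.0)]
    return {rid: make_model(k_ex=300.0, p_B=0.05, delta_A=da,
                            delta_delta=dd, R1_A=1.5, R2_A=10.0, R2_B=10.0)
            for rid, da, dd in table}


@pytest.fixture(scope="session")
def benchmark_noisy():
    """Regenerated five-residue 2%-noise dataset (fixed seed)."""
    spec = paper_validation_spec(seed=BENCHMARK_SEED)
    profiles, truth = generate(spec)
    return spec, profiles, truth


@pytest.fixture(scope="session")
def benchmark_noiseless():
    spec = replace(paper_validation_spec(seed=BENCHMARK_SEED),
                   intensity_noise_frac=0.0, b1_error_frac=0.0)
    profiles, truth = generate(spec)
    return spec, profiles, truth


def _timed_fit(profiles, acq, spec):
    t0 = time.perf_counter()
    result = joint_fit(profiles, acq, spec)
    return result, time.perf_counter() - t0


@pytest.fixture(scope="session")
def baldwin_fit(benchmark_noisy):
    spec, profiles, _ = benchmark_noisy
    return _timed_fit(profiles, spec.acquisition, FitSpec(method="baldwin"))


@pytest.fixture(scope="session")
def matrix_fit(benchmark_noisy):
    spec, profiles, _ = benchmark_noisy
    return _timed_fit(profiles, spec.acquisition, FitSpec(method="matrix"))


@pytest.fixture(scope="session")
def noex_fit(benchmark_noisy):
    spec, profiles, _ = benchmark_noisy
    return _timed_fit(profiles, spec.acquisition, FitSpec(method="noex"))


@pytest.fixture(scope="session")
def noiseless_fit(benchmark_noiseless):
    spec, profiles, _ = benchmark_noiseless
    return _timed_fit(profiles, spec.acquisition, FitSpec(method="matrix"))
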