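"""Forward models mapping exchange parameters to Z-spectrum intensities.

Three kernels are provided, all with the same contract
``(ExchangeModel, Acquisition, nu1, offsets_ppm) -> normalized intensities``:

``profile_matrix``
    Exact numerical solution of the two-state Bloch-McConnell equations.
    The evolution is generated by a 7x7 matrix acting on the augmented
    state ``[1, MxA, MyA, MzA, MxB, MyB, MzB]``; the constant first element
    implements longitudinal recovery toward thermal equilibrium
    (``Mz_S -> p_S``), which is what makes the generator 7x7 rather than
    6x6.  Magnetization starts at equilibrium, ``[1, 0,0,p_A, 0,0,p_B]``,
    and the reported intensity is ``Mz_A(T_sat)/p_A`` so that the
    zero-duration reference is exactly 1.

``profile_baldwin``
    Analytical rotating-frame approximation.  The effective relaxation rate
    R1rho of the spin-locked mode is obtained from the exact eigensystem of
    the coherent + exchange part of the Bloch-McConnell generator with the
    relaxation matrix applied as a first-order perturbation; this is exact
    in the exchange rates and RF amplitude, first order in R1/R2, and
    collapses to the textbook ``R1*cos^2(theta) + R2*sin^2(theta)`` when
    exchange is switched off.  Intensities follow the monoexponential
    rotating-frame model with its longitudinal steady state,
    ``I = Zss + (cos^2(theta) - Zss) * exp(-R1rho*T_sat)`` with
    ``Zss = R1A*cos^2(theta)/R1rho``, so the far-off-resonance baseline is 1.

``profile_noex``
    Exchange-free single-spin Bloch evolution (negative control).

``apply_b1_inhomogeneity`` averages any of the above over a truncated
Gaussian distribution of B1 amplitudes, modelling RF inhomogeneity across
the sample volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import scipy.linalg

from .exceptions import ValidationError
from .model import Acquisition, ExchangeModel, angular_frequencies, TWO_PI

__all__ = [
    "Propagator",
    "build_bm_matrix",
    "propagate",
    "profile_matrix",
    "r1rho_baldwin",
    "profile_baldwin",
    "profile_noex",
    "apply_b1_inhomogeneity",
    "gaussian_b1_grid",
    "predict_profile",
]


# ---------------------------------------------------------------------------
# Bloch-McConnell generators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Propagator:
    """Augmented 7x7 Bloch-McConnell generator (rate units, 1/s).

    State layout: ``[1, MxA, MyA, MzA, MxB, MyB, MzB]``.  Row 0 is zero so
    the constant element stays 1 under evolution.
    """

    generator: np.ndarray

    def __post_init__(self) -> None:
        gen = np.asarray(self.generator, dtype=float)
        if gen.shape != (7, 7):
            raise ValidationError("parameter 'generator': must be a 7x7 matrix")
        if np.any(gen[0] != 0.0):
            raise ValidationError("parameter 'generator': first row must be zero")
        object.__setattr__(self, "generator", gen)


def _homogeneous_blocks(model: ExchangeModel, omega_A, omega_B, omega1):
    """Stacked homogeneous 6x6 generator and constant recovery vector.

    ``omega_A``/``omega_B`` may be arrays (one matrix per offset); the RF
    field is applied along +x of the rotating frame.
    """
    omega_A = np.atleast_1d(np.asarray(omega_A, dtype=float))
    omega_B = np.atleast_1d(np.asarray(omega_B, dtype=float))
    n = omega_A.size
    kab, kba = model.k_AB, model.k_BA
    A = np.zeros((n, 6, 6))
    # state A block
    A[:, 0, 0] = -(model.R2_A + kab)
    A[:, 0, 1] = -omega_A
    A[:, 1, 0] = omega_A
    A[:, 1, 1] = -(model.R2_A + kab)
    A[:, 1, 2] = -omega1
    A[:, 2, 1] = omega1
    A[:, 2, 2] = -(model.R1_A + kab)
    # state B block
    A[:, 3, 3] = -(model.R2_B + kba)
    A[:, 3, 4] = -omega_B
    A[:, 4, 3] = omega_B
    A[:, 4, 4] = -(model.R2_B + kba)
    A[:, 4, 5] = -omega1
    A[:, 5, 4] = omega1
    A[:, 5, 5] = -(model.R1_B + kba)
    # exchange coupling
    for i in range(3):
        A[:, i, i + 3] = kba
        A[:, i + 3, i] = kab
    b = np.array([0.0, 0.0, model.R1_A * model.p_A,
                  0.0, 0.0, model.R1_B * model.p_B])
    return A, b


def build_bm_matrix(model: ExchangeModel, omega_A: float, omega_B: float,
                    omega1: float) -> Propagator:
    """Augmented 7x7 generator at a single (Omega_A, Omega_B, omega1)."""
    for name, val in (("omega_A", omega_A), ("omega_B", omega_B),
                      ("omega1", omega1)):
        if not np.isfinite(val):
            raise ValidationError(f"parameter '{name}': must be finite")
    A, b = _homogeneous_blocks(model, omega_A, omega_B, omega1)
    gen = np.zeros((7, 7))
    gen[1:, 1:] = A[0]
    gen[1:, 0] = b
    return Propagator(gen)


def propagate(prop: Propagator, M0: Sequence[float], T: float) -> np.ndarray:
    """Evolve the augmented state for a time T via matrix exponentiation."""
    if T < 0:
        raise ValidationError("parameter 'T': must be >= 0")
    M0 = np.asarray(M0, dtype=float)
    if M0.shape != (7,):
        raise ValidationError("parameter 'M0': must be a 7-vector")
    if not math.isclose(M0[0], 1.0, rel_tol=0.0, abs_tol=1e-12):
        raise ValidationError("parameter 'M0': element 0 must be 1")
    return scipy.linalg.expm(prop.generator * T) @ M0


# ---------------------------------------------------------------------------
# fast affine evolution  dM/dt = A M + b
# ---------------------------------------------------------------------------

def _evolve_affine(A: np.ndarray, b: np.ndarray, M0: np.ndarray,
                   T: float) -> np.ndarray:
    """Solve dM/dt = A M + b for stacked A (n,d,d), shared b and M0.

    Eigendecomposition route (mathematically the matrix exponential of the
    augmented generator); falls back to scipy expm per matrix if the
    eigenbasis is unusable.
    """
    n, d, _ = A.shape
    try:
        rhs = np.broadcast_to(-b, (n, d))[..., None]
        Minf = np.linalg.solve(A, rhs)[..., 0]
        w, V = np.linalg.eig(A)
        dev = M0[None, :] - Minf
        c = np.linalg.solve(V, dev.astype(complex)[..., None])[..., 0]
        # reconstruction check: V @ c must reproduce the initial deviation
        rec = np.einsum("nij,nj->ni", V, c).real
        scale = 1.0 + np.abs(dev)
        ok = np.all(np.isfinite(rec)) and np.max(np.abs(rec - dev) / scale) < 1e-9
        if not ok:
            raise np.linalg.LinAlgError("ill-conditioned eigenbasis")
        MT = Minf + np.einsum("nij,nj->ni", V, np.exp(w * T) * c).real
        if not np.all(np.isfinite(MT)):
            raise np.linalg.LinAlgError("non-finite evolution")
        return MT
    except np.linalg.LinAlgError:
        out = np.empty((n, d))
        gen = np.zeros((d + 1, d + 1))
        for i in range(n):
            gen[1:, 1:] = A[i]
            gen[1:, 0] = b
            aug = scipy.linalg.expm(gen * T) @ np.concatenate(([1.0], M0))
            out[i] = aug[1:]
        return out


def profile_matrix(model: ExchangeModel, acq: Acquisition, nu1: float,
                   offsets_ppm, observe: str = "A") -> np.ndarray:
    """Z-spectrum from the full 7x7 Bloch-McConnell propagation.

    ``observe`` selects which state's z-magnetization is read out
    (normalized by its own equilibrium population); the measured CEST
    signal is state A.
    """
    offsets = np.atleast_1d(np.asarray(offsets_ppm, dtype=float))
    if not np.all(np.isfinite(offsets)):
        raise ValidationError("parameter 'offsets_ppm': must be finite")
    omega_A, omega_B, omega1 = angular_frequencies(model, acq, offsets, nu1)
    A, b = _homogeneous_blocks(model, omega_A, omega_B, omega1)
    M0 = np.array([0.0, 0.0, model.p_A, 0.0, 0.0, model.p_B])
    MT = _evolve_affine(A, b, M0, acq.T_sat)
    if observe == "A":
        return MT[:, 2] / model.p_A
    if observe == "B":
        return MT[:, 5] / model.p_B
    raise ValidationError("parameter 'observe': must be 'A' or 'B'")


# ---------------------------------------------------------------------------
# analytical rotating-frame kernel
# ---------------------------------------------------------------------------

def _baldwin_modes(model: ExchangeModel, omega_A, omega_B, omega1: float):
    """Perturbed eigenvalues of the spin-lock and transverse modes.

    The coherent + exchange 6x6 generator is diagonalized exactly and the
    relaxation matrix is applied as a first-order (complex) eigenvalue
    shift.  Two modes are identified by overlap with ground-state-frame
    directions: the spin-locked mode (along the tilted effective field
    ``(sin(theta), 0, cos(theta))``, tan(theta) = omega1/Omega_A) whose
    decay rate is R1rho, and one of the transverse precessing pair (along
    ``(-cos(theta), 0, sin(theta))``) whose complex eigenvalue carries the
    transient's decay rate and precession frequency.

    Returns ``(lam_lock, lam_perp)`` as complex arrays (evolution
    eigenvalues; R1rho = -Re(lam_lock)).
    """
    if not (np.isfinite(omega1) and omega1 > 0):
        raise ValidationError("parameter 'omega1': must be finite and > 0")
    omega_A = np.atleast_1d(np.asarray(omega_A, dtype=float))
    omega_B = np.atleast_1d(np.asarray(omega_B, dtype=float))
    if not (np.all(np.isfinite(omega_A)) and np.all(np.isfinite(omega_B))):
        raise ValidationError("parameter 'omega_A/omega_B': must be finite")

    omega_eA = np.sqrt(omega_A ** 2 + omega1 ** 2)
    sin_t, cos_t = omega1 / omega_eA, omega_A / omega_eA

    if model.k_ex == 0.0:
        # exchange-free closed forms: textbook tilted-frame rates
        lock = -(model.R1_A * cos_t ** 2 + model.R2_A * sin_t ** 2)
        perp = (-(model.R2_A + (model.R1_A - model.R2_A) * sin_t ** 2 / 2.0)
                + 1j * omega_eA)
        return lock.astype(complex), perp

    relax_free = ExchangeModel(
        delta_A=model.delta_A, delta_delta=model.delta_delta,
        k_ex=model.k_ex, p_B=model.p_B,
        R1_A=0.0, R1_B=0.0, R2_A=0.0, R2_B=0.0,
    )
    N, _ = _homogeneous_blocks(relax_free, omega_A, omega_B, omega1)
    w, V = np.linalg.eig(N)
    Vinv = np.linalg.inv(V)
    rdiag = np.array([model.R2_A, model.R2_A, model.R1_A,
                      model.R2_B, model.R2_B, model.R1_B])
    # first-order complex eigenvalue shift of each mode by relaxation
    corr = np.einsum("nkm,m,nmk->nk", Vinv, rdiag, V)
    lam = w - corr

    n = omega_A.size
    u_lock = np.zeros((n, 6))
    u_lock[:, 0] = sin_t
    u_lock[:, 2] = cos_t
    u_perp = np.zeros((n, 6))
    u_perp[:, 0] = -cos_t
    u_perp[:, 2] = sin_t
    # LAPACK returns unit-norm eigenvector columns
    score_lock = np.abs(np.einsum("ni,nik->nk", u_lock.astype(complex), V))
    score_perp = np.abs(np.einsum("ni,nik->nk", u_perp.astype(complex), V))
    idx = np.arange(n)
    pick_lock = np.argmax(score_lock, axis=1)
    score_perp[idx, pick_lock] = -1.0  # transverse mode is a different mode
    pick_perp = np.argmax(score_perp, axis=1)
    lam_lock = lam[idx, pick_lock]
    lam_perp = lam[idx, pick_perp]
    if not (np.all(np.isfinite(lam_lock)) and np.all(np.isfinite(lam_perp))):
        raise ValidationError(
            "R1rho evaluation produced non-finite values (parameter pathology)")
    return lam_lock, lam_perp


def r1rho_baldwin(model: ExchangeModel, omega_A, omega_B,
                  omega1: float) -> np.ndarray:
    """Two-site rotating-frame relaxation rate R1rho (1/s).

    Exact in the exchange rates and RF amplitude, first order in the
    relaxation rates (see :func:`_baldwin_modes`).  At ``k_ex = 0`` this
    reduces exactly to ``R1*cos^2(theta) + R2*sin^2(theta)`` with
    ``tan(theta) = omega1/Omega_A``.
    """
    lam_lock, _ = _baldwin_modes(model, omega_A, omega_B, omega1)
    return -lam_lock.real


def profile_baldwin(model: ExchangeModel, acq: Acquisition, nu1: float,
                    offsets_ppm) -> np.ndarray:
    """Z-spectrum from the analytical R1rho kernel.

    The equilibrium ground-state magnetization is decomposed along the
    tilted effective field (tilt theta in the ground-state rotating frame).
    The locked component decays monoexponentially at R1rho toward the
    spin-lock steady state and is projected back onto z for detection; the
    orthogonal component precesses about the effective field at omega_e
    while decaying, producing the short-``T_sat`` transient::

        I = Zss + (cos^2(theta) - Zss) exp(-R1rho T)
                + sin^2(theta) exp(-lambda_perp T) cos(omega_e T)

    with ``Zss = R1A cos^2(theta) / R1rho``.  Limits: I -> 1 far off
    resonance (Zss -> 1), I -> 0 on resonance with the ground state
    (cos(theta) = 0 and the transient term's precession average), and
    I(T=0) = 1 (equilibrium).
    """
    offsets = np.atleast_1d(np.asarray(offsets_ppm, dtype=float))
    omega_A, omega_B, omega1 = angular_frequencies(model, acq, offsets, nu1)
    lam_lock, lam_perp = _baldwin_modes(model, omega_A, omega_B, omega1)
    r1rho = -lam_lock.real
    cos2 = omega_A ** 2 / (omega_A ** 2 + omega1 ** 2)
    zss = _steady_state_z(model, omega_A, omega_B, omega1)
    if zss is None:  # singular steady state (e.g. R1 = 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            zss = np.where(r1rho > 0, model.R1_A * cos2 / r1rho, 0.0)
    locked = zss + (cos2 - zss) * np.exp(-r1rho * acq.T_sat)
    transient = (1.0 - cos2) * np.exp(lam_perp * acq.T_sat).real
    return locked + transient


def _steady_state_z(model: ExchangeModel, omega_A, omega_B, omega1):
    """Exact spin-lock steady state Zss = Mz_A(inf)/p_A, or None if singular.

    The long-time limit of the Bloch-McConnell equations is the solution of
    the linear system ``A M_inf = -b``; this closed form replaces the usual
    ``R1 cos^2(theta) / R1rho`` approximation.
    """
    A, b = _homogeneous_blocks(model, omega_A, omega_B, omega1)
    n = A.shape[0]
    try:
        rhs = np.broadcast_to(-b, (n, 6))[..., None]
        minf = np.linalg.solve(A, rhs)[..., 0]
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(minf)):
        return None
    return minf[:, 2] / model.p_A


# ---------------------------------------------------------------------------
# exchange-free baseline kernel
# ---------------------------------------------------------------------------

def profile_noex(R1: float, R2: float, delta_A: float, acq: Acquisition,
                 nu1: float, offsets_ppm) -> np.ndarray:
    """Single-spin Bloch evolution with no chemical exchange.

    Full time-dependent solution (including R1 recovery during
    saturation), started from thermal equilibrium Mz = 1.
    """
    offsets = np.atleast_1d(np.asarray(offsets_ppm, dtype=float))
    if not np.all(np.isfinite(offsets)):
        raise ValidationError("parameter 'offsets_ppm': must be finite")
    omega = TWO_PI * (delta_A - offsets) * acq.larmor_MHz
    omega1 = TWO_PI * float(nu1)
    n = offsets.size
    A = np.zeros((n, 3, 3))
    A[:, 0, 0] = -R2
    A[:, 0, 1] = -omega
    A[:, 1, 0] = omega
    A[:, 1, 1] = -R2
    A[:, 1, 2] = -omega1
    A[:, 2, 1] = omega1
    A[:, 2, 2] = -R1
    b = np.array([0.0, 0.0, R1])
    M0 = np.array([0.0, 0.0, 1.0])
    MT = _evolve_affine(A, b, M0, acq.T_sat)
    return MT[:, 2]


# ---------------------------------------------------------------------------
# B1 inhomogeneity
# ---------------------------------------------------------------------------

def gaussian_b1_grid(nominal_nu1: float, frac_sigma: float, n_points: int):
    """Quadrature nodes and renormalized Gaussian weights over +/- 2 sigma."""
    if n_points < 1 or n_points % 2 == 0:
        raise ValidationError("parameter 'n_points': must be an odd integer >= 1")
    if frac_sigma < 0:
        raise ValidationError("parameter 'frac_sigma': must be >= 0")
    if frac_sigma > 0.5:
        raise ValidationError(
            "parameter 'frac_sigma': > 0.5 is an unphysical B1 spread")
    if frac_sigma == 0.0 or n_points == 1:
        return np.array([nominal_nu1]), np.array([1.0])
    s = np.linspace(-2.0, 2.0, n_points)  # units of sigma
    weights = np.exp(-0.5 * s * s)
    weights /= weights.sum()
    return nominal_nu1 * (1.0 + frac_sigma * s), weights


def apply_b1_inhomogeneity(profile_fn: Callable[[float, np.ndarray], np.ndarray],
                           nominal_nu1: float, frac_sigma: float,
                           n_points: int, offsets_ppm) -> np.ndarray:
    """Average ``profile_fn(nu1, offsets)`` over the Gaussian B1 distribution."""
    offsets = np.atleast_1d(np.asarray(offsets_ppm, dtype=float))
    nus, weights = gaussian_b1_grid(nominal_nu1, frac_sigma, n_points)
    if nus.size == 1:
        return np.asarray(profile_fn(float(nus[0]), offsets), dtype=float)
    out = np.zeros(offsets.shape)
    for nu, wgt in zip(nus, weights):
        out += wgt * np.asarray(profile_fn(float(nu), offsets), dtype=float)
    return out


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

_METHODS = ("baldwin", "matrix", "noex")


def predict_profile(model: ExchangeModel, acq: Acquisition, nu1: float,
                    offsets_ppm, method: str = "baldwin") -> np.ndarray:
    """Predicted Z-spectrum by method name, honoring B1 inhomogeneity.

    When ``acq.b1_frac_sigma > 0`` the kernel is averaged over the Gaussian
    B1 distribution with ``acq.b1_grid_points`` quadrature nodes.
    """
    if method not in _METHODS:
        raise ValidationError(
            f"parameter 'method': must be one of {_METHODS}, got {method!r}")
    if method == "matrix":
        fn = lambda v, off: profile_matrix(model, acq, v, off)
    elif method == "baldwin":
        fn = lambda v, off: profile_baldwin(model, acq, v, off)
    else:
        fn = lambda v, off: profile_noex(model.R1_A, model.R2_A,
                                         model.delta_A, acq, v, off)
    if acq.b1_frac_sigma > 0 and acq.b1_grid_points > 1:
        return apply_b1_inhomogeneity(fn, nu1, acq.b1_frac_sigma,
                                      acq.b1_grid_points, offsets_ppm)
    return fn(nu1, np.atleast_1d(np.asarray(offsets_ppm, dtype=float)))
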